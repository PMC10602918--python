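"""Format readers/writers shared by the toolkit: FASTA, FASTQ, collapsed
FASTA (">id-count" headers, the fastx_collapser dialect), TSV, JSON and
dot-bracket text.  Gzip is handled transparently by file extension."""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .design import ValidationError
from .srnametrics import ReadRecord


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences from a (possibly gzipped) FASTA file, in file order."""
    with _open(path) as fh:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise ValidationError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from FASTQ; counts are 1 per read (collapse separately)."""
    reads: list[str] = []
    with _open(path) as fh:
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                reads.append(seq)
        except ValueError as exc:
            raise ValidationError(f"malformed FASTQ record {len(reads) + 1} in {path}: {exc}") from exc
    return reads


def read_collapsed_fasta(path: str | Path) -> list[ReadRecord]:
    """Collapsed reads with ">id-count" headers; the count is mandatory."""
    records: list[ReadRecord] = []
    with _open(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
            head, sep, count = rec.id.rpartition("-")
            if not sep or not count.isdigit():
                raise ValidationError(
                    f"record {i} in {path}: header {rec.id!r} lacks a '-count' suffix; "
                    "for per-read input use FASTQ mode instead"
                )
            records.append(ReadRecord(str(rec.seq).upper().replace("U", "T"), int(count)))
    return records


def write_collapsed_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for rank, rec in enumerate(records, start=1):
            fh.write(f">{rank}-{rec.count}\n{rec.sequence}\n")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_dotbracket(name: str, sequence: str, dotbracket: str, path: str | Path) -> None:
    """Vienna-convention text: header, sequence, structure."""
    with _open(path, "wt") as fh:
        fh.write(f">{name}\n{sequence}\n{dotbracket}\n")


def write_provenance(path: str | Path, config: Mapping, version: str, seed: int | None = None) -> None:
    """Machine-readable provenance block accompanying every CLI run."""
    payload = {k: v for k, v in sorted(config.items())}
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    write_json({"tool": "amirnakit", "version": version, "seed": seed,
                "config": payload, "config_sha256": digest}, path)
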