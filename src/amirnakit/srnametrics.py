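"""sRNA-seq evaluation of amiRNA precursor processing.

Implements the exact-match small-RNA read analysis used to judge how
accurately a Dicer-like enzyme releases the mature 21-nt amiRNA from its
precursor: read collapsing, ungapped exact mapping of unique reads against a
reference (forward strand or both), per-position counts and RPM (reads per
million mapped reads), the processing-accuracy statistic (fraction of
19-24 nt (+) reads with 5' ends within +/-4 nt of the guide 5' end that are
the authentic 21-nt amiRNA), strand polarity, and 21-register phasing tables
downstream of a miRNA-guided cleavage site.

All matching is exact: no mismatches, no gaps.  That is a stated feature of
the method, not a shortcut.  Reads are handled in DNA space (as sequenced);
RNA references are converted to DNA for matching.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import GuideRNA, Precursor, ValidationError, as_dna, reverse_complement

logger = logging.getLogger(__name__)

MIN_SRNA_LEN = 19
MAX_SRNA_LEN = 24
ACCURACY_WINDOW = 4  # +/- nt around the guide 5' end
PHASE = 21


@dataclass(frozen=True, order=True)
class ReadRecord:
    """A collapsed read: unique sequence with its total count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"read count must be >= 1, got {self.count}")


@dataclass
class MappingProfile:
    """Per-position, per-length, per-strand 5'-end counts of exact hits.

    ``hits`` maps (position, length, strand) -> count, where position is the
    1-based reference coordinate of the read's 5' end (for (-)-strand reads
    this is the higher coordinate of the match).  A read matching at m
    positions contributes its count at each of them, but enters
    ``total_mapped`` only once; consequently the RPM values sum to 1e6 only
    when every mapped read hits a single position (the usual case for
    amiRNA precursors).
    """

    reference_name: str
    hits: dict[tuple[int, int, str], int] = field(default_factory=dict)
    total_mapped: int = 0
    rpm: dict[tuple[int, int, str], float] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.total_mapped == 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reference": self.reference_name, "position": pos, "length": length,
             "strand": strand, "count": cnt, "rpm": self.rpm.get((pos, length, strand), 0.0)}
            for (pos, length, strand), cnt in sorted(self.hits.items())
        ]
        return pd.DataFrame(rows, columns=["reference", "position", "length", "strand", "count", "rpm"])


@dataclass
class ProcessingReport:
    """Processing accuracy of an amiRNA precursor from a mapping profile."""

    window_reads: int
    exact_guide_reads: int
    accuracy: float | None  # None when window_reads == 0 (flagged undefined)
    size_by_offset: pd.DataFrame

    @property
    def undefined(self) -> bool:
        return self.accuracy is None


@dataclass
class PhasingTable:
    """Proportion of 21-nt (+) reads in each of the 21 phasing registers."""

    registers: np.ndarray  # shape (21,), index 0 is register 1
    n_reads: int
    cleavage_site: int

    @property
    def empty(self) -> bool:
        return self.n_reads == 0


# ---------------------------------------------------------------------------


def collapse_reads(raw_reads: Iterable[str]) -> list[ReadRecord]:
    """Collapse identical reads into unique sequences with counts.

    Non-nucleotide records are rejected (their total is logged, never raised).
    Output is sorted by descending count, then lexicographically.
    """
    counter: Counter[str] = Counter()
    rejected = 0
    for read in raw_reads:
        try:
            counter[as_dna(read)] += 1
        except ValidationError:
            rejected += 1
    if rejected:
        logger.warning("collapse_reads: rejected %d non-nucleotide reads", rejected)
    return [
        ReadRecord(seq, cnt)
        for seq, cnt in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def expand_reads(records: Iterable[ReadRecord]) -> list[str]:
    """Inverse of collapse_reads (for round-trip checks and FASTQ emission)."""
    out: list[str] = []
    for rec in records:
        out.extend([rec.sequence] * rec.count)
    return out


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All 0-based start offsets of exact, possibly overlapping matches."""
    out = []
    start = haystack.find(needle)
    while start >= 0:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def map_exact(
    reads: Iterable[ReadRecord],
    reference: str,
    reference_name: str = "reference",
    strands: str = "+",
) -> MappingProfile:
    """Exact, ungapped mapping of unique reads against a reference.

    ``strands`` is "+" (forward strand only, the default used for precursor
    processing analysis) or "both".  Every occurrence of a read is recorded
    at its 5'-end coordinate with the read's full count; the read's count
    enters ``total_mapped`` once regardless of how many positions it hits.
    RPM values are filled in by :func:`rpm_normalize`.
    """
    if strands not in ("+", "both"):
        raise ValidationError(f"strands must be '+' or 'both', got {strands!r}")
    ref = as_dna(reference)
    if not ref:
        raise ValidationError("reference must be non-empty")
    ref_rc = reverse_complement(ref)
    n = len(ref)

    profile = MappingProfile(reference_name=reference_name)
    for rec in reads:
        seq = rec.sequence
        L = len(seq)
        mapped = False
        for off in _occurrences(seq, ref):
            key = (off + 1, L, "+")
            profile.hits[key] = profile.hits.get(key, 0) + rec.count
            mapped = True
        if strands == "both":
            for off in _occurrences(seq, ref_rc):
                # 5' end of a (-) read sits at the higher reference coordinate
                pos = n - off
                key = (pos, L, "-")
                profile.hits[key] = profile.hits.get(key, 0) + rec.count
                mapped = True
        if mapped:
            profile.total_mapped += rec.count
    return rpm_normalize(profile)


def rpm_normalize(profile: MappingProfile) -> MappingProfile:
    """Fill reads-per-million-mapped values: rpm = count / total_mapped * 1e6.

    An empty profile (nothing mapped) gets all-zero RPM and keeps its
    ``empty`` flag set; it is not an error.
    """
    if profile.total_mapped == 0:
        profile.rpm = {key: 0.0 for key in profile.hits}
        return profile
    scale = 1_000_000 / profile.total_mapped
    profile.rpm = {key: cnt * scale for key, cnt in profile.hits.items()}
    return profile


def processing_accuracy(profile: MappingProfile, precursor: Precursor) -> ProcessingReport:
    """Fraction of window reads that are the authentic 21-nt mature amiRNA.

    Denominator: counts of (+) hits with length 19-24 nt whose 5' end lies in
    [guide_start - 4, guide_start + 4].  Numerator: counts at exactly
    (guide_start, 21, +) -- under exact ungapped mapping such reads are
    necessarily identical to the mature guide, which is asserted explicitly.
    Accuracy is flagged undefined (None) when the denominator is zero.
    """
    gs = precursor.guide_start
    if as_dna(precursor.sequence[gs - 1 : gs + 20]) != as_dna(precursor.guide):
        raise ValidationError("precursor guide_start does not address the mature guide")

    window = 0
    exact = 0
    rows = []
    for (pos, length, strand), cnt in profile.hits.items():
        if strand != "+" or not (MIN_SRNA_LEN <= length <= MAX_SRNA_LEN):
            continue
        offset = pos - gs
        if abs(offset) > ACCURACY_WINDOW:
            continue
        window += cnt
        rows.append({"offset": offset, "length": length, "count": cnt})
        if offset == 0 and length == 21:
            exact += cnt

    table = pd.DataFrame(rows, columns=["offset", "length", "count"])
    if not table.empty:
        table = table.sort_values(["offset", "length"]).reset_index(drop=True)
    accuracy = exact / window if window else None
    if accuracy is None:
        logger.warning("processing_accuracy: no 19-24 nt (+) reads in the +/-4 nt window")
    return ProcessingReport(
        window_reads=window,
        exact_guide_reads=exact,
        accuracy=accuracy,
        size_by_offset=table,
    )


def strand_polarity(
    reads: Iterable[ReadRecord], reference: str
) -> tuple[float | None, float | None]:
    """(+) and (-) fractions of mapped read counts against a reference.

    A read's count enters the (+) total if it matches the forward strand
    anywhere and the (-) total if it matches the reverse complement anywhere;
    a self-complementary read counts on both strands.  Fractions are taken
    over the summed strand totals, so they add to 1 whenever any read maps.
    Returns (None, None), flagged by logging, when nothing maps.
    """
    ref = as_dna(reference)
    ref_rc = reverse_complement(ref)
    plus = 0
    minus = 0
    for rec in reads:
        if rec.sequence in ref:
            plus += rec.count
        if rec.sequence in ref_rc:
            minus += rec.count
    total = plus + minus
    if total == 0:
        logger.warning("strand_polarity: no reads mapped to either strand")
        return (None, None)
    return (plus / total, minus / total)


def locate_cleavage_site(target: str, guide: GuideRNA) -> int:
    """1-based target coordinate of the last nucleotide 5' of the amiRNA cut.

    Plant AGO1-loaded miRNAs cleave their target between the nucleotides
    opposite guide positions 10 and 11.  The target must contain exactly one
    site perfectly complementary to the guide (a reverse-complement match);
    for a site starting at target position p the cut leaves p+10 as the last
    base of the 5' fragment.
    """
    tgt = as_dna(target)
    site = as_dna(reverse_complement(guide.sequence))
    offs = _occurrences(site, tgt)
    if len(offs) != 1:
        raise ValidationError(
            f"target must contain exactly one perfectly complementary site for "
            f"guide {guide.name!r}; found {len(offs)}"
        )
    return offs[0] + 1 + 10


def phasing_registers(
    reads: Iterable[ReadRecord], target: str, cleavage_site: int
) -> PhasingTable:
    """Proportion of 21-nt (+) reads in each of 21 registers past the cut.

    Only exact forward-strand 21-nt hits with 5' ends strictly downstream of
    the cleavage site are considered; the register of a read starting at
    position p is ((p - (cleavage_site + 1)) mod 21) + 1, so register 1 holds
    perfectly phased reads.  Proportions are over the considered counts; an
    all-zero table with n_reads = 0 is returned (and logged) when no read
    qualifies.
    """
    tgt = as_dna(target)
    if not (1 <= cleavage_site <= len(tgt) - PHASE):
        raise ValidationError(
            f"cleavage_site {cleavage_site} outside [1, {len(tgt) - PHASE}]"
        )
    counts = np.zeros(PHASE, dtype=float)
    n_reads = 0
    profile = map_exact(reads, tgt, strands="+")
    for (pos, length, strand), cnt in profile.hits.items():
        if length != PHASE or strand != "+" or pos <= cleavage_site:
            continue
        register = (pos - (cleavage_site + 1)) % PHASE  # 0-based
        counts[register] += cnt
        n_reads += cnt
    if n_reads == 0:
        logger.warning("phasing_registers: no qualifying 21-nt (+) reads downstream of the cut")
        return PhasingTable(registers=counts, n_reads=0, cleavage_site=cleavage_site)
    return PhasingTable(registers=counts / n_reads, n_reads=n_reads, cleavage_site=cleavage_site)
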