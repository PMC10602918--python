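"""Synthetic sRNA read simulation with controlled processing fidelity.

The deposited sequencing libraries behind the published processing-accuracy,
strand-polarity and phasing observations are not needed to exercise this
package: this module generates collapsed read sets with known generating
parameters (exact-processing fraction, 5'-offset and size spectra, strand
bias, phased fraction), so every metric in :mod:`amirnakit.srnametrics` can
be checked for parameter recovery at the configured depth.

Counts are drawn as multinomial allocations over the discrete outcome space
(not per-read streams) for speed; all randomness flows through a single
seeded NumPy generator, so identical seed + config give identical read sets.

The default offset distribution (symmetric triangular on -4..+4 excluding 0)
and size distribution (peaked at 21 nt, with minor 19/20/22/23 classes and a
24-nt class emulating transgene-derived sRNAs) are plausible placeholders
for real Dicer-like imprecision spectra, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import Precursor, ValidationError, as_dna
from .srnametrics import ReadRecord, reverse_complement

MAX_REDRAWS = 100
MIN_GENOME_LEN = 24  # longest simulated sRNA class must fit


def _default_offsets() -> dict[int, float]:
    weights = {o: 5 - abs(o) for o in range(-4, 5) if o != 0}
    total = sum(weights.values())
    return {o: w / total for o, w in weights.items()}


def _default_sizes() -> dict[int, float]:
    return {19: 0.03, 20: 0.12, 21: 0.60, 22: 0.12, 23: 0.03, 24: 0.10}


@dataclass
class SimConfig:
    """Generating parameters for synthetic sRNA read sets.

    exact_fraction   probability a guide-arm read is the exact mature amiRNA
    guide_star_ratio fraction of duplex-derived reads from the guide arm
                     (the remainder are exact 21-nt star reads)
    strand_bias      (+)-strand probability for viral-genome simulation
    phased_fraction  fraction of target-derived 21-nt reads in register 1
    """

    seed: int = 0
    depth: int = 100_000
    exact_fraction: float = 0.95
    offset_distribution: Mapping[int, float] = field(default_factory=_default_offsets)
    size_distribution: Mapping[int, float] = field(default_factory=_default_sizes)
    guide_star_ratio: float = 0.9
    strand_bias: float = 0.5
    phased_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("exact_fraction", "guide_star_ratio", "strand_bias", "phased_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 0:
            raise ValidationError("depth must be non-negative")
        for dist, name in ((self.offset_distribution, "offset_distribution"),
                           (self.size_distribution, "size_distribution")):
            total = float(sum(dist.values()))
            if not np.isclose(total, 1.0):
                raise ValidationError(f"{name} must sum to 1, sums to {total}")
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"{name} has negative probabilities")
        if 0 in self.offset_distribution and self.offset_distribution[0] > 0:
            raise ValidationError("offset_distribution must exclude offset 0 (that is the exact class)")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "depth": self.depth,
            "exact_fraction": self.exact_fraction,
            "offset_distribution": {str(k): v for k, v in self.offset_distribution.items()},
            "size_distribution": {str(k): v for k, v in self.size_distribution.items()},
            "guide_star_ratio": self.guide_star_ratio,
            "strand_bias": self.strand_bias,
            "phased_fraction": self.phased_fraction,
        }


def _records(counter: Mapping[str, int]) -> list[ReadRecord]:
    return [
        ReadRecord(seq, int(cnt))
        for seq, cnt in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        if cnt > 0
    ]


def simulate_precursor_reads(precursor: Precursor, cfg: SimConfig) -> list[ReadRecord]:
    """Simulate (+)-strand reads from a precursor with known accuracy.

    Each read is star-arm with probability (1 - guide_star_ratio) (an exact
    21-nt star read, which falls outside the guide accuracy window);
    otherwise it is guide-arm: the exact mature guide with probability
    exact_fraction, else a mis-processed read whose 5' offset (in -4..+4,
    never 0) and length (19-24 nt) are drawn from the configured
    distributions.  All reads are exact substrings of the precursor (+)
    strand; out-of-bounds offset/length cells are redrawn, with a failure
    after 100 rounds if no probability mass is feasible.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = as_dna(precursor.sequence)
    gs = precursor.guide_start
    ss = precursor.star_start
    n = len(seq)

    cells: list[tuple[str, float]] = []
    star_read = seq[ss - 1 : ss + 20]
    exact_read = seq[gs - 1 : gs + 20]
    p_star = 1.0 - cfg.guide_star_ratio
    p_guide = cfg.guide_star_ratio
    cells.append((star_read, p_star))
    cells.append((exact_read, p_guide * cfg.exact_fraction))

    offcells: list[tuple[str | None, float]] = []
    for off, p_off in sorted(cfg.offset_distribution.items()):
        for length, p_len in sorted(cfg.size_distribution.items()):
            start = gs - 1 + off
            read = seq[start : start + length] if 0 <= start and start + length <= n else None
            offcells.append((read, p_guide * (1.0 - cfg.exact_fraction) * p_off * p_len))

    probs = np.array([p for _, p in cells] + [p for _, p in offcells])
    reads = [r for r, _ in cells] + [r for r, _ in offcells]
    counts = rng.multinomial(cfg.depth, probs / probs.sum()) if cfg.depth else np.zeros(len(probs), int)

    # redraw reads that landed in infeasible (out-of-bounds) cells
    feasible = np.array([r is not None for r in reads])
    for _ in range(MAX_REDRAWS):
        bad = int(counts[~feasible].sum())
        if bad == 0:
            break
        if not feasible.any() or probs[feasible].sum() == 0:
            raise ValidationError("no feasible read cell for this precursor/config")
        counts[~feasible] = 0
        p = np.where(feasible, probs, 0.0)
        counts = counts + rng.multinomial(bad, p / p.sum())
    else:
        raise ValidationError("failed to place simulated reads after 100 redraws")

    out: dict[str, int] = {}
    for read, cnt in zip(reads, counts):
        if cnt and read is not None:
            out[read] = out.get(read, 0) + int(cnt)
    return _records(out)


def simulate_viral_sirnas(genome: str, cfg: SimConfig) -> list[ReadRecord]:
    """Simulate 19-24 nt siRNAs sampled uniformly along a viral genome.

    Strand is (+) with probability ``strand_bias``; a bias of 0.5 emulates
    siRNAs diced from double-stranded replication intermediates, a strong
    (+) skew emulates hairpin/subgenomic-RNA-derived reads.  (-)-strand
    reads are reverse complements of genome windows.
    """
    g = as_dna(genome)
    if len(g) < MIN_GENOME_LEN:
        raise ValidationError(f"genome must be at least {MIN_GENOME_LEN} nt")
    rng = np.random.default_rng(cfg.seed)

    sizes = sorted(cfg.size_distribution.items())
    size_probs = np.array([p for _, p in sizes])
    length_counts = rng.multinomial(cfg.depth, size_probs / size_probs.sum())
    out: dict[str, int] = {}
    for (length, _), n_len in zip(sizes, length_counts):
        if n_len == 0:
            continue
        n_plus = rng.binomial(n_len, cfg.strand_bias)
        for strand, n_reads in (("+", n_plus), ("-", n_len - n_plus)):
            if n_reads == 0:
                continue
            starts = rng.integers(0, len(g) - length + 1, size=n_reads)
            for start, cnt in zip(*np.unique(starts, return_counts=True)):
                window = g[start : start + length]
                read = window if strand == "+" else reverse_complement(window)
                out[read] = out.get(read, 0) + int(cnt)
    return _records(out)


def simulate_phased_reads(target: str, cleavage_site: int, cfg: SimConfig) -> list[ReadRecord]:
    """Simulate 21-nt (+) reads downstream of a cleavage site.

    A ``phased_fraction`` of reads start exactly at cleavage_site + 1 + 21k
    (register 1); the remainder start uniformly at any position downstream of
    the cut that leaves a full 21-mer.
    """
    t = as_dna(target)
    if not (1 <= cleavage_site <= len(t) - 21):
        raise ValidationError(f"cleavage_site {cleavage_site} invalid for target of length {len(t)}")
    rng = np.random.default_rng(cfg.seed)

    first = cleavage_site + 1
    last = len(t) - 20  # last valid 1-based start
    phased_starts = np.arange(first, last + 1, 21)
    all_starts = np.arange(first, last + 1)

    n_phased = rng.binomial(cfg.depth, cfg.phased_fraction)
    out: dict[str, int] = {}
    for pool, n_reads in ((phased_starts, n_phased), (all_starts, cfg.depth - n_phased)):
        if n_reads == 0:
            continue
        picks = pool[rng.integers(0, len(pool), size=n_reads)]
        for start, cnt in zip(*np.unique(picks, return_counts=True)):
            read = t[start - 1 : start + 20]
            out[read] = out.get(read, 0) + int(cnt)
    return _records(out)
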