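"""Hairpin validation and base-pair-maximization folding.

A well-formed MIR390-based amiRNA precursor folds into a basal stem
(~15-17 bp), a guide/star duplex and a distal stem-loop.  ``pair_by_layout``
verifies the backbone-declared pairing against the assembled sequence and
reports a dot-bracket structure; ``fold_nussinov`` provides an independent,
layout-agnostic structural cross-check via classical base-pair maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design import Precursor, SEGMENT_ROLES, declared_pairs, is_complementary


@dataclass
class StructureReport:
    """Result of checking a precursor against its declared pairing layout."""

    dotbracket: str
    basal_stem_bp: int
    duplex_paired: int
    dsl_stem_bp: int
    loop_length: int
    violations: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def pair_by_layout(precursor: Precursor, allow_gu: bool = True) -> StructureReport:
    """Pair positions per the backbone layout and verify complementarity.

    Declared pairs (basal stem arms, guide/star duplex per template, DSL stem,
    compensation and star-overhang pairs) must be Watson-Crick or, when
    ``allow_gu``, G:U complementary.  Violations are listed as
    ``(position, expected, found)`` and never silently fixed.  Declared
    duplex mismatches are expected to NOT pair and are reported if they do.
    """
    missing = [r for r in SEGMENT_ROLES if r not in precursor.segment_map]
    if missing:
        raise KeyError(f"precursor segment_map missing roles: {missing}")

    lengths = {
        role: max(0, end - start + 1)
        for role, (start, end) in precursor.segment_map.items()
    }
    seq = precursor.sequence
    pairs = declared_pairs(lengths, precursor.duplex_template)

    brackets = ["."] * len(seq)
    violations: list[tuple[int, str, str]] = []
    counts = {"bs": 0, "star_tail": 0, "duplex": 0, "dsl": 0, "comp": 0}

    for i, j, kind in pairs:
        a, b = seq[i - 1], seq[j - 1]
        if kind == "mismatch":
            if is_complementary(a, b, allow_gu):
                violations.append((i, f"declared mismatch with {j}", f"{a}:{b} pairs"))
            continue
        if is_complementary(a, b, allow_gu):
            brackets[i - 1] = "("
            brackets[j - 1] = ")"
            counts[kind] += 1
        else:
            violations.append((i, f"pair with {j}", f"{a}:{b} not complementary"))

    return StructureReport(
        dotbracket="".join(brackets),
        basal_stem_bp=counts["bs"] + counts["star_tail"],
        duplex_paired=counts["duplex"],
        dsl_stem_bp=counts["dsl"] + counts["comp"],
        loop_length=lengths["loop"],
        violations=violations,
    )


def fold_nussinov(sequence: str, min_loop: int = 3, allow_gu: bool = True) -> str:
    """Maximum-base-pair secondary structure (dot-bracket, Vienna convention).

    Classical base-pair maximization with a minimum hairpin loop of
    ``min_loop`` unpaired bases and G:U wobble allowed by default.  The
    traceback is a deterministic left-to-right scan preferring the leftmost
    pairing partner, so identical inputs always give identical structures.
    No pseudoknots, no thermodynamics; intended as a structural cross-check,
    not an MFE prediction.
    """
    seq = sequence.strip().upper().replace("T", "U")
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence length {n} < min_loop + 2 = {min_loop + 2}")

    can = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            can[i][j] = is_complementary(seq[i], seq[j], allow_gu)

    # M[i][j] = max pairs in seq[i..j]; recursion on the last position j:
    # either j unpaired, or j pairs some k in [i, j-min_loop-1].
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i][j - 1]
            for k in range(i, j - min_loop):
                if can[k][j]:
                    left = M[i][k - 1] if k > i else 0
                    inner = M[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + 1 + inner
                    if cand > best:  # strict '>' keeps the leftmost partner on ties
                        best = cand
            M[i][j] = best

    brackets = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_loop + 1:
            continue
        if M[i][j] == M[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if can[k][j]:
                left = M[i][k - 1] if k > i else 0
                inner = M[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + 1 + inner == M[i][j]:
                    brackets[k] = "("
                    brackets[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return "".join(brackets)


def count_pairs(dotbracket: str) -> int:
    """Number of base pairs in a dot-bracket string (must be balanced)."""
    depth = 0
    pairs = 0
    for ch in dotbracket:
        if ch == "(":
            depth += 1
            pairs += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket string")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket string")
    return pairs
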