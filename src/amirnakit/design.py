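"""Backbone registry and assembly of MIR390-based amiRNA precursors.

Plant artificial microRNAs (amiRNAs) are 21-nt small RNAs expressed from an
engineered miRNA precursor in which the native miRNA/miRNA* duplex is replaced
by the amiRNA/amiRNA* duplex.  This module holds the registry of precursor
*backbones* -- the AtMIR390a-derived full-length (``pri``, 521 nt) and
basal-stem-only (``BS``, with no flanking ssRNA segments) architectures, the
OsMIR390-derived distal stem-loops, the deletion (``Δ``) series, and the 89-nt
shortened chimeric ``shc`` precursor -- and the operations that assemble a
precursor, its star (passenger) strand, and the annealed cloning
oligonucleotides for the BsaI-based "B/c" vectors.

Every backbone is described by nine ordered segments::

    flank5  bs5_arm  guide_slot  dsl5_arm  loop  dsl3_arm  star_slot  bs3_arm  flank3

with the basal stem (BS) pairing bs5_arm/bs3_arm, the 21/21 guide/star duplex
in the middle, and the distal stem-loop (DSL) above it.  The duplex carries
2-nt 3' overhangs: guide positions 1-19 pair star positions 19-1 (with one
declared mismatch facing guide position 11, mirroring the miR390/miR390*
duplex), guide positions 20/21 pair the two duplex-proximal dsl3_arm bases --
the two per-amiRNA *compensation nucleotides* that are rewritten for each
guide to preserve the drawn secondary structure -- and star positions 20/21
pair the two duplex-proximal bs5_arm bases, which are backbone sequence and
hence fixed template data.

Coordinates are 1-based and inclusive throughout.  Sequences are accepted in
DNA or RNA alphabet, case-insensitive; precursors are handled in RNA space,
cloning oligos in DNA space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Alphabet helpers
# ---------------------------------------------------------------------------

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SEGMENT_ROLES = (
    "flank5",
    "bs5_arm",
    "guide_slot",
    "dsl5_arm",
    "loop",
    "dsl3_arm",
    "star_slot",
    "bs3_arm",
    "flank3",
)

GUIDE_LENGTH = 21
DUPLEX_LENGTH = 2 * GUIDE_LENGTH

BSAI_SITES = ("GGTCTC", "GAGACC")  # recognition site and its reverse complement


class ValidationError(ValueError):
    """Raised when an input sequence or spec violates a declared invariant."""


class BackboneLookupError(KeyError):
    """Raised for unknown backbone or vector names; lists registered names."""


def as_rna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case RNA (T -> U)."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValidationError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return s


def as_dna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case DNA (U -> T)."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValidationError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return s


def rna_complement(base: str) -> str:
    return base.translate(_RNA_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving the input alphabet (RNA or DNA)."""
    if "U" in seq.upper():
        return as_rna(seq).translate(_RNA_COMPLEMENT)[::-1]
    if "T" in seq.upper():
        return as_dna(seq).translate(_DNA_COMPLEMENT)[::-1]
    # ambiguous (no U/T): treat as RNA
    return seq.upper().translate(_RNA_COMPLEMENT)[::-1]


def is_complementary(a: str, b: str, allow_gu: bool = True) -> bool:
    """Watson-Crick (optionally G:U wobble) complementarity of two RNA bases."""
    pair = frozenset((a, b))
    if pair in (frozenset("AU"), frozenset("GC")):
        return True
    return allow_gu and pair == frozenset("GU")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuideRNA:
    """A 21-nt amiRNA guide strand (RNA alphabet, T normalized to U)."""

    sequence: str
    name: str = "amiRNA"

    def __post_init__(self) -> None:
        seq = as_rna(self.sequence)
        if len(seq) != GUIDE_LENGTH:
            raise ValidationError(
                f"guide {self.name!r} must be exactly {GUIDE_LENGTH} nt, got {len(seq)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class DuplexTemplate:
    """Declared pairing layout of the 21/21 guide/star duplex.

    ``pairs`` and ``mismatches`` are 1-based (guide_pos, star_pos) tuples;
    ``star_fill`` fixes star positions not determined by the guide (the 3'
    overhang bases, which face backbone sequence in the hairpin).
    """

    pairs: tuple[tuple[int, int], ...]
    mismatches: tuple[tuple[int, int], ...] = ()
    star_fill: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for g, s in tuple(self.pairs) + tuple(self.mismatches):
            if not (1 <= g <= GUIDE_LENGTH and 1 <= s <= GUIDE_LENGTH):
                raise ValidationError(f"template position ({g},{s}) outside 21/21 duplex")
            if s in covered:
                raise ValidationError(f"star position {s} declared twice in template")
            covered.add(s)
        for s in self.star_fill:
            if s in covered:
                raise ValidationError(f"star position {s} both paired and filled")
            covered.add(s)
        if covered != set(range(1, GUIDE_LENGTH + 1)):
            missing = sorted(set(range(1, GUIDE_LENGTH + 1)) - covered)
            raise ValidationError(f"template leaves star positions {missing} undefined")


#: Fully base-paired, blunt-ended 21/21 duplex (guide i pairs star 22-i).
ALL_PAIRED_TEMPLATE = DuplexTemplate(
    pairs=tuple((i, 22 - i) for i in range(1, 22)),
)


def mir390_template(bs5_arm: str) -> DuplexTemplate:
    """Default duplex template: 2-nt 3' overhangs and a mismatch at guide 11.

    Guide i pairs star (20-i) for i in 1..19 except the declared mismatch
    facing guide position 11 (star position 9).  Star 20/21 are the 3'
    overhang, fixed to pair the two duplex-proximal bases of the basal-stem
    5' arm they face in the hairpin.
    """
    arm = as_rna(bs5_arm) if bs5_arm else ""
    fill: dict[int, str] = {}
    fill[20] = rna_complement(arm[-1]) if len(arm) >= 1 else "U"
    fill[21] = rna_complement(arm[-2]) if len(arm) >= 2 else "U"
    return DuplexTemplate(
        pairs=tuple((i, 20 - i) for i in range(1, 20) if i != 11),
        mismatches=((11, 9),),
        star_fill=fill,
    )


@dataclass(frozen=True)
class BackboneSpec:
    """A named precursor architecture: ordered segments plus duplex template.

    ``guide_slot``/``star_slot`` hold 21-nt placeholder sequences (the native
    miR390a guide and its derived star) that are replaced on assembly.
    """

    name: str
    segments: tuple[tuple[str, str], ...]
    duplex_template: DuplexTemplate

    def __post_init__(self) -> None:
        roles = tuple(r for r, _ in self.segments)
        if roles != SEGMENT_ROLES:
            raise ValidationError(
                f"backbone {self.name!r}: segments must be the ordered roles {SEGMENT_ROLES}"
            )
        for role, seq in self.segments:
            if seq and seq != as_rna(seq):
                raise ValidationError(f"backbone {self.name!r}: segment {role} not RNA")
        if len(self.segment("guide_slot")) != GUIDE_LENGTH:
            raise ValidationError(f"backbone {self.name!r}: guide_slot must be 21 nt")
        if len(self.segment("star_slot")) != GUIDE_LENGTH:
            raise ValidationError(f"backbone {self.name!r}: star_slot must be 21 nt")

    def segment(self, role: str) -> str:
        for r, seq in self.segments:
            if r == role:
                return seq
        raise KeyError(role)

    @property
    def dsl_length(self) -> int:
        return sum(len(self.segment(r)) for r in ("dsl5_arm", "loop", "dsl3_arm"))

    @property
    def bs_region_length(self) -> int:
        return sum(len(self.segment(r)) for r in ("flank5", "bs5_arm", "bs3_arm", "flank3"))

    @property
    def bs_stem_length(self) -> int:
        return len(self.segment("bs5_arm")) + len(self.segment("bs3_arm"))

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.segments)


@dataclass(frozen=True)
class Precursor:
    """An assembled, annotated amiRNA precursor (RNA, 1-based coordinates)."""

    name: str
    sequence: str
    segment_map: Mapping[str, tuple[int, int]]  # role -> (start, end) inclusive; end < start marks empty
    guide_start: int
    star_start: int
    guide: str
    duplex_template: DuplexTemplate
    ambiguous_guide: bool = False  # guide occurs elsewhere in the precursor

    def __post_init__(self) -> None:
        g = self.guide_start
        if self.sequence[g - 1 : g + 20] != self.guide:
            raise ValidationError(f"precursor {self.name!r}: guide_start does not address the guide")
        pos = 1
        for role in SEGMENT_ROLES:
            start, end = self.segment_map[role]
            if end < start:  # empty segment
                if start != pos:
                    raise ValidationError(f"precursor {self.name!r}: segment map does not tile at {role}")
                continue
            if start != pos:
                raise ValidationError(f"precursor {self.name!r}: segment map does not tile at {role}")
            pos = end + 1
        if pos != len(self.sequence) + 1:
            raise ValidationError(f"precursor {self.name!r}: segment map does not cover the sequence")


@dataclass(frozen=True)
class OligoPair:
    """Two annealed cloning oligos with 4-base 5' overhangs for a B/c vector."""

    forward: str
    reverse: str
    overhang5: str
    overhang3: str
    vector: str
    ligation_ok: bool
    name: str = "amiRNA"


@dataclass(frozen=True)
class VectorSpec:
    """A BsaI-linearized B/c acceptor vector around a backbone's insert site.

    ``left_arm``/``right_arm`` are the sense-strand vector sequences flanking
    the excised stuffer; the fixed 4-base 5' overhangs exposed by BsaI
    digestion determine the oligo overhangs.
    """

    name: str
    backbone: str
    oligo_length: int
    left_arm: str  # DNA, ends at the left cut
    right_arm: str  # DNA, starts after the right cut
    overhang_left: str  # first 4 sense bases of the insert (pairs vector bottom overhang)
    overhang_right: str  # first 4 sense bases after the insert (vector top overhang)


# ---------------------------------------------------------------------------
# Declared pairing layout (shared with the structure module)
# ---------------------------------------------------------------------------


def declared_pairs(
    segment_lengths: Mapping[str, int], template: DuplexTemplate
) -> list[tuple[int, int, str]]:
    """Absolute 1-based position pairs implied by a backbone's layout.

    Returns (i, j, kind) with i < j and kind in {"duplex", "mismatch",
    "comp", "star_tail", "dsl", "bs"}.  "mismatch" entries are declared
    non-pairing duplex positions; every other entry must be Watson-Crick or
    G:U complementary in a well-formed precursor.

    The stems are anchored away from the duplex (DSL at the loop, BS at the
    base) so that the Δ-series deletions, taken from the duplex-proximal stem
    ends, preserve the parent pairing register.
    """
    f5 = segment_lengths["flank5"]
    b5 = segment_lengths["bs5_arm"]
    d5 = segment_lengths["dsl5_arm"]
    lp = segment_lengths["loop"]
    d3 = segment_lengths["dsl3_arm"]
    b3 = segment_lengths["bs3_arm"]

    g0 = f5 + b5  # offset of guide_slot
    dsl5_0 = g0 + GUIDE_LENGTH
    dsl3_0 = dsl5_0 + d5 + lp
    star0 = dsl3_0 + d3
    bs3_0 = star0 + GUIDE_LENGTH

    out: list[tuple[int, int, str]] = []
    for g, s in template.pairs:
        out.append((g0 + g, star0 + s, "duplex"))
    for g, s in template.mismatches:
        out.append((g0 + g, star0 + s, "mismatch"))
    # compensation nucleotides: guide 20/21 pair the duplex-proximal dsl3 bases
    if d3 >= 1:
        out.append((g0 + 20, dsl3_0 + d3, "comp"))
    if d3 >= 2:
        out.append((g0 + 21, dsl3_0 + d3 - 1, "comp"))
    # star 3' overhang pairs the duplex-proximal bs5 bases
    if b5 >= 1:
        out.append((f5 + b5, star0 + 20, "star_tail"))
    if b5 >= 2:
        out.append((f5 + b5 - 1, star0 + 21, "star_tail"))
    # DSL stem, anchored at the loop
    for s in range(1, min(d5, d3 - 2) + 1):
        out.append((dsl5_0 + d5 - s + 1, dsl3_0 + s, "dsl"))
    # basal stem, anchored at the base
    for u in range(1, min(b5 - 2, b3) + 1):
        out.append((f5 + u, bs3_0 + b3 - u + 1, "bs"))
    return [(min(i, j), max(i, j), kind) for i, j, kind in out]


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def _load_bundle() -> dict:
    with resources.files("amirnakit.data").joinpath("backbones_synthetic.yaml").open() as fh:
        return yaml.safe_load(fh)


def _compose(name: str, flank5: str, bs5: str, dsl5: str, loop: str, dsl3: str,
             bs3: str, flank3: str, native_guide: str) -> BackboneSpec:
    template = mir390_template(bs5)
    star = design_star(GuideRNA(native_guide, "native"), template)
    # placeholder compensation bases face the native guide
    dsl3 = list(dsl3)
    if len(dsl3) >= 1:
        dsl3[-1] = rna_complement(native_guide[19])
    if len(dsl3) >= 2:
        dsl3[-2] = rna_complement(native_guide[20])
    segments = (
        ("flank5", flank5),
        ("bs5_arm", bs5),
        ("guide_slot", native_guide),
        ("dsl5_arm", dsl5),
        ("loop", loop),
        ("dsl3_arm", "".join(dsl3)),
        ("star_slot", star),
        ("bs3_arm", bs3),
        ("flank3", flank3),
    )
    return BackboneSpec(name=name, segments=segments, duplex_template=template)


def _delete_stem(arm5: str, arm3: str, k: int, proximal_end_of_5: str) -> tuple[str, str]:
    """Remove k nt symmetrically from the duplex-proximal ends of a stem.

    The odd leftover is taken from the longer arm.  ``proximal_end_of_5`` is
    "start" for the DSL stem (dsl5 begins at the duplex) and "end" for the
    basal stem (bs5 ends at the duplex).
    """
    if k > len(arm5) + len(arm3):
        raise ValidationError(f"cannot delete {k} nt from a {len(arm5)}+{len(arm3)} stem")
    half, extra = divmod(k, 2)
    if len(arm3) >= len(arm5):
        k5, k3 = half, half + extra
    else:
        k5, k3 = half + extra, half
    if proximal_end_of_5 == "start":
        return arm5[k5:], arm3[: len(arm3) - k3] if k3 else arm3
    return arm5[: len(arm5) - k5] if k5 else arm5, arm3[k3:]


_EXPECTED_DSL = {
    "pri": 31, "AtDSL-D6": 25, "AtDSL-D13": 18, "AtDSL-D21": 10, "AtDSL-D25": 6,
    "OsDSL": 16, "OsDSL-D2": 14, "OsDSL-D4": 12, "OsDSL-D6": 10, "OsDS-AtL": 12,
    "BS": 31, "BS-D7": 31, "BS-D17": 31, "BS-D23": 31, "BS-D31": 31, "shc": 14,
}
_EXPECTED_TOTAL = {"pri": 521, "shc": 89, "BS": 106}
_EXPECTED_BS_STEM = {
    "BS": 33, "BS-D7": 26, "BS-D17": 16, "BS-D23": 10, "BS-D31": 2, "shc": 33, "pri": 33,
}


def _build_registry() -> dict[str, BackboneSpec]:
    b = _load_bundle()
    seg = {k: as_rna(v) for k, v in b["segments"].items()}
    guide = as_rna(b["native_guide"])
    at = dict(flank5=seg["at_flank5"], bs5=seg["at_bs5"], bs3=seg["at_bs3"],
              flank3=seg["at_flank3"], native_guide=guide)
    no_flank = dict(at, flank5="", flank3="")
    at_dsl = (seg["at_dsl5"], seg["at_loop"], seg["at_dsl3"])
    os_dsl = (seg["os_dsl5"], seg["os_loop"], seg["os_dsl3"])

    reg: dict[str, BackboneSpec] = {}

    def add(name: str, base: dict, dsl: tuple[str, str, str], dsl_del: int = 0, bs_del: int = 0):
        d5, lp, d3 = dsl
        if dsl_del:
            d5, d3 = _delete_stem(d5, d3, dsl_del, "start")
        bs5, bs3 = base["bs5"], base["bs3"]
        if bs_del:
            bs5, bs3 = _delete_stem(bs5, bs3, bs_del, "end")
        reg[name] = _compose(name, base["flank5"], bs5, d5, lp, d3, bs3,
                             base["flank3"], base["native_guide"])

    add("pri", at, at_dsl)
    for k in (6, 13, 21, 25):
        add(f"AtDSL-D{k}", at, at_dsl, dsl_del=k)
    add("OsDSL", at, os_dsl)
    for k in (2, 4, 6):
        add(f"OsDSL-D{k}", at, os_dsl, dsl_del=k)
    add("OsDS-AtL", at, (seg["os_dsl5"], seg["at_loop"], seg["os_dsl3"]))
    add("BS", no_flank, at_dsl)
    for k in (7, 17, 23, 31):
        add(f"BS-D{k}", no_flank, at_dsl, bs_del=k)
    add("shc", no_flank, os_dsl, dsl_del=2)

    # fail fast on a mistyped bundle: every printed length must hold
    for name, spec in reg.items():
        if spec.dsl_length != _EXPECTED_DSL[name]:
            raise ValidationError(f"bundle error: {name} DSL length {spec.dsl_length} != {_EXPECTED_DSL[name]}")
        if name in _EXPECTED_TOTAL and spec.total_length != _EXPECTED_TOTAL[name]:
            raise ValidationError(f"bundle error: {name} total {spec.total_length} != {_EXPECTED_TOTAL[name]}")
        if name in _EXPECTED_BS_STEM and spec.bs_stem_length != _EXPECTED_BS_STEM[name]:
            raise ValidationError(f"bundle error: {name} basal stem {spec.bs_stem_length} != {_EXPECTED_BS_STEM[name]}")
        if spec.total_length != spec.bs_region_length + DUPLEX_LENGTH + spec.dsl_length:
            raise ValidationError(f"bundle error: {name} length arithmetic broken")
    if reg["pri"].bs_region_length != 448:
        raise ValidationError("bundle error: pri basal region must be 448 nt")
    return reg


_REGISTRY: dict[str, BackboneSpec] | None = None


def _registry() -> dict[str, BackboneSpec]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _build_registry()
    return _REGISTRY


def _canonical_name(name: str) -> str:
    return name.replace("Δ", "D").strip()


def list_backbones() -> list[str]:
    """Names of all registered precursor backbones."""
    return sorted(_registry())


def get_backbone(name: str) -> BackboneSpec:
    """Look up a registered backbone by name (Δ and D spellings accepted)."""
    reg = _registry()
    canon = _canonical_name(name)
    for key in reg:
        if key.lower() == canon.lower():
            return reg[key]
    raise BackboneLookupError(
        f"unknown backbone {name!r}; registered backbones: {', '.join(sorted(reg))}"
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def design_star(guide: GuideRNA, template: DuplexTemplate) -> str:
    """Design the 21-nt star (passenger) strand for a guide under a template.

    The star is the reverse-complement partner of the guide at every
    template-paired position, deviates at declared mismatch positions (the
    star base is set equal to the facing guide base, which can never pair),
    and takes fixed template bases at the unpaired 3'-overhang positions.
    Deterministic for a fixed template.
    """
    star = [""] * GUIDE_LENGTH
    for g, s in template.pairs:
        star[s - 1] = rna_complement(guide.sequence[g - 1])
    for g, s in template.mismatches:
        star[s - 1] = guide.sequence[g - 1]
    for s, base in template.star_fill.items():
        star[s - 1] = as_rna(base)
    return "".join(star)


def build_precursor(guide: GuideRNA, backbone: BackboneSpec) -> Precursor:
    """Assemble a precursor: slot in guide and star, rewrite compensation bases.

    The two compensation nucleotides (the duplex-proximal dsl3_arm bases that
    face guide positions 20/21 in the hairpin) are set to the Watson-Crick
    complements of the guide bases they face, preserving the backbone's
    secondary structure for any guide.
    """
    star = design_star(guide, backbone.duplex_template)
    parts: list[tuple[str, str]] = []
    for role, seq in backbone.segments:
        if role == "guide_slot":
            seq = guide.sequence
        elif role == "star_slot":
            seq = star
        elif role == "dsl3_arm" and seq:
            comp = list(seq)
            comp[-1] = rna_complement(guide.sequence[19])
            if len(comp) >= 2:
                comp[-2] = rna_complement(guide.sequence[20])
            seq = "".join(comp)
        parts.append((role, seq))

    sequence = "".join(seq for _, seq in parts)
    segment_map: dict[str, tuple[int, int]] = {}
    pos = 1
    for role, seq in parts:
        segment_map[role] = (pos, pos + len(seq) - 1)
        pos += len(seq)
    guide_start = segment_map["guide_slot"][0]
    star_start = segment_map["star_slot"][0]

    ambiguous = sequence.count(guide.sequence) > 1
    if ambiguous:
        logger.warning(
            "guide %s occurs more than once in the %s precursor; downstream "
            "read mapping will be ambiguous", guide.name, backbone.name,
        )
    prec = Precursor(
        name=f"{backbone.name}-{guide.name}",
        sequence=sequence,
        segment_map=segment_map,
        guide_start=guide_start,
        star_start=star_start,
        guide=guide.sequence,
        duplex_template=backbone.duplex_template,
        ambiguous_guide=ambiguous,
    )
    expected = backbone.bs_region_length + DUPLEX_LENGTH + backbone.dsl_length
    if len(sequence) != expected:
        raise ValidationError(f"assembled {prec.name} length {len(sequence)} != declared {expected}")
    return prec


# --- cloning oligos ---------------------------------------------------------


def _vector_registry() -> dict[str, VectorSpec]:
    b = _load_bundle()
    vectors: dict[str, VectorSpec] = {}
    for name, cfg in b["vectors"].items():
        backbone = get_backbone(cfg["backbone"])
        f5 = backbone.segment("flank5")
        bs5 = backbone.segment("bs5_arm")
        bs3 = backbone.segment("bs3_arm")
        f3 = backbone.segment("flank3")
        star_tail = backbone.segment("star_slot")[19:21]
        left_arm = as_dna(f5 + bs5[:-4])
        right_arm = as_dna(star_tail + bs3 + f3)
        vectors[name] = VectorSpec(
            name=name,
            backbone=cfg["backbone"],
            oligo_length=int(cfg["oligo_length"]),
            left_arm=left_arm,
            right_arm=right_arm,
            overhang_left=as_dna(bs5[-4:]),
            overhang_right=as_dna(star_tail + bs3[:2]),
        )
    return vectors


_VECTORS: dict[str, VectorSpec] | None = None


def get_vector(name: str) -> VectorSpec:
    """Look up a B/c cloning vector spec by name."""
    global _VECTORS
    if _VECTORS is None:
        _VECTORS = _vector_registry()
    for key, spec in _VECTORS.items():
        if key.lower() == name.strip().lower():
            return spec
    raise BackboneLookupError(
        f"unknown vector {name!r}; registered vectors: {', '.join(sorted(_VECTORS))}"
    )


def list_vectors() -> list[str]:
    global _VECTORS
    if _VECTORS is None:
        _VECTORS = _vector_registry()
    return sorted(_VECTORS)


class BsaISiteError(ValidationError):
    """The designed insert contains an internal BsaI site (GGTCTC/GAGACC)."""


def design_oligos(guide: GuideRNA, vector: str | VectorSpec) -> OligoPair:
    """Design the two annealed cloning oligos for a guide and a B/c vector.

    The annealed duplex carries two 4-base 5' overhangs complementary to the
    BsaI-exposed vector overhangs.  The forward (sense) oligo spans the last
    four basal-stem 5'-arm bases, the guide, the complete DSL (with the two
    compensation nucleotides already adjusted) and the first 19 star bases;
    the star's last two bases and the first two basal-stem 3'-arm bases are
    vector-encoded.  This yields 75-base oligos for AtMIR390a-B/c (31-nt DSL)
    and 58-base oligos for BS-AtMIR390a-B/c (14-nt DSL).  An in-silico
    ligation into the vector is performed and must reconstruct the precursor
    exactly; the result is recorded on the returned pair.
    """
    vec = vector if isinstance(vector, VectorSpec) else get_vector(vector)
    backbone = get_backbone(vec.backbone)
    prec = build_precursor(guide, backbone)
    dna = as_dna(prec.sequence)
    gs, ss = prec.guide_start, prec.star_start

    forward = dna[gs - 5 : ss + 18]  # bs5[-4:] + guide + DSL + star[:19]
    reverse = reverse_complement(dna[gs - 1 : ss + 22])  # guide + DSL + star + bs3[:2]

    for site in BSAI_SITES:
        idx = forward.find(site)
        if idx >= 0:
            raise BsaISiteError(
                f"guide {guide.name!r} creates an internal BsaI site ({site}) at "
                f"insert position {idx + 1}; it would be destroyed on digestion"
            )
    if len(forward) != vec.oligo_length or len(reverse) != vec.oligo_length:
        raise ValidationError(
            f"oligo length {len(forward)}/{len(reverse)} != declared {vec.oligo_length} for {vec.name}"
        )

    pair = OligoPair(
        forward=forward,
        reverse=reverse,
        overhang5=forward[:4],
        overhang3=reverse[:4],
        vector=vec.name,
        ligation_ok=False,
        name=guide.name,
    )
    ligated = ligate(pair, vec)
    ok = ligated is not None and as_dna(prec.sequence) in ligated
    return OligoPair(**{**pair.__dict__, "ligation_ok": ok})


def ligate(pair: OligoPair, vector: str | VectorSpec) -> str | None:
    """In-silico ligation of an annealed oligo pair into a BsaI-cut vector.

    Checks overhang compatibility with the vector and internal annealing of
    the two oligos; returns the reconstructed sense strand across the insert,
    or None if the junctions are incompatible.
    """
    vec = vector if isinstance(vector, VectorSpec) else get_vector(vector)
    if pair.forward[:4] != vec.overhang_left:
        return None
    if pair.reverse[:4] != reverse_complement(vec.overhang_right):
        return None
    # the oligos must anneal over their shared region
    top_core = pair.forward[4:]
    bottom_core = reverse_complement(pair.reverse)[: len(pair.reverse) - 4]
    if top_core != bottom_core[: len(top_core)]:
        return None
    return vec.left_arm + pair.forward + vec.right_arm


def extract_fragment(reference: str, start: int, end: int, orientation: str = "forward") -> str:
    """Inclusive 1-based subsequence, reverse-complemented when orientation='reverse'."""
    if orientation not in ("forward", "reverse"):
        raise ValidationError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    if not (1 <= start <= end <= len(reference)):
        raise ValidationError(
            f"coordinates {start}..{end} out of range for reference of length {len(reference)}"
        )
    frag = reference[start - 1 : end]
    return reverse_complement(frag) if orientation == "reverse" else frag
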