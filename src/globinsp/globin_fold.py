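"""Myoglobin-fold validation and helix-relative intron position naming.

All single-domain globins share the 3/3 alpha-helical myoglobin fold: a
pattern of predominantly hydrophobic residues at ~36 conserved,
solvent-inaccessible positions on helices A through H (named helix letter +
index within helix, e.g. G5, plus the inter-helical CD1 and FG4), and an
invariant proximal histidine at F8 that ligates the heme iron. A candidate
sequence aligned to an annotated reference (sperm whale myoglobin by
default) is checked for: the F8 His, coverage of the helices that form the
heme pocket core (B, C, E, F, G — helix D is genuinely absent in some true
globins and is not required), and, optionally, a minimum hydrophobic
fraction at the template positions. An externally computed
structure-profile compatibility Z-score may be supplied as metadata and is
then additionally required to exceed 6.

Intron positions given as nucleotide offsets into a coding sequence are
mapped to the field's helix-relative notation: B12.2 denotes an intron
between positions 2 and 3 of the codon of helix-B residue 12, G7.0 one
falling exactly between the codons of helix-G residues 6 and 7.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .io_formats import AA_WITH_X, GAP, SequenceRecord, StructAlignment

INTRA_HELICES = "ABCDEFGH"
INTER_SEGMENTS = ("CD", "EF", "FG", "GH")

METHODS_POSITIONS = (
    "A8", "A11", "A12", "A15",
    "B6", "B9", "B10", "B13", "B14",
    "C4", "CD1",
    "E4", "E7", "E8", "E11", "E12", "E15", "E18", "E19",
    "F1", "F4", "F8", "FG4",
    "G5", "G8", "G11", "G12", "G13", "G15", "G16",
    "H7", "H8", "H11", "H12", "H15", "H19",
)

S1FIG_POSITIONS = (
    "A8", "A11", "A12", "A15",
    "B6", "B9", "B10", "B13", "B14",
    "C5", "CD1", "CD4",
    "E4", "E7", "E8", "E11", "E12", "E15", "E18", "E19",
    "F1", "F4", "F8", "FG4",
    "G5", "G8", "G11", "G12", "G13", "G15", "G16",
    "H7", "H8", "H11", "H12", "H15", "H19",
)

DEFAULT_HYDROPHOBIC = frozenset("ACFILMVWY")
REQUIRED_HELICES = frozenset("BCEFG")


def _split_label(label: str) -> tuple[str, int]:
    """'B12' -> ('B', 12); 'CD1' -> ('CD', 1)."""
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    helix, idx = label[:i], label[i:]
    if not helix or not idx.isdigit():
        raise ValueError(f"malformed helix-position label: {label!r}")
    return helix, int(idx)


@dataclass(eq=False)
class MbFoldTemplate:
    """The ordered helix-position labels defining the fold check."""

    positions: tuple[str, ...] = METHODS_POSITIONS
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC
    min_hydrophobic_fraction: float = 0.70

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("template labels must be unique")
        if sum(1 for p in self.positions if p == "F8") != 1:
            raise ValueError("template must contain F8 exactly once")
        for label in self.positions:
            _split_label(label)

    @classmethod
    def default(cls, variant: str = "methods") -> "MbFoldTemplate":
        if variant == "methods":
            return cls(METHODS_POSITIONS)
        if variant == "s1fig":
            return cls(S1FIG_POSITIONS)
        raise ValueError(f"unknown template variant: {variant!r}")


@dataclass(eq=False)
class HelixAnnotation:
    """Helix-relative labels for every residue of a reference sequence.

    ``helices`` maps segment name (A–H and the inter-helical corners CD, EF,
    FG, GH) to inclusive 1-based (start, end) residue numbers on the
    reference.
    """

    reference_id: str
    length: int
    helices: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (start, end) in self.helices.items():
            if not 1 <= start <= end <= self.length:
                raise ValueError(f"segment {name} bounds outside reference")

    def label_of(self, ordinal: int) -> str | None:
        """Helix-relative label for a 0-based reference residue ordinal."""
        number = ordinal + 1
        for name, (start, end) in self.helices.items():
            if start <= number <= end:
                return f"{name}{number - start + 1}"
        return None

    def region_of(self, ordinal: int) -> str:
        label = self.label_of(ordinal)
        if label is not None:
            return label
        number = ordinal + 1
        starts = [s for s, _ in self.helices.values()]
        return "pre-A" if number < min(starts) else "post-H"

    def ordinal_of(self, label: str) -> int:
        """0-based reference ordinal of a helix-position label like 'G5'."""
        helix, idx = _split_label(label)
        if helix not in self.helices:
            raise KeyError(f"annotation incomplete: no segment {helix!r}")
        start, end = self.helices[helix]
        number = start + idx - 1
        if number > end:
            raise KeyError(f"annotation incomplete: {label} beyond segment end")
        return number - 1


def default_reference() -> tuple[SequenceRecord, HelixAnnotation]:
    """The shipped sperm whale myoglobin reference and its helix annotation."""
    raw = (resources.files("globinsp") / "data" / "sperm_whale_mb.json").read_text()
    data = json.loads(raw)
    record = SequenceRecord(data["id"], data["sequence"], data["description"])
    annotation = HelixAnnotation(
        reference_id=data["id"],
        length=len(data["sequence"]),
        helices={k: tuple(v) for k, v in data["helices"].items()},
    )
    return record, annotation


def classify_hydrophobic(residue: str, template: MbFoldTemplate | None = None) -> bool:
    """Whether a one-letter code belongs to the template's hydrophobic set.

    X (unknown) never counts as hydrophobic.
    """
    if template is None:
        template = MbFoldTemplate()
    if len(residue) != 1 or residue.upper() not in AA_WITH_X:
        raise ValueError(f"invalid amino-acid code: {residue!r}")
    return residue.upper() in template.hydrophobic_set


@dataclass(eq=False)
class FoldCheckResult:
    """Outcome of the myoglobin-fold check for one candidate."""

    candidate_id: str
    positions: list[tuple[str, str | None, bool]]  # (label, residue, hydrophobic)
    f8_his: bool
    helices_present: frozenset
    hydrophobic_fraction: float
    verdict: bool
    fugue_z: float | None = None
    strict: bool = False

    def position_residue(self, label: str) -> str | None:
        for lab, res, _ in self.positions:
            if lab == label:
                return res
        raise KeyError(label)


def check_mb_fold(aln: StructAlignment, template: MbFoldTemplate | None = None,
                  annotation: HelixAnnotation | None = None,
                  fugue_z: float | None = None,
                  strict: bool = False) -> FoldCheckResult:
    """Check a candidate aligned to the annotated reference against the fold.

    The alignment must contain the annotated reference and exactly one other
    member (the candidate). Verdict is pass iff the F8 His is present, each
    of helices B, C, E, F and G has candidate residues at >= 50% of its
    template positions, the hydrophobic fraction over all template positions
    meets the template minimum (waived in ``strict`` mode, which applies the
    bare His + helix-coverage criteria), and, when a Z-score is supplied,
    it exceeds 6.
    """
    if template is None:
        template = MbFoldTemplate()
    if annotation is None:
        _, annotation = default_reference()
    if annotation.reference_id not in aln.member_ids:
        raise ValueError(
            f"alignment lacks the annotated reference {annotation.reference_id!r}"
        )
    others = [m for m in aln.member_ids if m != annotation.reference_id]
    if len(others) != 1:
        raise ValueError("alignment must contain the reference and exactly "
                         "one candidate")
    candidate = others[0]
    ref_row = aln.row(annotation.reference_id)

    positions: list[tuple[str, str | None, bool]] = []
    helix_hits: dict[str, list[bool]] = {}
    n_hydrophobic = 0
    f8_his = False
    for label in template.positions:
        ordinal = annotation.ordinal_of(label)  # KeyError -> incomplete
        cols = (ref_row == ordinal).nonzero()[0]
        if cols.size != 1:
            raise ValueError(
                f"annotation incomplete: reference residue for {label} "
                "not present in the alignment"
            )
        residue = aln.residue_at(candidate, int(cols[0]))
        hydro = residue is not None and classify_hydrophobic(residue, template)
        positions.append((label, residue, hydro))
        n_hydrophobic += int(hydro)
        helix, _ = _split_label(label)
        if len(helix) == 1 and helix in INTRA_HELICES:
            helix_hits.setdefault(helix, []).append(residue is not None)
        if label == "F8":
            f8_his = residue == "H"

    helices_present = frozenset(
        h for h, hits in helix_hits.items() if sum(hits) >= 0.5 * len(hits)
    )
    fraction = n_hydrophobic / len(template.positions)
    verdict = f8_his and REQUIRED_HELICES <= helices_present
    if not strict:
        verdict = verdict and fraction >= template.min_hydrophobic_fraction
    if fugue_z is not None:
        verdict = verdict and fugue_z > 6.0
    return FoldCheckResult(
        candidate_id=candidate, positions=positions, f8_his=f8_his,
        helices_present=helices_present, hydrophobic_fraction=fraction,
        verdict=verdict, fugue_z=fugue_z, strict=strict,
    )


def map_intron_position(cds_offset_nt: int, aln: StructAlignment,
                        annotation: HelixAnnotation | None = None,
                        candidate_id: str | None = None) -> str:
    """Helix-relative notation for an intron at a CDS nucleotide offset.

    The offset counts nucleotides of the candidate's coding sequence before
    the intron. Phase 0 means the intron falls between codons, in which case
    the notation names the following residue (an intron between the codons
    of helix-G residues 6 and 7 is G7.0); phases 1 and 2 fall inside the
    named residue's codon.
    """
    if annotation is None:
        _, annotation = default_reference()
    others = [m for m in aln.member_ids if m != annotation.reference_id]
    if candidate_id is None:
        if len(others) != 1:
            raise ValueError("candidate_id required for multi-member alignments")
        candidate_id = others[0]
    cand_seq = aln.sequences.get(candidate_id)
    if cand_seq is None:
        raise ValueError(f"no sequence stored for member {candidate_id!r}")
    protein_length = len(cand_seq)
    if not 1 <= cds_offset_nt < 3 * protein_length:
        raise ValueError("cds offset outside the coding sequence")

    residue_number = cds_offset_nt // 3 + 1  # 1-based, on the candidate
    phase = cds_offset_nt % 3
    cand_row = aln.row(candidate_id)
    cols = (cand_row == residue_number - 1).nonzero()[0]
    if cols.size != 1:
        raise ValueError("candidate residue missing from the alignment")
    ref_ordinal = int(aln.row(annotation.reference_id)[cols[0]])
    if ref_ordinal == GAP:
        return f"unaligned.{phase}"
    return f"{annotation.region_of(ref_ordinal)}.{phase}"
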