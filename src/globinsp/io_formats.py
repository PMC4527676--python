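"""Readers, writers and container types for the formats the toolkit touches.

No science lives here: FASTA sequences and gapped alignments, PDB-derived
C-alpha traces, Newick trees and TSV side tables (confidence tracks,
similarity/distance matrices) are parsed into plain containers that the
analysis modules consume.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

GAP = -1
"""Sentinel for a gap in a :class:`StructAlignment` column."""

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_WITH_X = AA_ALPHABET | {"X"}
GAP_CHARS = {"-", "."}


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One amino-acid sequence (optionally gapped when part of an MSA)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - AA_WITH_X - GAP_CHARS
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )
        self.sequence = self.sequence.replace(".", "-")

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def __len__(self) -> int:
        return len(self.sequence)


def _normalise_aa(raw: str) -> str:
    """Uppercase and map non-standard one-letter codes to X, keeping gaps."""
    out = []
    for ch in raw.upper():
        if ch in AA_WITH_X or ch in GAP_CHARS:
            out.append("-" if ch in GAP_CHARS else ch)
        elif ch == "*":
            continue  # trailing stop codons in translated entries
        else:
            out.append("X")
    return "".join(out)


def read_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text into records; lowercase is uppercased, rare codes → X."""
    if not text.strip():
        raise ValueError("empty FASTA input")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = _normalise_aa(str(rec.seq))
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], width: int = 60) -> str:
    lines = []
    for rec in records:
        header = rec.description if rec.description.startswith(rec.id) else rec.id
        lines.append(f">{header}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i : i + width])
    return "\n".join(lines) + "\n"


def read_msa(text: str) -> list[SequenceRecord]:
    """Read a gapped FASTA alignment; all rows must have equal length."""
    records = read_fasta(text)
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    return records


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TraceResidue:
    """A residue represented by its C-alpha atom."""

    number: int
    icode: str | None
    amino_acid: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")

    @property
    def key(self) -> tuple[int, str | None]:
        return (self.number, self.icode)


@dataclass(eq=False)
class CoordinateTrace:
    """One chain's ordered C-alpha trace (coordinates in Å)."""

    structure_id: str
    chain_id: str
    residues: list[TraceResidue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty trace: no residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue number, insertion code) in trace")

    @property
    def coords(self) -> np.ndarray:
        return np.stack([r.position for r in self.residues])

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _one_letter(resname: str) -> str:
    if resname == "MSE":
        return "M"
    code = seq1(resname, custom_map={})
    return code if code in AA_ALPHABET else "X"


def read_structure(pdb_text: str, chain: str | None = None,
                   structure_id: str = "structure") -> CoordinateTrace:
    """Extract one chain's C-alpha trace from PDB-format text.

    Only the first MODEL is read. Alternate locations are resolved to the
    highest-occupancy conformer (ties: first encountered). HETATM residues
    are excluded except selenomethionine, which is read as Met.
    """
    if not pdb_text.strip():
        raise ValueError("empty PDB input")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("empty trace: PDB text contains no model") from None

    def trace_of(ch) -> list[TraceResidue]:
        residues = []
        for res in ch:
            hetflag, number, icode = res.id
            if hetflag.strip() and res.get_resname() != "MSE":
                continue
            if "CA" not in res:
                continue
            atom = res["CA"]  # disordered atoms resolve to top occupancy
            residues.append(
                TraceResidue(number, icode.strip() or None,
                             _one_letter(res.get_resname()), atom.get_coord())
            )
        return residues

    chains = list(model)
    if chain is not None:
        matching = [c for c in chains if c.id == chain]
        if not matching:
            raise ValueError(f"chain not found: {chain!r}")
        residues = trace_of(matching[0])
        if not residues:
            raise ValueError(f"empty trace: chain {chain!r} has no C-alpha atoms")
        return CoordinateTrace(structure_id, chain, residues)
    for c in chains:
        residues = trace_of(c)
        if residues:
            return CoordinateTrace(structure_id, c.id, residues)
    raise ValueError("empty trace: no chain with C-alpha atoms")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class StructAlignment:
    """A column-wise alignment of several members (sequences or structures).

    Each column maps a member to a 0-based ordinal into that member's residue
    list, or :data:`GAP`. An optional per-column confidence in [0, 1] may be
    attached, mirroring the column-support tracks emitted by joint
    structure-alignment samplers.
    """

    member_ids: list[str]
    matrix: np.ndarray  # (n_members, n_columns), int, GAP = -1
    confidence: np.ndarray | None = None
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.member_ids):
            raise ValueError("alignment matrix shape does not match member ids")
        for row, mid in zip(self.matrix, self.member_ids):
            vals = row[row != GAP]
            if np.any(np.diff(vals) <= 0):
                raise ValueError(f"ordinals for member {mid!r} are not increasing")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (self.n_columns,):
                raise ValueError(
                    f"confidence length {self.confidence.size} does not match "
                    f"{self.n_columns} columns"
                )
            if np.any((self.confidence < 0) | (self.confidence > 1)):
                raise ValueError("confidence values must lie in [0, 1]")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, member_id: str) -> np.ndarray:
        try:
            idx = self.member_ids.index(member_id)
        except ValueError:
            raise KeyError(f"member not in alignment: {member_id!r}") from None
        return self.matrix[idx]

    def pair_columns(self, a: str, b: str) -> np.ndarray:
        """Indices of columns where both members are aligned (non-gap)."""
        return np.flatnonzero((self.row(a) != GAP) & (self.row(b) != GAP))

    def residue_at(self, member_id: str, column: int) -> str | None:
        """One-letter residue of *member* at *column*, or None on gap."""
        ordinal = int(self.row(member_id)[column])
        if ordinal == GAP:
            return None
        seq = self.sequences.get(member_id)
        return seq[ordinal] if seq is not None else None

    @classmethod
    def from_gapped(cls, records: list[SequenceRecord],
                    confidence: np.ndarray | None = None) -> "StructAlignment":
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        n_cols = lengths.pop()
        matrix = np.full((len(records), n_cols), GAP, dtype=int)
        for i, rec in enumerate(records):
            ordinal = 0
            for j, ch in enumerate(rec.sequence):
                if ch != "-":
                    matrix[i, j] = ordinal
                    ordinal += 1
        return cls(
            member_ids=[r.id for r in records],
            matrix=matrix,
            confidence=confidence,
            sequences={r.id: r.ungapped for r in records},
        )

    def to_gapped(self) -> list[SequenceRecord]:
        records = []
        for mid, row in zip(self.member_ids, self.matrix):
            seq = self.sequences.get(mid)
            if seq is None:
                raise ValueError(f"no sequence stored for member {mid!r}")
            chars = ["-" if o == GAP else seq[o] for o in row]
            records.append(SequenceRecord(mid, "".join(chars)))
        return records


def read_gapped_alignment(fasta_text: str) -> StructAlignment:
    """Read a gapped FASTA alignment into a column-wise alignment."""
    return StructAlignment.from_gapped(read_msa(fasta_text))


def read_confidence(tsv_text: str) -> np.ndarray:
    """Read a per-column confidence track from a single-header-row TSV."""
    if not tsv_text.strip():
        raise ValueError("empty confidence input")
    frame = pd.read_csv(io.StringIO(tsv_text), sep="\t")
    values = frame.iloc[:, -1].to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("confidence track contains no rows")
    if np.any((values < 0) | (values > 1)) or not np.all(np.isfinite(values)):
        raise ValueError("confidence values must be finite and in [0, 1]")
    return values


def write_confidence(values: np.ndarray) -> str:
    lines = ["column\tconfidence"]
    lines += [f"{i}\t{v:.4f}" for i, v in enumerate(np.asarray(values, float))]
    return "\n".join(lines) + "\n"


def attach_confidence(aln: StructAlignment, values: np.ndarray) -> StructAlignment:
    return StructAlignment(aln.member_ids, aln.matrix, values, aln.sequences)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a phylogenetic tree; branch length is the edge to the parent."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None,
                 children: list["TreeNode"] | None = None) -> None:
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[TreeNode] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]


@dataclass(eq=False)
class PhyloTree:
    """Unrooted tree with branch lengths and optional percent supports."""

    root: TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names()
        if len(names) < 2:
            raise ValueError("tree must have at least 2 leaves")
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        for node in self.root.walk():
            if node.length < 0:
                raise ValueError("branch lengths must be non-negative")

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset, float | None]:
        """Non-trivial splits, each keyed by the side without the reference leaf.

        The reference leaf is the alphabetically first label, which gives every
        unrooted bipartition a unique canonical representation. Values are the
        supports attached to the corresponding internal branches.
        """
        all_leaves = set(self.leaf_names())
        ref = min(all_leaves)
        splits: dict[frozenset, float | None] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if ref in side:
                side = frozenset(all_leaves - side)
            if len(side) >= 2 and len(all_leaves) - len(side) >= 2:
                splits[side] = node.support
        return splits

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names()
        index = {n: i for i, n in enumerate(names)}
        dist = np.zeros((len(names), len(names)))

        def below(node):
            # returns {leaf: distance to this node}
            if node.is_leaf:
                return {node.name: 0.0}
            merged: dict[str, float] = {}
            groups = []
            for child in node.children:
                sub = {k: v + child.length for k, v in below(child).items()}
                groups.append(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            d = da + db
                            dist[index[la], index[lb]] = d
                            dist[index[lb], index[la]] = d
            for g in groups:
                merged.update(g)
            return merged

        below(self.root)
        return pd.DataFrame(dist, index=names, columns=names)


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        label = node.name or ""
        return f"{label}:{_format_length(node.length)}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = "" if node.support is None else str(int(round(node.support)))
    return f"({inner}){label}:{_format_length(node.length)}"


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree; supports are written as internal-node labels."""
    inner = ",".join(_newick_node(c) for c in tree.root.children)
    label = "" if tree.root.support is None else str(int(round(tree.root.support)))
    return f"({inner}){label};\n"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick text; numeric internal labels are read as supports."""
    if not text.strip():
        raise ValueError("empty Newick input")
    if text.count("(") != text.count(")"):
        raise ValueError("Newick parse error: unbalanced parentheses")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(name=name, length=length)
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        return TreeNode(
            name=None, length=length, support=support,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    return PhyloTree(convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(ids: list[str], values: np.ndarray, corner: str = "id") -> str:
    """Write a square labelled matrix as TSV (header row + id column)."""
    values = np.asarray(values, dtype=float)
    lines = [corner + "\t" + "\t".join(ids)]
    for i, name in enumerate(ids):
        cells = "\t".join(
            "NA" if not math.isfinite(values[i, j]) else f"{values[i, j]:.4f}"
            for j in range(len(ids))
        )
        lines.append(f"{name}\t{cells}")
    return "\n".join(lines) + "\n"


def read_matrix_tsv(text: str) -> tuple[list[str], np.ndarray]:
    if not text.strip():
        raise ValueError("empty matrix input")
    frame = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, na_values=["NA"])
    ids = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != ids:
        raise ValueError("matrix row and column ids differ")
    return ids, frame.to_numpy(dtype=float)
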