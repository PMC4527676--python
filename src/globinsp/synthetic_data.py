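"""Seed-deterministic generators for the inputs the analysis stages expect.

The generators emulate the statistical structure the downstream methods
assume: amino-acid families evolved on a known tree under a Poisson
substitution process with uniform replacement (the regime the Poisson
distance correction inverts exactly), C-alpha bundles derived from an
idealised helical template with controllable per-site noise, rigid motions
and deletions, and tandem multidomain concatenations with planted domain
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import (
    GAP,
    CoordinateTrace,
    PhyloTree,
    SequenceRecord,
    StructAlignment,
    TraceResidue,
    TreeNode,
)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# sequence families on a tree
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Configuration for evolving an amino-acid family on a known tree.

    Branch lengths are expected substitutions per site. Substitution counts
    per site and branch are Poisson(b); each substitution replaces the
    residue with a uniformly chosen different amino acid.
    """

    tree: PhyloTree
    n_sites: int
    seed: int
    root_composition: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        self.root_composition = np.asarray(self.root_composition, dtype=float)
        if self.root_composition.shape != (20,) or not np.isclose(
            self.root_composition.sum(), 1.0
        ):
            raise ValueError("root_composition must be a 20-vector summing to 1")


def simulate_family(config: SimulationConfig) -> tuple[list[SequenceRecord], PhyloTree]:
    """Evolve sequences down ``config.tree``; returns leaf records + true tree.

    Sites evolve independently. The traversal order is fixed (preorder), so
    identical configs give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    root_state = rng.choice(20, size=n, p=config.root_composition)

    records: list[SequenceRecord] = []

    def descend(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            counts = rng.poisson(child.length, size=n)
            child_state = state.copy()
            hit = np.flatnonzero(counts)
            for site in hit:
                s = child_state[site]
                for _ in range(counts[site]):
                    s = (s + rng.integers(1, 20)) % 20
                child_state[site] = s
            if child.is_leaf:
                seq = "".join(AA_ORDER[i] for i in child_state)
                records.append(SequenceRecord(child.name, seq))
            else:
                descend(child, child_state)

    descend(config.tree.root, root_state)
    return records, config.tree


def random_topology(n_taxa: int, seed: int,
                    branch_length_range: tuple[float, float] = (0.05, 0.3),
                    prefix: str = "t") -> PhyloTree:
    """Random unrooted binary topology with uniform branch lengths.

    Built by sequential random attachment (each new leaf subdivides a random
    existing edge), which samples valid unrooted shapes without bias toward
    balanced or caterpillar trees.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    lo, hi = branch_length_range

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    names = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    root = TreeNode(children=[TreeNode(names[0], bl()),
                              TreeNode(names[1], bl()),
                              TreeNode(names[2], bl())])
    # edges as (parent, child) pairs
    edges = [(root, c) for c in root.children]
    for name in names[3:]:
        parent, child = edges[int(rng.integers(len(edges)))]
        mid = TreeNode(length=bl(), children=[child, TreeNode(name, bl())])
        child.length = bl()  # redraw both halves so lengths stay in range
        parent.children[parent.children.index(child)] = mid
        edges.remove((parent, child))
        edges += [(parent, mid), (mid, child), (mid, mid.children[1])]
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def make_helical_template(n_helices: int = 8, residues_per_helix: int = 19,
                          structure_id: str = "bundle",
                          bundle_radius: float = 8.0) -> CoordinateTrace:
    """Idealised alpha-helical bundle C-alpha trace.

    Each helix uses canonical alpha-helix geometry: 1.5 Å rise per residue,
    100 degrees of turn per residue, C-alpha at 2.3 Å from the helix axis
    (successive C-alpha separation ~3.8 Å). Helices run antiparallel on a
    circular bundle layout. Deterministic: no randomness involved.
    """
    if n_helices < 1 or residues_per_helix < 1:
        raise ValueError("need at least one helix with one residue")
    residues: list[TraceResidue] = []
    number = 1
    seq_cycle = "LAFKEVIG"  # generic hydrophobic-rich helical pattern
    for h in range(n_helices):
        angle = 2.0 * np.pi * h / max(n_helices, 2)
        cx = bundle_radius * np.cos(angle)
        cy = bundle_radius * np.sin(angle)
        direction = 1.0 if h % 2 == 0 else -1.0
        for k in range(residues_per_helix):
            phase = np.deg2rad(100.0 * k) * direction + angle
            x = cx + 2.3 * np.cos(phase)
            y = cy + 2.3 * np.sin(phase)
            z = direction * 1.5 * k
            aa = seq_cycle[(h + k) % len(seq_cycle)]
            residues.append(TraceResidue(number, None, aa, np.array([x, y, z])))
            number += 1
    return CoordinateTrace(structure_id, "A", residues)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (via a random unit quaternion)."""
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()


@dataclass
class StructurePerturbConfig:
    """Noise / rigid-motion / deletion model applied to a template trace."""

    template: CoordinateTrace
    per_site_sigma: float | np.ndarray = 0.0
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    deletion_spans: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        sigma = np.asarray(self.per_site_sigma, dtype=float)
        if np.any(~np.isfinite(sigma)) or np.any(sigma < 0):
            raise ValueError("per_site_sigma must be finite and non-negative")
        n = len(self.template)
        for start, end in self.deletion_spans:
            if not (0 <= start < end <= n):
                raise ValueError(f"deletion span ({start}, {end}) outside template")


def perturb_structure(config: StructurePerturbConfig,
                      structure_id: str = "perturbed"
                      ) -> tuple[CoordinateTrace, StructAlignment]:
    """Noisy, rigidly moved, possibly truncated copy of a template trace.

    Returns the perturbed trace together with the ground-truth column mapping
    back to the template (one column per template residue; deleted spans are
    gaps on the perturbed side).
    """
    template = config.template
    n = len(template)
    rng = np.random.default_rng(config.seed)
    sigma = np.broadcast_to(np.asarray(config.per_site_sigma, float), (n,))

    deleted = np.zeros(n, dtype=bool)
    for start, end in config.deletion_spans:
        deleted[start:end] = True

    coords = template.coords + rng.normal(size=(n, 3)) * sigma[:, None]
    if config.rotation is not None:
        coords = coords @ np.asarray(config.rotation, float).T
    if config.translation is not None:
        coords = coords + np.asarray(config.translation, float)

    residues = []
    matrix = np.full((2, n), GAP, dtype=int)
    matrix[0] = np.arange(n)
    kept_ordinal = 0
    for i, res in enumerate(template.residues):
        if deleted[i]:
            continue
        residues.append(TraceResidue(res.number, res.icode, res.amino_acid,
                                     coords[i]))
        matrix[1, i] = kept_ordinal
        kept_ordinal += 1

    trace = CoordinateTrace(structure_id, template.chain_id, residues)
    aln = StructAlignment(
        member_ids=[template.structure_id, structure_id],
        matrix=matrix,
        sequences={template.structure_id: template.sequence,
                   structure_id: trace.sequence},
    )
    return trace, aln


# ---------------------------------------------------------------------------
# multidomain proteins
# ---------------------------------------------------------------------------

def make_multidomain(domain: SequenceRecord, k: int, linker_len: int = 8,
                     mutation_rate: float = 0.1, seed: int = 0,
                     record_id: str | None = None
                     ) -> tuple[SequenceRecord, list[tuple[int, int]]]:
    """Concatenate *k* mutated copies of a domain joined by GS linkers.

    Each copy independently receives point mutations (per-site Bernoulli at
    ``mutation_rate``, replacement uniform over the other 19 amino acids).
    Returns the chimeric record and the planted 0-based half-open intervals.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    base = domain.ungapped
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    linker = ("GS" * linker_len)[:linker_len]

    pieces: list[str] = []
    intervals: list[tuple[int, int]] = []
    offset = 0
    for copy in range(k):
        chars = list(base)
        if mutation_rate > 0:
            hits = np.flatnonzero(rng.random(len(chars)) < mutation_rate)
            for site in hits:
                aa = chars[site]
                if aa not in index:
                    continue
                chars[site] = AA_ORDER[(index[aa] + rng.integers(1, 20)) % 20]
        piece = "".join(chars)
        intervals.append((offset, offset + len(piece)))
        pieces.append(piece)
        offset += len(piece)
        if copy < k - 1:
            pieces.append(linker)
            offset += len(linker)
    rid = record_id or f"{domain.id}_x{k}"
    return SequenceRecord(rid, "".join(pieces)), intervals
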