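"""Distance-matrix structure comparison for aligned C-alpha traces.

The central statistic is the per-site distance-matrix RMSD (dRMSD): for two
structures A and B sharing n aligned columns,

    dRMSD_i(A, B) = sqrt( 1/(n-1) * sum_j [ d_ij(A) - d_ij(B) ]^2 )

where d_ij is the intramolecular C-alpha/C-alpha distance and the sum runs
over the aligned columns j. Because it compares internal distances rather
than coordinates, the statistic is invariant under rigid motion of either
structure and needs no superposition. The overall RMSD of a pair is the
root of the mean of the squared per-site contributions.

Least-squares rigid-body superposition (Kabsch) is provided for producing
overlays, and a structure-guided fallback alignment builder for the case
where no externally computed alignment is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io_formats import GAP, CoordinateTrace, StructAlignment

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class IntraDistanceMatrix:
    """Symmetric matrix of intramolecular C-alpha distances (Å)."""

    structure_id: str
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("distance matrix must be square")

    def __len__(self) -> int:
        return self.d.shape[0]


def intra_distances(trace: CoordinateTrace) -> IntraDistanceMatrix:
    """All-against-all Euclidean C-alpha distances within one trace."""
    coords = trace.coords
    if len(coords) == 1:
        return IntraDistanceMatrix(trace.structure_id, np.zeros((1, 1)))
    return IntraDistanceMatrix(trace.structure_id, squareform(pdist(coords)))


@dataclass(eq=False)
class SiteDeviationProfile:
    """Per-alignment-column dRMSD values for one structure pair.

    ``values`` has one entry per alignment column; columns gapped in either
    structure are NaN with ``gap_mask`` True. ``n_aligned`` is the n of the
    dRMSD formula; ``overall_rmsd`` summarises the non-gap columns.
    """

    pair: tuple[str, str]
    values: np.ndarray
    gap_mask: np.ndarray
    n_aligned: int
    overall_rmsd: float
    helix_labels: list[str | None] | None = None
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.values.shape != self.gap_mask.shape:
            raise ValueError("values and gap_mask lengths differ")
        if int((~self.gap_mask).sum()) != self.n_aligned:
            raise ValueError("n_aligned inconsistent with gap mask")

    @property
    def n_columns(self) -> int:
        return self.values.size

    def aligned_values(self) -> np.ndarray:
        return self.values[~self.gap_mask]


def aligned_length(aln: StructAlignment, a: str, b: str) -> int:
    """Number of columns where both members are aligned (the formula's n)."""
    return int(aln.pair_columns(a, b).size)


def per_site_drmsd(mat_a: IntraDistanceMatrix, mat_b: IntraDistanceMatrix,
                   aln: StructAlignment, sqrt_overall: bool = True
                   ) -> SiteDeviationProfile:
    """Per-column dRMSD between two structures under a given alignment.

    The j-sum runs over all n aligned columns (the j = i term contributes
    zero since d_ii = 0). With ``sqrt_overall`` (default) the overall value
    is the root-mean-square of the per-site values; with it disabled the
    literal mean of squared contributions is reported instead.
    """
    a, b = mat_a.structure_id, mat_b.structure_id
    cols = aln.pair_columns(a, b)
    n = cols.size
    if n < 2:
        raise ValueError("insufficient aligned residues: need at least 2")
    ia = aln.row(a)[cols]
    ib = aln.row(b)[cols]
    sub_a = mat_a.d[np.ix_(ia, ia)]
    sub_b = mat_b.d[np.ix_(ib, ib)]
    diff = sub_a - sub_b
    per_site = np.sqrt(np.sum(diff * diff, axis=1) / (n - 1))

    values = np.full(aln.n_columns, np.nan)
    values[cols] = per_site
    gap_mask = np.ones(aln.n_columns, dtype=bool)
    gap_mask[cols] = False

    mean_sq = float(np.mean(per_site * per_site))
    overall = float(np.sqrt(mean_sq)) if sqrt_overall else mean_sq
    return SiteDeviationProfile(
        pair=(a, b), values=values, gap_mask=gap_mask, n_aligned=n,
        overall_rmsd=overall, confidence=aln.confidence,
    )


def average_profiles(p1: SiteDeviationProfile, p2: SiteDeviationProfile
                     ) -> SiteDeviationProfile:
    """Column-wise mean of two profiles over the same alignment columns.

    A column is gapped in the output when it is gapped in either input; the
    overall value carried is the mean of the two inputs' overall values.
    """
    if p1.n_columns != p2.n_columns:
        raise ValueError("profiles have different column counts")
    gap_mask = p1.gap_mask | p2.gap_mask
    values = np.where(gap_mask, np.nan, (p1.values + p2.values) / 2.0)
    return SiteDeviationProfile(
        pair=(f"mean({p1.pair[0]},{p2.pair[0]})", p1.pair[1]),
        values=values,
        gap_mask=gap_mask,
        n_aligned=int((~gap_mask).sum()),
        overall_rmsd=(p1.overall_rmsd + p2.overall_rmsd) / 2.0,
        confidence=p1.confidence if p1.confidence is not None else p2.confidence,
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SuperpositionResult:
    """Least-squares rigid transform mapping structure B onto structure A."""

    rotation: np.ndarray
    translation: np.ndarray
    coordinate_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(trace_a: CoordinateTrace, trace_b: CoordinateTrace,
              aln: StructAlignment) -> SuperpositionResult:
    """Kabsch superposition of B onto A over the aligned C-alpha pairs.

    Minimises the sum of squared deviations with a proper rotation
    (reflections excluded). Requires at least 3 non-collinear pairs.
    """
    cols = aln.pair_columns(trace_a.structure_id, trace_b.structure_id)
    if cols.size < 3:
        raise ValueError("superposition requires at least 3 aligned pairs")
    xa = trace_a.coords[aln.row(trace_a.structure_id)[cols]]
    xb = trace_b.coords[aln.row(trace_b.structure_id)[cols]]
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    ya, yb = xa - ca, xb - cb
    if np.linalg.matrix_rank(yb, tol=1e-8) < 2:
        raise ValueError("aligned points are collinear; rotation ill-defined")
    h = yb.T @ ya
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    translation = ca - rotation @ cb
    moved = xb @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xa) ** 2, axis=1))))
    return SuperpositionResult(rotation, translation, rmsd)


# ---------------------------------------------------------------------------
# fallback structure-guided alignment
# ---------------------------------------------------------------------------

def _pairwise_structure_alignment(ref: CoordinateTrace, other: CoordinateTrace,
                                  max_pair_distance: float = 5.0,
                                  n_iter: int = 3) -> dict[int, int]:
    """Monotone residue pairing ref→other by iterated superpose-and-pair.

    Seeds correspondences with a global sequence alignment of the two trace
    sequences, superposes on them, then re-pairs mutually nearest C-alphas
    within ``max_pair_distance`` under a monotonicity constraint, iterating
    to convergence. Returns a dict ref ordinal → other ordinal.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(ref.sequence, other.sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))

    mapping = dict(pairs)
    for _ in range(n_iter):
        if len(mapping) < 3:
            break
        idx_a = np.fromiter(mapping.keys(), dtype=int)
        idx_b = np.fromiter((mapping[i] for i in idx_a), dtype=int)
        sub = StructAlignment(
            member_ids=[ref.structure_id, other.structure_id],
            matrix=np.vstack([np.sort(idx_a), idx_b[np.argsort(idx_a)]]),
        )
        sup = superpose(ref, other, sub)
        moved = sup.apply(other.coords)
        # greedy monotone nearest-neighbour chaining within the cutoff
        dists = np.linalg.norm(ref.coords[:, None, :] - moved[None, :, :], axis=2)
        new_mapping: dict[int, int] = {}
        j_min = 0
        for i in range(len(ref)):
            if j_min >= len(other):
                break
            j = int(j_min + np.argmin(dists[i, j_min:]))
            if dists[i, j] <= max_pair_distance:
                new_mapping[i] = j
                j_min = j + 1
        if new_mapping == mapping or len(new_mapping) < 3:
            break
        mapping = new_mapping
    return mapping


def structure_guided_alignment(traces: list[CoordinateTrace],
                               max_pair_distance: float = 5.0
                               ) -> StructAlignment:
    """Build a multiple alignment of traces with no external alignment.

    The first trace acts as reference: every other trace is aligned to it by
    progressive pairwise superposition and nearest-C-alpha pairing within
    ``max_pair_distance`` Å; columns are the reference residues plus, for
    completeness, nothing else (residues unmatched to the reference are left
    out). This is a pragmatic stand-in for an externally computed consensus
    alignment and should be reported as such alongside any derived numbers.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    ids = [t.structure_id for t in traces]
    if len(set(ids)) != len(ids):
        raise ValueError("structure ids must be unique")
    ref = traces[0]
    n_cols = len(ref)
    matrix = np.full((len(traces), n_cols), GAP, dtype=int)
    matrix[0] = np.arange(n_cols)
    for row, other in enumerate(traces[1:], start=1):
        mapping = _pairwise_structure_alignment(ref, other, max_pair_distance)
        for i, j in mapping.items():
            matrix[row, i] = j
    return StructAlignment(
        member_ids=ids, matrix=matrix,
        sequences={t.structure_id: t.sequence for t in traces},
    )


def plot_profile(profile: SiteDeviationProfile, ax=None):
    """Per-site dRMSD bar profile with gap shading, the overall level as a
    dashed line and the column-confidence track underneath (when present).

    Requires matplotlib; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(profile.n_columns)
    ax.bar(x, np.nan_to_num(profile.values), width=1.0, color="0.3")
    for col in np.flatnonzero(profile.gap_mask):
        ax.axvspan(col - 0.5, col + 0.5, color="0.85", zorder=0)
    ax.axhline(profile.overall_rmsd, color="red", linestyle="--", lw=1)
    if profile.confidence is not None:
        scale = max(float(np.nanmax(profile.values)), 1.0)
        ax.fill_between(x, -0.15 * scale * profile.confidence, 0,
                        color="tab:blue", alpha=0.5)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("per-site dRMSD (Å)")
    ax.set_title(f"{profile.pair[0]} vs {profile.pair[1]} "
                 f"(n={profile.n_aligned}, overall {profile.overall_rmsd:.2f} Å)")
    return ax


def profile_table(profile: SiteDeviationProfile) -> "pd.DataFrame":
    """Tidy per-column table (column, dRMSD, gap flag, confidence, helix)."""
    import pandas as pd

    data = {
        "column": np.arange(profile.n_columns),
        "drmsd": profile.values,
        "gap": profile.gap_mask,
    }
    if profile.helix_labels is not None:
        data["helix"] = profile.helix_labels
    if profile.confidence is not None:
        data["confidence"] = profile.confidence
    return pd.DataFrame(data)
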