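"""Pairwise percent-identity matrices and greedy redundancy reduction.

Identity between two MSA rows is computed over comparable columns (both
residues non-gap); the reduction step is a deterministic Hobohm-1 sweep in
input order, keeping a sequence only when its identity to every previously
kept sequence falls below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord


def percent_identity(row_a: str, row_b: str,
                     denominator: str = "comparable") -> float:
    """Percent identity between two equally long gapped rows.

    With ``denominator="comparable"`` (default) columns containing a gap in
    either row are excluded from both numerator and denominator; with
    ``denominator="alignment"`` the full alignment length divides instead.
    Returns NaN when no column is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if denominator not in ("comparable", "alignment"):
        raise ValueError(f"unknown denominator mode: {denominator!r}")
    a = np.frombuffer(row_a.encode(), dtype="S1")
    b = np.frombuffer(row_b.encode(), dtype="S1")
    comparable = (a != b"-") & (b != b"-")
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return float("nan")
    same = int(((a == b) & comparable).sum())
    denom = n_comp if denominator == "comparable" else len(row_a)
    return 100.0 * same / denom


@dataclass(eq=False)
class SimilarityMatrix:
    """Symmetric percent-identity matrix with a fixed id order."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite & finite.T],
                           self.values.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be exactly 100")
        off = self.values[finite]
        if np.any((off < 0) | (off > 100)):
            raise ValueError("identities must lie in [0, 100]")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def build_matrix(msa: list[SequenceRecord],
                 denominator: str = "comparable") -> SimilarityMatrix:
    """All-against-all percent identities for the rows of an MSA."""
    if not msa:
        raise ValueError("empty MSA")
    if len({len(r.sequence) for r in msa}) != 1:
        raise ValueError("alignment rows differ in length")
    n = len(msa)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(msa[i].sequence, msa[j].sequence, denominator)
            values[i, j] = values[j, i] = pid
    return SimilarityMatrix([r.id for r in msa], values)


def reduce_redundancy(matrix: SimilarityMatrix,
                      threshold_pct: float = 90.0) -> list[str]:
    """Greedy Hobohm-1 sweep: ids kept at the identity threshold, input order.

    A sequence is kept iff its identity to every previously kept sequence is
    strictly below ``threshold_pct``. Missing pairwise values never force
    removal (treated as 0 identity).
    """
    if not 0.0 < threshold_pct <= 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    kept: list[int] = []
    for i in range(len(matrix.ids)):
        row = matrix.values[i]
        if all(
            not (np.isfinite(row[j]) and row[j] >= threshold_pct) for j in kept
        ):
            kept.append(i)
    return [matrix.ids[i] for i in kept]
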