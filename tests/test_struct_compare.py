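"""The dRMSD statistic, aligned lengths, averaging and superposition."""

import numpy as np
import pytest

from globinsp.io_formats import GAP, StructAlignment
from globinsp.struct_compare import (
    aligned_length,
    average_profiles,
    intra_distances,
    per_site_drmsd,
    structure_guided_alignment,
    superpose,
)
from globinsp.synthetic_data import (
    StructurePerturbConfig,
    make_helical_template,
    perturb_structure,
    random_rotation,
)

from conftest import make_trace


def identity_alignment(a, b, n):
    return StructAlignment([a, b], np.tile(np.arange(n), (2, 1)))


def brute_force_drmsd(da, db, pairs):
    """Naive double-loop evaluation of the per-site statistic."""
    n = len(pairs)
    out = []
    for i, (ia, ib) in enumerate(pairs):
        acc = 0.0
        for ja, jb in pairs:
            acc += (da[ia, ja] - db[ib, jb]) ** 2
        out.append(np.sqrt(acc / (n - 1)))
    return np.array(out)


def test_intra_distances_basics():
    t2 = make_trace([[0, 0, 0], [3.8, 0, 0]])
    assert np.isclose(intra_distances(t2).d[0, 1], 3.8)
    t1 = make_trace([[1.0, 2.0, 3.0]])
    assert intra_distances(t1).d.shape == (1, 1)
    t3 = make_trace([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    assert np.isclose(intra_distances(t3).d[0, 2], 7.6)


def test_per_site_drmsd_hand_worked_three_residues():
    """3 aligned residues with one perturbed distance: exact closed-form."""
    a = make_trace([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], "A")
    px = (5.0 ** 2 - 3.8 ** 2 + 3.8 ** 2) / (2 * 3.8)
    py = np.sqrt(5.0 ** 2 - px ** 2)
    b = make_trace([[0, 0, 0], [3.8, 0, 0], [px, py, 0]], "B")
    profile = per_site_drmsd(intra_distances(a), intra_distances(b),
                             identity_alignment("A", "B", 3))
    expected = np.array([2.6 / np.sqrt(2.0), 0.0, 2.6 / np.sqrt(2.0)])
    assert np.allclose(profile.values, expected, atol=1e-12)
    assert np.isclose(profile.values[0], 1.8385, atol=5e-5)
    assert np.isclose(profile.overall_rmsd, 1.5011, atol=5e-5)
    assert np.isclose(profile.overall_rmsd,
                      np.sqrt(np.mean(expected ** 2)), atol=1e-12)
    assert profile.n_aligned == 3


@pytest.mark.parametrize("n,seed", [(5, 0), (9, 1), (12, 2), (15, 3)])
def test_per_site_drmsd_matches_brute_force(n, seed):
    rng = np.random.default_rng(seed)
    a = make_trace(rng.normal(scale=5, size=(n, 3)), "A")
    b = make_trace(rng.normal(scale=5, size=(n, 3)), "B")
    # random monotone partial alignment with gaps on both sides
    cols = max(n, 4)
    matrix = np.tile(np.arange(cols), (2, 1))
    drop_a = rng.choice(cols, size=2, replace=False)
    drop_b = rng.choice(cols, size=2, replace=False)
    matrix = np.full((2, cols), GAP)
    ka = kb = 0
    for c in range(cols):
        if c not in drop_a and ka < n:
            matrix[0, c] = ka
            ka += 1
        if c not in drop_b and kb < n:
            matrix[1, c] = kb
            kb += 1
    aln = StructAlignment(["A", "B"], matrix)
    da, db = intra_distances(a), intra_distances(b)
    profile = per_site_drmsd(da, db, aln)
    pairs = [(matrix[0, c], matrix[1, c]) for c in aln.pair_columns("A", "B")]
    assert np.allclose(profile.aligned_values(),
                       brute_force_drmsd(da.d, db.d, pairs), atol=1e-12)


def test_drmsd_self_comparison_is_zero(bundle_template):
    d = intra_distances(bundle_template)
    aln = identity_alignment("bundle", "copy", len(bundle_template))
    d2 = intra_distances(make_trace(bundle_template.coords, "copy"))
    profile = per_site_drmsd(d, d2, aln)
    assert np.nanmax(profile.values) == 0.0
    assert profile.overall_rmsd == 0.0


def test_drmsd_rigid_motion_invariance(bundle_template):
    rng = np.random.default_rng(7)
    d = intra_distances(bundle_template)
    for _ in range(5):
        rotation = random_rotation(rng)
        shift = rng.normal(scale=20, size=3)
        moved = make_trace(bundle_template.coords @ rotation.T + shift, "m")
        profile = per_site_drmsd(
            d, intra_distances(moved),
            identity_alignment("bundle", "m", len(bundle_template)),
        )
        assert np.nanmax(profile.values) < 1e-9


def test_drmsd_symmetry_and_zero_iff_equal():
    rng = np.random.default_rng(5)
    a = make_trace(rng.normal(size=(8, 3)), "A")
    b = make_trace(rng.normal(size=(8, 3)), "B")
    aln = identity_alignment("A", "B", 8)
    pab = per_site_drmsd(intra_distances(a), intra_distances(b), aln)
    aln_ba = StructAlignment(["B", "A"], aln.matrix)
    pba = per_site_drmsd(intra_distances(b), intra_distances(a), aln_ba)
    assert np.array_equal(pab.values, pba.values)
    assert pab.overall_rmsd > 0  # distinct matrices => nonzero


def test_drmsd_insufficient_columns_error():
    a = make_trace([[0, 0, 0], [1, 0, 0]], "A")
    b = make_trace([[0, 0, 0], [1, 0, 0]], "B")
    aln = StructAlignment(["A", "B"], np.array([[0, 1], [0, GAP]]))
    with pytest.raises(ValueError, match="insufficient aligned"):
        per_site_drmsd(intra_distances(a), intra_distances(b), aln)


def test_overall_rmsd_mean_square_mode():
    rng = np.random.default_rng(2)
    a = make_trace(rng.normal(size=(6, 3)), "A")
    b = make_trace(rng.normal(size=(6, 3)), "B")
    aln = identity_alignment("A", "B", 6)
    sqrt_mode = per_site_drmsd(intra_distances(a), intra_distances(b), aln)
    raw_mode = per_site_drmsd(intra_distances(a), intra_distances(b), aln,
                              sqrt_overall=False)
    assert np.isclose(sqrt_mode.overall_rmsd ** 2, raw_mode.overall_rmsd)


def test_aligned_length_counts_shared_columns():
    n = 10
    matrix = np.tile(np.arange(n), (2, 1))
    matrix[0, 3] = GAP
    matrix[1, 7] = GAP
    matrix[0, 4:] = [3, 4, 5, 6, 7, 8]
    matrix[1, 8:] = [7, 8]
    aln = StructAlignment(["A", "B"], matrix)
    assert aligned_length(aln, "A", "B") == 8
    full = identity_alignment("A", "B", 153)
    assert aligned_length(full, "A", "B") == 153


def test_average_profiles_rules():
    a = make_trace([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]], "A")
    b = make_trace([[0, 0, 0], [3.8, 0, 0], [7.6, 1, 0], [11.4, 0, 0]], "B")
    c = make_trace([[0, 0, 0], [3.8, 0, 0], [7.6, -1, 0], [11.4, 0, 0]], "C")
    aln_ab = identity_alignment("A", "B", 4)
    aln_ac = identity_alignment("A", "C", 4)
    p1 = per_site_drmsd(intra_distances(b), intra_distances(a), aln_ab)
    p2 = per_site_drmsd(intra_distances(c), intra_distances(a), aln_ac)
    mean = average_profiles(p1, p2)
    assert np.allclose(mean.values, (p1.values + p2.values) / 2)
    assert np.isclose(mean.overall_rmsd,
                      (p1.overall_rmsd + p2.overall_rmsd) / 2)
    same = average_profiles(p1, p1)
    assert np.allclose(same.values, p1.values)

    # a gap in either input gaps the output column
    gap_matrix = aln_ac.matrix.copy()
    gap_matrix[0, 2] = GAP
    p2_gap = per_site_drmsd(intra_distances(c), intra_distances(a),
                            StructAlignment(["C", "A"], gap_matrix))
    mixed = average_profiles(p1, p2_gap)
    assert mixed.gap_mask[2]
    with pytest.raises(ValueError, match="column counts"):
        average_profiles(p1, per_site_drmsd(
            intra_distances(make_trace([[0, 0, 0], [1, 0, 0], [2, 0, 0]], "B")),
            intra_distances(make_trace([[0, 0, 0], [1, 0, 0], [2, 0, 0]], "A")),
            identity_alignment("B", "A", 3)))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_superpose_identity_and_known_rotation(bundle_template):
    n = len(bundle_template)
    aln = identity_alignment("bundle", "m", n)
    same = make_trace(bundle_template.coords, "m")
    res = superpose(bundle_template, same, aln)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
    assert res.coordinate_rmsd < 1e-9

    rng = np.random.default_rng(1)
    rotation = random_rotation(rng)
    shift = rng.normal(scale=10, size=3)
    moved = make_trace(bundle_template.coords @ rotation.T + shift, "m")
    res = superpose(bundle_template, moved, aln)
    assert res.coordinate_rmsd < 1e-9
    assert np.allclose(res.rotation @ rotation, np.eye(3), atol=1e-8)
    assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
    assert np.isclose(np.linalg.det(res.rotation), 1.0)


def test_superpose_noise_rmsd_band():
    """100 points with sigma 0.5 Å noise: fitted RMSD near sigma*sqrt(3)."""
    rng = np.random.default_rng(0)
    base = rng.normal(scale=10, size=(100, 3))
    aln = identity_alignment("A", "B", 100)
    a = make_trace(base, "A")
    inside = 0
    for seed in range(20):
        noise_rng = np.random.default_rng(seed)
        b = make_trace(base + noise_rng.normal(scale=0.5, size=(100, 3)), "B")
        rmsd = superpose(a, b, aln).coordinate_rmsd
        inside += 0.6 <= rmsd <= 1.1
    assert inside == 20


def test_superpose_never_worse_than_unrotated_overlay():
    rng = np.random.default_rng(9)
    base = rng.normal(scale=8, size=(40, 3))
    a = make_trace(base, "A")
    b = make_trace(base @ random_rotation(rng).T + rng.normal(size=3), "B")
    aln = identity_alignment("A", "B", 40)
    fitted = superpose(a, b, aln).coordinate_rmsd
    raw = np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1)))
    assert fitted <= raw + 1e-12


def test_superpose_errors():
    a = make_trace([[0, 0, 0], [1, 0, 0]], "A")
    b = make_trace([[0, 0, 0], [1, 0, 0]], "B")
    with pytest.raises(ValueError, match="at least 3"):
        superpose(a, b, identity_alignment("A", "B", 2))
    col_a = make_trace([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], "A")
    col_b = make_trace([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], "B")
    with pytest.raises(ValueError, match="collinear"):
        superpose(col_a, col_b, identity_alignment("A", "B", 4))


def test_structure_guided_alignment_recovers_truth():
    template = make_helical_template(4, 15, structure_id="ref")
    rng = np.random.default_rng(3)
    trace, true_aln = perturb_structure(
        StructurePerturbConfig(template, per_site_sigma=0.3,
                               rotation=random_rotation(rng),
                               translation=np.array([5.0, -3.0, 2.0]),
                               deletion_spans=[(15, 30)], seed=3),
        structure_id="moved",
    )
    guessed = structure_guided_alignment([template, trace])
    true_cols = true_aln.pair_columns("ref", "moved")
    guessed_cols = guessed.pair_columns("ref", "moved")
    agree = sum(
        guessed.row("moved")[c] == true_aln.row("moved")[c]
        for c in true_cols if c in set(guessed_cols.tolist())
    )
    assert agree >= 0.9 * true_cols.size
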