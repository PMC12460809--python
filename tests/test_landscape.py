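import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from ringscape import (
    ProtomerRecord,
    build_coordinate_matrix,
    cluster_landscape,
    project,
    standardize_and_pca,
    superpose,
    superpose_subdomain,
)


def _horn_quaternion_superpose(mobile, target):
    """Independent closed-form (quaternion eigenvalue) superposition oracle."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(k)
    q = v[:, np.argmax(w)]  # (w, x, y, z)
    rot = Rotation.from_quat([q[1], q[2], q[3], q[0]])
    moved = rot.apply(a) + target.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def _random_points(rng, n=25):
    return rng.normal(size=(n, 3)) * 5.0


def test_superpose_identity_is_exact(rng):
    pts = _random_points(rng)
    rot, trans, rmsd = superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(rot.apply(pts) + trans, pts, atol=1e-9)


def test_superpose_recovers_planted_rigid_motion(rng):
    pts = _random_points(rng)
    planted = Rotation.from_euler("z", 30.0, degrees=True)
    target = planted.apply(pts) + np.array([5.0, 0.0, 0.0])
    rot, _, rmsd = superpose(pts, target)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.degrees(rot.magnitude()) == pytest.approx(30.0, abs=1e-6)


def test_superpose_matches_quaternion_oracle(rng):
    for _ in range(20):
        mobile = _random_points(rng)
        target = _random_points(rng) + rng.normal(scale=0.5, size=(25, 3))
        _, _, rmsd = superpose(mobile, target)
        assert rmsd == pytest.approx(_horn_quaternion_superpose(mobile, target), abs=1e-9)


def test_superpose_noise_rmsd_scale(rng):
    """Fitting two copies with iid per-coordinate noise sigma: the pairwise
    per-atom deviation has variance 2 sigma^2 per coordinate over 3
    coordinates, so RMSD -> sigma * sqrt(6) for large n (slightly below,
    as the 6 rigid-body parameters absorb part of the noise)."""
    sigma = 0.4
    rmsds = []
    for _ in range(30):
        base = rng.normal(size=(200, 3)) * 10.0
        a = base + rng.normal(scale=sigma, size=base.shape)
        b = base + rng.normal(scale=sigma, size=base.shape)
        _, _, rmsd = superpose(a, b)
        rmsds.append(rmsd)
    assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(6.0), rel=0.02)


def test_superpose_rejects_degenerate_input():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        superpose(line, line)
    with pytest.raises(ValueError, match="at least 3"):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _protomer(model_id, coords, position="A"):
    return ProtomerRecord(
        model_id=model_id, position_label=position, condition="hydrolyzing",
        nucleotide_state="apo", substrate_engaged=True,
        calpha_coords=coords, chain_id="A",
    )


def test_superpose_subdomain_requires_shared_residues(rng, domains):
    coords = {r: rng.normal(size=3) for r in range(224, 228)}
    p = _protomer("a", coords)
    q = _protomer("b", {r: rng.normal(size=3) for r in range(300, 330)})
    with pytest.raises(ValueError, match="shared"):
        superpose_subdomain(p, q, domains.large_range)


def test_coordinate_matrix_shapes(rng, domains):
    residues = list(range(224, 234)) + list(range(400, 410))
    protomers = [
        _protomer(f"m{i}", {r: rng.normal(size=3) * 4 for r in residues})
        for i in range(12)
    ]
    cm = build_coordinate_matrix(protomers, domains)
    assert cm.C.shape == (12, 20, 3)
    assert cm.C_flat.shape == (12, 60)
    assert cm.row_index[0] == ("m0", "A")
    np.testing.assert_array_equal(cm.C_flat[3], cm.C[3].reshape(-1))


def test_identical_protomers_give_identical_rows(rng, domains):
    residues = list(range(224, 240)) + list(range(400, 416))
    coords = {r: rng.normal(size=3) * 4 for r in residues}
    protomers = [_protomer(f"m{i}", dict(coords)) for i in range(4)]
    cm = build_coordinate_matrix(protomers, domains)
    for row in cm.C_flat[1:]:
        np.testing.assert_allclose(row, cm.C_flat[0], atol=1e-9)


def test_landscape_rigid_motion_invariance(default_ensemble, domains):
    """A global rotation+translation of every input model leaves C_flat
    (hence the latent space and clusters) unchanged to 1e-6 A."""
    protomers = default_ensemble.protomers
    cm1 = build_coordinate_matrix(protomers, domains)
    rot = Rotation.from_euler("zyx", [63.0, -20.0, 111.0], degrees=True)
    shift = np.array([-30.0, 12.0, 7.0])
    moved = [
        _protomer(p.model_id, {r: rot.apply(c) + shift for r, c in p.calpha_coords.items()},
                  p.position_label)
        for p in protomers
    ]
    cm2 = build_coordinate_matrix(moved, domains)
    assert np.abs(cm1.C - cm2.C).max() < 1e-6


def test_pca_rank_two_data_needs_two_components(rng):
    basis = rng.normal(size=(2, 30))
    weights = rng.normal(size=(20, 2))
    X = weights @ basis + rng.normal(size=30)  # rank-2 + constant offset
    res = standardize_and_pca(X, variance_target=0.99)
    assert res.k == 2


def test_pca_three_orthogonal_modes(rng):
    modes = np.linalg.qr(rng.normal(size=(60, 3)))[0].T  # 3 orthonormal rows
    weights = rng.normal(size=(24, 3)) * np.array([5.0, 4.0, 3.0])
    X = weights @ modes + rng.normal(scale=1e-4, size=(24, 60))
    res = standardize_and_pca(X, variance_target=0.99)
    assert res.k == 3


def test_pca_ratios_nonincreasing_and_sum_to_one(default_ensemble, domains):
    cm = build_coordinate_matrix(default_ensemble.protomers, domains)
    res = standardize_and_pca(cm.C_flat)
    full = res.explained_variance_ratio_full
    assert np.all(np.diff(full) <= 1e-12)
    assert full.sum() == pytest.approx(1.0, abs=1e-9)
    assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9
    assert res.explained_variance_ratio.sum() >= 0.99 - 1e-9


def test_pca_reconstruction_error_monotone_in_k(rng):
    X = rng.normal(size=(15, 40)) * rng.uniform(0.5, 3.0, size=40)
    res = standardize_and_pca(X, variance_target=1.0)
    Xs = (X - res.scaler_mean) / res.scaler_scale
    errors = []
    for k in range(1, res.k + 1):
        proj = res.C_trans[:, :k] @ res.components[:k]
        errors.append(np.sum((Xs - proj) ** 2))
    assert np.all(np.diff(errors) <= 1e-9)


def test_pca_sign_convention_largest_loading_positive(rng):
    X = rng.normal(size=(20, 30))
    res = standardize_and_pca(X, variance_target=1.0)
    for comp in res.components:
        assert comp[np.argmax(np.abs(comp))] > 0


def test_pca_k_override_and_validation(rng):
    X = rng.normal(size=(10, 12))
    res = standardize_and_pca(X, k_override=4)
    assert res.k == 4 and res.C_trans.shape == (10, 4)
    with pytest.raises(ValueError):
        standardize_and_pca(X, k_override=99)
    with pytest.raises(ValueError):
        standardize_and_pca(X[:1])
    with pytest.raises(ValueError):
        standardize_and_pca(X, variance_target=0.0)


def test_cluster_recovery_on_well_separated_points(rng):
    centers = rng.normal(size=(5, 4)) * 50.0
    pts = np.concatenate([c + rng.normal(scale=0.5, size=(6, 4)) for c in centers])
    truth = np.repeat(np.arange(5), 6)
    labels = cluster_landscape(pts, min_cluster_size=3)
    assert len(set(labels)) == 5 and -1 not in labels
    assert adjusted_rand_score(truth, labels) == 1.0


def test_cluster_labels_ordered_by_size(rng):
    big = rng.normal(scale=0.3, size=(12, 2)) + 100.0
    small = rng.normal(scale=0.3, size=(5, 2)) - 100.0
    labels = cluster_landscape(np.concatenate([small, big]), min_cluster_size=3)
    assert set(labels[5:]) == {0}  # largest cluster gets label 0
    assert set(labels[:5]) == {1}


def test_cluster_identical_points_form_one_cluster():
    pts = np.tile([1.0, 2.0, 3.0], (8, 1))
    labels = cluster_landscape(pts, min_cluster_size=3)
    assert set(labels) == {0}


def test_cluster_too_few_points_all_noise():
    with pytest.warns(UserWarning, match="noise"):
        labels = cluster_landscape(np.zeros((2, 3)), min_cluster_size=3)
    assert list(labels) == [-1, -1]
    with pytest.raises(ValueError):
        cluster_landscape(np.zeros((5, 3)), min_cluster_size=1)


def test_project_selects_requested_modes(rng):
    X = rng.normal(size=(9, 6))
    np.testing.assert_array_equal(project(X, (1, 2)), X[:, :2])
    np.testing.assert_array_equal(project(X, (1, 5)), X[:, [0, 4]])
    with pytest.raises(ValueError):
        project(X, (1, 7))


def test_projection_separates_planted_clusters(rng):
    """In a low-dimensional projection of a synthetic 3-cluster ensemble the
    ground-truth clusters are compact (silhouette > 0.5)."""
    from sklearn.metrics import silhouette_score

    centers = np.array([[0.0, 0], [30, 0], [0, 30]])
    lat = np.concatenate([c + rng.normal(scale=1.0, size=(8, 2)) for c in centers])
    X = np.concatenate([lat, rng.normal(scale=1.0, size=(24, 3))], axis=1)
    proj = project(X, (1, 2))
    truth = np.repeat(np.arange(3), 8)
    assert silhouette_score(proj, truth) > 0.5
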