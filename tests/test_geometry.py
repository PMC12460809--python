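import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import permutation_test

from ringscape import (
    DistanceTable,
    EnsembleSpec,
    atom_distance,
    compare_protomer_groups,
    distance_distributions,
    export_attributes,
    fit_plane,
    generate_ensemble,
    helix_axis,
    interhelix_angle,
    make_hexamer_model,
    subdomain_angle,
    subdomain_centers_of_mass,
)
from ringscape.geometry import DEFAULT_PAIRS
from ringscape.model_io import extract_protomers
from ringscape.synthetic import ideal_helix


def test_helix_axis_of_long_ideal_helix_along_z():
    pts = ideal_helix(45, start=np.zeros(3), axis=(0.0, 0.0, 1.0))
    ax = helix_axis(pts)
    assert ax.n_residues == 45
    assert np.linalg.norm(ax.direction) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(ax.direction, [0, 0, 1], atol=1e-3)


def test_helix_axis_equivariance_under_rotation(rng):
    pts = ideal_helix(45, start=np.zeros(3), axis=(0.0, 0.0, 1.0))
    rot = Rotation.from_euler("xyz", [40.0, -25.0, 77.0], degrees=True)
    ax = helix_axis(rot.apply(pts))
    np.testing.assert_allclose(ax.direction, rot.apply([0, 0, 1]), atol=1e-3)


def test_helix_axis_n_residues_for_marker_helices(domains, scaffold):
    p = extract_protomers(scaffold, {"A": "A"}, domains, "hydrolyzing")[0]
    a3 = helix_axis(p.coords(domains.residues("helix_a3")))
    a8 = helix_axis(p.coords(domains.residues("helix_a8")))
    assert (a3.n_residues, a8.n_residues) == (9, 11)


def test_helix_axis_too_few_points():
    with pytest.raises(ValueError):
        helix_axis(np.zeros((2, 3)))


@pytest.mark.parametrize(
    "u,v,expected",
    [
        ([1, 0, 0], [1, 0, 0], 0.0),
        ([1, 0, 0], [0, 1, 0], 90.0),
        ([1, 0, 0], [-1, 0, 0], 180.0),
    ],
)
def test_interhelix_angle_reference_cases(u, v, expected):
    assert interhelix_angle(u, v) == pytest.approx(expected, abs=1e-12)


@given(st.integers(0, 10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_interhelix_angle_matches_arccos_oracle(seed):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    v = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    oracle = math.degrees(math.acos(np.clip(u @ v, -1.0, 1.0)))
    assert interhelix_angle(u, v) == pytest.approx(oracle, abs=1e-9)
    # symmetry and rotation invariance
    assert interhelix_angle(v, u) == pytest.approx(interhelix_angle(u, v), abs=1e-12)
    rot = Rotation.random(random_state=int(seed))
    assert interhelix_angle(rot.apply(u), rot.apply(v)) == pytest.approx(
        interhelix_angle(u, v), abs=1e-8
    )


def test_interhelix_angle_zero_vector():
    with pytest.raises(ValueError):
        interhelix_angle([0, 0, 0], [1, 0, 0])


def test_subdomain_angle_equal_for_copies(domains, scaffold):
    p = extract_protomers(scaffold, {"A": "A"}, domains, "hydrolyzing")[0]
    q = extract_protomers(scaffold, {"A": "A"}, domains, "hydrolyzing")[0]
    assert subdomain_angle(p, domains) == pytest.approx(subdomain_angle(q, domains))


def test_subdomain_angle_recovers_planted_hinge(domains):
    """Rotating the small subdomain by a known hinge angle shifts the
    alpha3-alpha8 angle by that amount (noise-free construction)."""
    res = generate_ensemble(
        EnsembleSpec(
            n_clusters=2, protomers_per_cluster=3, hinge_angles_deg=(0.0, 15.0),
            coordinate_noise_sigma=0.0, seed=0,
        )
    )
    angles = {}
    for p in res.protomers:
        row = res.truth[
            (res.truth.model_id == p.model_id) & (res.truth.position == p.position_label)
        ].iloc[0]
        angles.setdefault(row.cluster, []).append(subdomain_angle(p, domains))
    delta = np.mean(angles[1]) - np.mean(angles[0])
    assert delta == pytest.approx(15.0, abs=0.5)


def test_subdomain_angle_missing_helix_names_range(domains, scaffold):
    p = extract_protomers(scaffold, {"A": "A"}, domains, "hydrolyzing")[0]
    for r in range(442, 453):
        p.calpha_coords.pop(r, None)
    with pytest.raises(ValueError, match="helix_a8"):
        subdomain_angle(p, domains)


def test_fit_plane_coplanar_points_zero_residual():
    pts = np.array([[0.0, 0, 1], [1, 0, 1], [0, 1, 1], [2, 3, 1]])
    fit = fit_plane(pts)
    assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(np.abs(fit.normal), [0, 0, 1], atol=1e-12)
    assert fit.offset == pytest.approx(fit.normal[2] * 1.0)


def test_fit_plane_symmetric_offsets_give_residual_d():
    # hexagon vertices offset alternately +-d: the offsets are orthogonal to
    # the in-plane coordinates, so the TLS plane is the hexagon plane and the
    # rms orthogonal residual is exactly d
    d = 0.75
    ang = np.radians(60.0 * np.arange(6))
    pts = np.column_stack(
        [2.0 * np.cos(ang), 2.0 * np.sin(ang), d * (-1.0) ** np.arange(6)]
    )
    assert fit_plane(pts).rms_residual == pytest.approx(d, abs=1e-12)


def test_fit_plane_collinear_errors():
    with pytest.raises(ValueError, match="collinear"):
        fit_plane(np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]]))


def test_fit_plane_rigid_motion_invariance(rng):
    pts = rng.normal(size=(10, 3))
    fit = fit_plane(pts)
    rot = Rotation.from_euler("zxz", [10.0, 60.0, -30.0], degrees=True)
    moved = fit_plane(rot.apply(pts) + np.array([3.0, -2.0, 9.0]))
    assert moved.rms_residual == pytest.approx(fit.rms_residual, abs=1e-9)
    assert abs(moved.normal @ rot.apply(fit.normal)) == pytest.approx(1.0, abs=1e-9)


def test_hexamer_ring_planes_are_flat(domains):
    model = make_hexamer_model(domains)
    protomers = extract_protomers(
        model, {c: c for c in "ABCDEF"}, domains, "hydrolyzing"
    )
    large = subdomain_centers_of_mass(protomers, domains, "large")
    small = subdomain_centers_of_mass(protomers, domains, "small")
    # identical protomers rotated about the ring axis: each tier's centers
    # are exactly coplanar
    assert fit_plane(large).rms_residual < 1e-6
    assert fit_plane(small).rms_residual < 1e-6
    # the combined fit quantifies the axial separation of the two tiers
    both = subdomain_centers_of_mass(protomers, domains, "both")
    assert both.shape == (12, 3)
    gap = abs(large[:, 2].mean() - small[:, 2].mean())
    assert fit_plane(both).rms_residual == pytest.approx(gap / 2.0, rel=1e-6)


def test_atom_distance_basics(domains, scaffold):
    sel = ("A", domains.named_residues["P262"], "CA")
    assert atom_distance(scaffold, sel, sel) == 0.0
    with pytest.raises(KeyError, match="999"):
        atom_distance(scaffold, sel, ("A", 999, "CA"))


def test_atom_distance_three_four_five():
    from ringscape import Atom, StructureModel

    model = StructureModel(
        "t",
        [
            Atom("A", 1, "GLY", "CA", np.array([0.0, 0, 0]), False),
            Atom("A", 2, "GLY", "CA", np.array([3.0, 4, 0]), False),
        ],
    )
    assert atom_distance(model, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(5.0)


def test_atom_distance_triangle_inequality(domains, scaffold):
    sels = [("A", r, "CA") for r in (262, 294, 374)]
    d01 = atom_distance(scaffold, sels[0], sels[1])
    d12 = atom_distance(scaffold, sels[1], sels[2])
    d02 = atom_distance(scaffold, sels[0], sels[2])
    assert d02 <= d01 + d12 + 1e-12


def test_distance_table_row_counts_and_apo(default_ensemble, domains):
    models = {m.model_id: m for m in default_ensemble.models}
    table = distance_distributions(default_ensemble.protomers, models, domains)
    n_prot = len(default_ensemble.protomers)
    assert len(table.rows) == n_prot * len(DEFAULT_PAIRS)  # all atoms present
    s = table.summaries()
    assert set(s.columns) == {"pair_label", "is_E", "mean", "sd", "n"}

    # an apo protomer contributes no Pbeta rows
    apo = generate_ensemble(
        EnsembleSpec(
            n_clusters=2, protomers_per_cluster=3, hinge_angles_deg=(0.0, 8.0),
            nucleotide_by_cluster=("apo", "ATP_Mg"), coordinate_noise_sigma=0.0, seed=0,
        )
    )
    models = {m.model_id: m for m in apo.models}
    t2 = distance_distributions(apo.protomers, models, apo.domains)
    apo_rows = t2.rows[t2.rows.nucleotide_state == "apo"]
    assert not apo_rows.pair_label.str.contains("Pbeta").any()


def test_welch_identical_samples_t_zero_p_one():
    rows = pd.DataFrame(
        {
            "model_id": ["m"] * 8,
            "position": ["E"] * 4 + ["A"] * 4,
            "pair_label": ["x"] * 8,
            "distance": [5.0, 6.0, 7.0, 8.0] * 2,
            "nucleotide_state": ["ATP"] * 8,
        }
    )
    out = compare_protomer_groups(DistanceTable(rows), "x")
    assert out.t.iloc[0] == pytest.approx(0.0)
    assert out.p.iloc[0] == pytest.approx(1.0)
    assert not out["significant_0.05"].iloc[0]


def test_welch_power_on_separated_groups(rng):
    """Groups of n=20 with means 3 sigma apart: p < 0.005 in >= 99% of
    seeded replicates."""
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(3.0, 1.0, 20)
        rows = pd.DataFrame(
            {
                "model_id": ["m"] * 40,
                "position": ["E"] * 20 + ["A"] * 20,
                "pair_label": ["x"] * 40,
                "distance": np.concatenate([a, b]),
                "nucleotide_state": ["ATP"] * 40,
            }
        )
        out = compare_protomer_groups(DistanceTable(rows), "x")
        hits += bool(out["significant_0.005"].iloc[0])
    assert hits / n_rep >= 0.99


def test_welch_matches_permutation_oracle_small_samples(rng):
    """On n <= 8 groups the Welch p-value tracks a studentized permutation
    test within small-sample discreteness error."""

    def welch_t(x, y, axis=-1):
        nx, ny = x.shape[axis], y.shape[axis]
        mx, my = x.mean(axis=axis), y.mean(axis=axis)
        vx, vy = x.var(axis=axis, ddof=1), y.var(axis=axis, ddof=1)
        return (mx - my) / np.sqrt(vx / nx + vy / ny)

    from scipy.stats import ttest_ind

    for shift in (0.0, 1.0, 2.0):
        x = rng.normal(0.0, 1.0, 8)
        y = rng.normal(shift, 1.5, 8)
        p_welch = ttest_ind(x, y, equal_var=False).pvalue
        oracle = permutation_test(
            (x, y), welch_t, permutation_type="independent", n_resamples=20_000,
            alternative="two-sided", vectorized=True, rng=np.random.default_rng(7),
        )
        assert p_welch == pytest.approx(oracle.pvalue, abs=0.06)


def test_welch_small_group_skipped_with_warning():
    rows = pd.DataFrame(
        {
            "model_id": ["m"] * 5,
            "position": ["E", "E", "E", "E", "A"],
            "pair_label": ["x"] * 5,
            "distance": [1.0, 2.0, 3.0, 4.0, 5.0],
            "nucleotide_state": ["ATP"] * 5,
        }
    )
    with pytest.warns(UserWarning, match="skipped"):
        out = compare_protomer_groups(DistanceTable(rows), "x")
    assert out.empty


def test_e_group_distances_significantly_closer(default_ensemble, domains):
    """The pre-hydrolysis (largest-hinge) cluster occupies ring position E
    with the nucleotide seated deeper: every E-vs-other comparison for the
    Sensor-1-to-Pbeta pair is significant."""
    models = {m.model_id: m for m in default_ensemble.models}
    table = distance_distributions(default_ensemble.protomers, models, domains)
    out = compare_protomer_groups(table, "N374-Pbeta")
    assert len(out) == 4  # E vs each other occupied position
    assert out["significant_0.05"].all()
    s = table.summaries()
    e_mean = s[(s.pair_label == "N374-Pbeta") & s.is_E]["mean"].iloc[0]
    o_mean = s[(s.pair_label == "N374-Pbeta") & ~s.is_E]["mean"].iloc[0]
    assert e_mean < o_mean


def test_export_attributes_formats(tmp_path):
    angles = {("A", i): 40.0 + i for i in range(6)}
    path = export_attributes(angles, tmp_path / "ang.txt", "subdomainAngle")
    lines = path.read_text().splitlines()
    assert lines[0] == "attribute: subdomainAngle"
    assert len([l for l in lines if l.startswith("\t")]) == 6

    per_chain = {c: float(i) for i, c in enumerate("ABCDEF")}
    path2 = export_attributes(per_chain, tmp_path / "ch.txt", "clusterLabel", recipient="chains")
    body = [l for l in path2.read_text().splitlines() if l.startswith("\t")]
    assert body == [f"\t/{c}\t{float(i)}" for i, c in enumerate("ABCDEF")]

    with pytest.raises(ValueError):
        export_attributes({1: 2.0}, tmp_path / "bad.txt", "x", recipient="residues")
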