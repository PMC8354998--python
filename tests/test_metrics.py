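"""Distance metrics: exact nearest point, both-way reports, curves, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import surfseed as ss
from surfseed.metrics import REF_TO_TEST, TEST_TO_REF, DistanceSamples

from conftest import make_grid, make_icosphere, oracle_closest_points


def samples_from(unsigned, signed=None):
    unsigned = np.asarray(unsigned, dtype=float)
    signed = unsigned if signed is None else np.asarray(signed, dtype=float)
    return DistanceSamples(
        source_points=np.zeros((len(unsigned), 3)),
        unsigned=unsigned, signed=signed,
        direction=np.zeros(len(unsigned), dtype=np.int8))


# -------------------------------------------------------- nearest point


def test_point_on_surface_distance_zero(icosphere):
    u, s, nearest = ss.point_to_surface_distance(icosphere.vertices[5], icosphere)
    assert u == pytest.approx(0, abs=1e-12)
    assert s == pytest.approx(0, abs=1e-12)


def test_point_above_triangle_interior():
    tri = ss.TriangleMesh(np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]]),
                          np.array([[0, 1, 2]]))
    u, s, nearest = ss.point_to_surface_distance(np.array([2.0, 2.0, 3.0]), tri)
    assert u == pytest.approx(3.0, abs=1e-12)
    assert s == pytest.approx(3.0, abs=1e-12)     # above = outward side
    np.testing.assert_allclose(nearest, [2, 2, 0], atol=1e-12)
    u2, s2, _ = ss.point_to_surface_distance(np.array([2.0, 2.0, -3.0]), tri)
    assert s2 == pytest.approx(-3.0, abs=1e-12)


def test_accelerated_equals_exhaustive_trimesh_scan():
    """Pruned nearest-point search agrees with an independent all-triangle
    scan (different kernel) to well below a nanometre."""
    rng = np.random.default_rng(7)
    mesh = make_icosphere(2, radius=10.0)   # 320 triangles
    pts = rng.uniform(-15, 15, size=(300, 3))
    query = ss.SurfaceDistanceQuery(mesh)
    unsigned, _, nearest = query.query(pts)
    d_oracle, p_oracle = oracle_closest_points(pts, mesh)
    np.testing.assert_allclose(unsigned, d_oracle, atol=1e-9)
    np.testing.assert_allclose(nearest, p_oracle, atol=1e-6)


# ----------------------------------------------------- both-way samples


def test_identical_meshes_all_zero(icosphere):
    samples = ss.both_way_distances(icosphere, icosphere)
    assert len(samples) == 2 * icosphere.n_vertices
    assert samples.unsigned.max() == 0
    report = ss.compute_report(samples)
    assert report.assd == 0 and report.max_error == 0


def test_parallel_sheets_constant_offset():
    a = make_grid(10)
    b = make_grid(10, z=0.5)
    samples = ss.both_way_distances(a, b)
    np.testing.assert_allclose(samples.unsigned, 0.5, atol=1e-12)
    assert samples.n_test_to_ref == a.n_vertices
    assert samples.n_ref_to_test == b.n_vertices


def test_protruding_bump_localises_error():
    base = make_grid(10)
    bumped_vertices = base.vertices.copy()
    center = np.flatnonzero((np.abs(base.vertices[:, 0] - 5) < 1.6)
                            & (np.abs(base.vertices[:, 1] - 5) < 1.6))
    bumped_vertices[center, 2] += 2.0
    bumped = ss.TriangleMesh(bumped_vertices, base.faces)
    samples = ss.both_way_distances(bumped, base)
    t2r = samples.unsigned[samples.direction == TEST_TO_REF]
    assert t2r[center].min() > 0
    far = np.linalg.norm(base.vertices[:, :2] - [5, 5], axis=1) > 4
    np.testing.assert_allclose(t2r[far], 0, atol=1e-12)
    # a bump is a protrusion: its signed distances are positive
    assert samples.signed[samples.direction == TEST_TO_REF][center].min() > 0


# ----------------------------------------------------------------- report


def test_report_hand_arithmetic():
    rep = ss.compute_report(samples_from([0, 0, 0, 1]), tolerance=0.2)
    assert rep.assd == pytest.approx(0.25)
    assert rep.rms == pytest.approx(0.5)
    assert rep.max_error == 1
    assert rep.pct_below_tolerance == pytest.approx(75.0)
    assert rep.aasd == pytest.approx(0.25)


def test_report_constant_distances():
    rep = ss.compute_report(samples_from(np.full(50, 0.3)), tolerance=0.2)
    for value in (rep.assd, rep.rms, rep.max_error, rep.p95):
        assert value == pytest.approx(0.3, abs=1e-12)
    assert rep.pct_below_tolerance == 0.0
    rep2 = ss.compute_report(samples_from(np.full(50, 0.1)), tolerance=0.2)
    assert rep2.pct_below_tolerance == 100.0


def test_report_matches_textbook_formulas():
    rng = np.random.default_rng(42)
    d = np.abs(rng.normal(0, 1.0, size=10_000))
    sgn = rng.choice([-1.0, 1.0], size=d.size)
    rep = ss.compute_report(samples_from(d, d * sgn), tolerance=0.2)
    assert rep.assd == pytest.approx(d.sum() / d.size, abs=1e-12)
    assert rep.aasd == pytest.approx((d * sgn).sum() / d.size, abs=1e-12)
    assert rep.rms == pytest.approx(np.sqrt((d ** 2).sum() / d.size), abs=1e-12)
    assert rep.max_error == d.max()
    srt = np.sort(d)
    rank = 0.95 * (d.size - 1)
    lo, frac = int(np.floor(rank)), rank - np.floor(rank)
    assert rep.p95 == pytest.approx(srt[lo] + frac * (srt[lo + 1] - srt[lo]), abs=1e-12)
    assert rep.pct_below_tolerance == pytest.approx(100.0 * (d < 0.2).sum() / d.size)


def test_empty_samples_rejected():
    with pytest.raises(ss.InvalidInputError):
        ss.compute_report(samples_from([]))
    with pytest.raises(ss.InvalidInputError):
        ss.cumulative_error_curve(samples_from([]))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
       st.floats(0.01, 5.0))
def test_pct_below_tolerance_monotone(dists, tol):
    s = samples_from(dists)
    lo = ss.compute_report(s, tolerance=tol).pct_below_tolerance
    hi = ss.compute_report(s, tolerance=tol * 2).pct_below_tolerance
    assert lo <= hi
    rep = ss.compute_report(s, tolerance=tol)
    assert 0 <= rep.assd <= rep.max_error + 1e-12
    assert rep.p95 <= rep.max_error + 1e-12


# ------------------------------------------------------------------ curve


def test_curve_constant_and_p95_consistency():
    s = samples_from(np.full(20, 0.7))
    curve = ss.cumulative_error_curve(s)
    np.testing.assert_allclose(curve[:, 1], 0.7)
    rng = np.random.default_rng(1)
    s2 = samples_from(rng.uniform(0, 3, 500))
    curve2 = ss.cumulative_error_curve(s2, percentiles=[0, 50, 95, 100])
    assert curve2[2, 1] == pytest.approx(ss.compute_report(s2).p95, abs=1e-12)
    assert np.all(np.diff(curve2[:, 1]) >= 0)


def test_curve_approximates_uniform_cdf():
    rng = np.random.default_rng(123)
    s = samples_from(rng.uniform(0, 1, 100_000))
    curve = ss.cumulative_error_curve(s, percentiles=np.arange(0, 101, 5))
    np.testing.assert_allclose(curve[:, 1], curve[:, 0] / 100.0, atol=0.01)


def test_curve_rejects_bad_percentiles():
    with pytest.raises(ss.InvalidInputError):
        ss.cumulative_error_curve(samples_from([1.0]), percentiles=[-5])


# -------------------------------------------------------------- partition


def test_partition_two_cubes_by_mid_plane(two_cubes):
    z_mid = np.mean(two_cubes.joint_zs)
    pos, neg = ss.partition_by_plane(two_cubes.mesh, (0, 0, z_mid), (0, 0, 1))
    labels = two_cubes.labels
    # everything strictly off the neck mid-plane splits by cube of origin
    off_plane = ~np.isclose(two_cubes.mesh.vertices[:, 2], z_mid)
    np.testing.assert_array_equal(pos[off_plane], labels[off_plane] == 2)
    # on-plane vertices go to the positive side
    assert pos[~off_plane].all()


def test_partition_degenerate_and_flip(icosphere):
    pos, neg = ss.partition_by_plane(icosphere, (0, 0, -5), (0, 0, 1))
    assert pos.all() and not neg.any()
    p1, n1 = ss.partition_by_plane(icosphere, (0, 0, 0), (0, 0, 1))
    p2, n2 = ss.partition_by_plane(icosphere, (0, 0, 0), (0, 0, -1))
    on_plane = np.isclose(icosphere.vertices[:, 2], 0)
    np.testing.assert_array_equal(p1[~on_plane], n2[~on_plane])
    with pytest.raises(ss.InvalidInputError):
        ss.partition_by_plane(icosphere, (0, 0, 0), (0, 0, 0))


def test_scale_equivariance(chain3):
    mesh = chain3.mesh
    noisy = ss.perturb_mesh(mesh, 0.3, random_seed=9)
    rep1 = ss.compute_report(ss.both_way_distances(noisy, mesh))
    scaled_a = ss.TriangleMesh(noisy.vertices * 3.0, noisy.faces)
    scaled_b = ss.TriangleMesh(mesh.vertices * 3.0, mesh.faces)
    rep3 = ss.compute_report(ss.both_way_distances(scaled_a, scaled_b))
    for attr in ("assd", "aasd", "rms", "max_error", "p95"):
        assert getattr(rep3, attr) == pytest.approx(3 * getattr(rep1, attr), rel=1e-9)


def test_symmetric_statistics(chain3):
    mesh = chain3.mesh
    noisy = ss.perturb_mesh(mesh, 0.2, random_seed=2)
    ab = ss.compute_report(ss.both_way_distances(noisy, mesh))
    ba = ss.compute_report(ss.both_way_distances(mesh, noisy))
    for attr in ("assd", "rms", "max_error", "p95"):
        assert getattr(ab, attr) == pytest.approx(getattr(ba, attr), abs=1e-12)


# -------------------------------------------------------------------- ICC


def test_icc_perfect_agreement():
    x = np.column_stack([[1, 2, 3, 4.0]] * 3)
    x[0, 0] += 1e-9  # avoid the zero-variance guard
    assert ss.icc(x) == pytest.approx(1.0, abs=1e-6)


def test_icc_shrout_fleiss_worked_table():
    """Classic 6-subject x 4-rater table; ICC(2,1) = 0.29, and the value must
    match an independent direct ANOVA recomputation to 1e-6."""
    x = np.array([[9, 2, 5, 8], [6, 1, 3, 2], [8, 4, 6, 8],
                  [7, 1, 2, 6], [10, 5, 6, 9], [6, 2, 4, 7]], dtype=float)
    value = ss.icc(x)
    assert value == pytest.approx(0.29, abs=0.005)

    # independent recomputation straight from sums of squares
    n, k = x.shape
    mean = x.mean()
    msr = (((x.mean(axis=1) - mean) ** 2).sum() * k) / (n - 1)
    msc = (((x.mean(axis=0) - mean) ** 2).sum() * n) / (k - 1)
    mse = (((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + mean) ** 2).sum()
           / ((n - 1) * (k - 1)))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert value == pytest.approx(expected, abs=1e-6)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, size=(8, 3)) + rng.normal(0, 2, size=(8, 1))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(8), 3),
        "rater": np.tile(np.arange(3), 8),
        "score": x.ravel(),
    })
    table = pg.intraclass_corr(df, "subject", "rater", "score")
    expected = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert ss.icc(x) == pytest.approx(expected, abs=1e-9)


def test_icc_sign_and_errors():
    r1 = np.array([-1.5, -0.5, 0.5, 1.5])
    assert ss.icc(np.column_stack([r1, -r1])) < 0
    with pytest.raises(ss.InvalidInputError):
        ss.icc(np.ones((4, 3)))
    with pytest.raises(ss.InvalidInputError):
        ss.icc(np.array([[1.0, 2.0]]))
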