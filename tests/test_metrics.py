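import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cuffshear as cs
from cuffshear.metrics import compute_base_metrics
from cuffshear.synthetic import radius_profile

from conftest import random_field


# ---------------------------------------------------------------------------
# Independent brute-force oracles: naive loops, no shared code with the
# implementation.
# ---------------------------------------------------------------------------

def _norm(v):
    return math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)


def oracle_tawss(vectors):
    out = []
    for node in vectors:
        out.append(sum(_norm(v) for v in node) / len(node))
    return out


def oracle_osi(vectors):
    out = []
    for node in vectors:
        total = [sum(v[i] for v in node) for i in range(3)]
        mags = sum(_norm(v) for v in node)
        out.append(0.5 * (1 - _norm(total) / mags) if mags > 0 else 0.0)
    return out


def oracle_rrt(vectors):
    out = []
    for node in vectors:
        mean = [sum(v[i] for v in node) / len(node) for i in range(3)]
        out.append(1.0 / _norm(mean) if _norm(mean) > 0 else float("inf"))
    return out


def oracle_tss(vectors, normals):
    out = []
    for node, n in zip(vectors, normals):
        mean = [sum(v[i] for v in node) / len(node) for i in range(3)]
        mn = _norm(mean)
        if mn == 0:
            out.append(0.0)
            continue
        p = [c / mn for c in mean]
        q = [n[1] * p[2] - n[2] * p[1],
             n[2] * p[0] - n[0] * p[2],
             n[0] * p[1] - n[1] * p[0]]
        qn = _norm(q)
        if qn == 0:
            out.append(0.0)
            continue
        q = [c / qn for c in q]
        out.append(sum(abs(v[0] * q[0] + v[1] * q[1] + v[2] * q[2])
                       for v in node) / len(node))
    return out


def oracle_sad(vectors, adjacency):
    n_nodes = len(vectors)
    n_t = len(vectors[0])
    out = []
    for j in range(n_nodes):
        total = 0.0
        for i in range(n_t):
            acc = 0.0
            for k in adjacency[j]:
                a, b = vectors[j][i], vectors[k][i]
                na, nb = _norm(a), _norm(b)
                if na == 0 or nb == 0:
                    continue
                cosang = (a[0] * b[0] + a[1] * b[1] + a[2] * b[2]) / (na * nb)
                acc += math.acos(max(-1.0, min(1.0, cosang)))
            total += acc / len(adjacency[j])
        out.append(total / n_t)
    return out


def _field(vectors):
    vectors = np.asarray(vectors, dtype=float)
    k = vectors.shape[1]
    times = np.arange(k) * (0.125 / k)
    return cs.WSSFieldSeries(vectors=vectors, times=times, period=0.125)


class TestOracleEquivalence:
    """All metrics match naive reimplementations on random small fields."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mesh = cs.build_tube_mesh(lambda s: np.full_like(s, 0.3), 2.0, 5, 6)
        assert mesh.n_nodes <= 50
        adjacency = cs.node_neighbors(mesh)
        vectors = rng.normal(0, 2.0, size=(mesh.n_nodes, 30, 3))
        field = _field(vectors)

        np.testing.assert_allclose(cs.tawss(field).values,
                                   oracle_tawss(vectors), atol=1e-10)
        np.testing.assert_allclose(cs.osi(field).values,
                                   oracle_osi(vectors), atol=1e-10)
        np.testing.assert_allclose(cs.rrt(field).values,
                                   oracle_rrt(vectors), atol=1e-10)
        np.testing.assert_allclose(
            cs.transwss(field, mesh.normals).values,
            oracle_tss(vectors, mesh.normals), atol=1e-10)
        adj_lists = [list(a) for a in adjacency]
        np.testing.assert_allclose(cs.sad(field, adjacency).values,
                                   oracle_sad(vectors, adj_lists), atol=1e-10)


class TestHandComputedExamples:
    def test_reversing_field_20_10(self):
        # 20 instants at (+1,0,0), 10 at (-1,0,0) Pa
        vectors = np.zeros((1, 30, 3))
        vectors[0, :20, 0] = 1.0
        vectors[0, 20:, 0] = -1.0
        field = _field(vectors)
        assert cs.tawss(field).values[0] == pytest.approx(1.0)
        assert cs.osi(field).values[0] == pytest.approx(1.0 / 3.0)
        assert cs.rrt(field).values[0] == pytest.approx(3.0)

    def test_constant_unidirectional(self):
        vectors = np.tile([2.0, 0.0, 0.0], (1, 30, 1))
        field = _field(vectors)
        assert cs.tawss(field).values[0] == pytest.approx(2.0)
        assert cs.osi(field).values[0] == pytest.approx(0.0)
        assert cs.rrt(field).values[0] == pytest.approx(0.5)

    def test_half_cycle_full_reversal_maximizes_osi(self):
        vectors = np.zeros((1, 30, 3))
        vectors[0, :15, 0] = 1.0
        vectors[0, 15:, 0] = -1.0
        assert cs.osi(_field(vectors)).values[0] == pytest.approx(0.5)

    def test_transverse_wss_perpendicular_switch(self):
        # 15 instants along x, 15 along y, normal z: tSS = 1/sqrt(2)
        vectors = np.zeros((1, 30, 3))
        vectors[0, :15, 0] = 1.0
        vectors[0, 15:, 1] = 1.0
        tss = cs.transwss(_field(vectors), np.array([[0.0, 0.0, 1.0]]))
        assert tss.values[0] == pytest.approx(1 / np.sqrt(2))

    def test_transverse_wss_zero_for_pure_reversal(self):
        vectors = np.zeros((1, 30, 3))
        vectors[0, ::2, 0] = 1.0
        vectors[0, 1::2, 0] = -0.5
        tss = cs.transwss(_field(vectors), np.array([[0.0, 0.0, 1.0]]))
        assert tss.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_sad_orthogonal_neighbor(self):
        vectors = np.zeros((2, 30, 3))
        vectors[0, :, 0] = 1.0
        vectors[1, :, 1] = 1.0
        adjacency = [np.array([1]), np.array([0])]
        vals = cs.sad(_field(vectors), adjacency).values
        np.testing.assert_allclose(vals, np.pi / 2)

    def test_sad_uniform_direction_is_zero(self):
        # spatially uniform direction, varying magnitude -> SAD 0 everywhere
        rng = np.random.default_rng(0)
        mags = rng.uniform(0.5, 2.0, size=(10, 30))
        vectors = mags[:, :, None] * np.array([1.0, 0.0, 0.0])
        adjacency = [np.array([(j + 1) % 10]) for j in range(10)]
        np.testing.assert_allclose(cs.sad(_field(vectors), adjacency).values,
                                   0.0, atol=1e-12)

    def test_sad_invariant_under_global_rotation(self):
        rng = np.random.default_rng(3)
        vectors = rng.normal(0, 1, size=(6, 10, 3))
        adjacency = [np.array([(j + 1) % 6]) for j in range(6)]
        base = cs.sad(_field(vectors), adjacency).values
        a = 0.7
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0],
                        [0, 0, 1.0]])
        rotated = cs.sad(_field(vectors @ rot.T), adjacency).values
        np.testing.assert_allclose(rotated, base, atol=1e-10)


class TestThresholds:
    def test_zero_spread_collapses_thresholds(self):
        thr = cs.fit_thresholds(cs.MetricMap("TAWSS", np.full(50, 1.5)))
        assert thr.low == pytest.approx(1.5)
        assert thr.high == pytest.approx(1.5)

    def test_log_normal_population_limit(self):
        rng = np.random.default_rng(12345)
        vals = np.exp(rng.normal(0.0, 1.0, size=10_000))
        thr = cs.fit_thresholds(cs.MetricMap("TAWSS", vals))
        assert thr.low == pytest.approx(np.exp(-0.67), rel=0.02)
        assert thr.high == pytest.approx(np.exp(0.67), rel=0.02)

    def test_low_threshold_isolates_bottom_quartile(self):
        rng = np.random.default_rng(999)
        vals = np.exp(rng.normal(0.0, 1.0, size=10_000))
        thr = cs.fit_thresholds(cs.MetricMap("TAWSS", vals))
        frac_low = np.mean(vals < thr.low)
        frac_high = np.mean(vals > thr.high)
        assert frac_low == pytest.approx(0.25, abs=0.02)
        assert frac_high == pytest.approx(0.25, abs=0.02)

    def test_geometric_symmetry_invariant(self):
        rng = np.random.default_rng(4)
        vals = np.exp(rng.normal(0.5, 0.3, size=200))
        thr = cs.fit_thresholds(cs.MetricMap("TAWSS", vals))
        assert thr.low * thr.high == pytest.approx(
            np.exp(2 * thr.source_mean_log), rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_scale_equivariance(self, k, seed):
        rng = np.random.default_rng(seed)
        vals = np.exp(rng.normal(0.0, 0.4, size=100))
        base = cs.fit_thresholds(cs.MetricMap("TAWSS", vals))
        scaled = cs.fit_thresholds(cs.MetricMap("TAWSS", k * vals))
        assert scaled.low == pytest.approx(k * base.low, rel=1e-9)
        assert scaled.high == pytest.approx(k * base.high, rel=1e-9)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            cs.fit_thresholds(cs.MetricMap("TAWSS", np.array([1.0, 0.0])))
        with pytest.raises(ValueError):
            cs.fit_thresholds(cs.MetricMap("TAWSS", np.array([1.0])))


class TestLsiHsi:
    def test_lsi_piecewise_linear(self):
        thr = cs.TawssThresholds(low=2.0, high=4.0, source_mean_log=0.0,
                                 source_sd_log=0.0)
        tmap = cs.MetricMap("TAWSS", np.array([2.0, 1.0, 3.0, 5.0]))
        np.testing.assert_allclose(cs.lsi(tmap, thr).values,
                                   [0.0, 0.5, 0.0, 0.0])

    def test_hsi_piecewise(self):
        thr = cs.TawssThresholds(low=2.0, high=4.0, source_mean_log=0.0,
                                 source_sd_log=0.0)
        tmap = cs.MetricMap("TAWSS", np.array([4.0, 8.0, 1.0, 4e6]))
        vals = cs.hsi(tmap, thr).values
        np.testing.assert_allclose(vals[:3], [0.0, 0.5, 0.0])
        assert 0.99 < vals[3] < 1.0  # asymptote toward 1, never reached

    def test_window_of_normal_wss(self):
        # between the thresholds both indices vanish
        thr = cs.TawssThresholds(low=2.0, high=4.0, source_mean_log=0.0,
                                 source_sd_log=0.0)
        tmap = cs.MetricMap("TAWSS", np.array([3.0]))
        assert cs.lsi(tmap, thr).values[0] == 0.0
        assert cs.hsi(tmap, thr).values[0] == 0.0

    def test_mutual_exclusivity_on_random_data(self):
        rng = np.random.default_rng(8)
        vals = np.exp(rng.normal(0.0, 1.0, size=500))
        tmap = cs.MetricMap("TAWSS", vals)
        thr = cs.fit_thresholds(tmap)
        product = cs.lsi(tmap, thr).values * cs.hsi(tmap, thr).values
        np.testing.assert_allclose(product, 0.0, atol=0)


class TestBoundsAndIdentities:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_metric_bounds_on_random_fields(self, seed):
        field = random_field(40, 30, seed)
        normals_rng = np.random.default_rng(seed + 1000)
        normals = normals_rng.normal(size=(40, 3))
        normals /= np.linalg.norm(normals, axis=1)[:, None]
        t = cs.tawss(field).values
        o = cs.osi(field).values
        ts = cs.transwss(field, normals).values
        assert np.all((o >= 0) & (o <= 0.5))
        assert np.all(ts <= t + 1e-12)
        assert np.all(t >= 0) and np.all(ts >= 0)

    def test_rrt_identity(self):
        field = random_field(40, 30, seed=21)
        r = cs.rrt(field).values
        mean_norm = np.linalg.norm(field.vectors.mean(axis=1), axis=1)
        np.testing.assert_allclose(r * mean_norm, 1.0, rtol=1e-9)

    def test_rrt_equals_osi_tawss_form(self):
        field = random_field(40, 30, seed=22)
        r = cs.rrt(field).values
        alt = 1.0 / ((1 - 2 * cs.osi(field).values) * cs.tawss(field).values)
        np.testing.assert_allclose(r, alt, rtol=1e-9)

    def test_tawss_homogeneity(self):
        field = random_field(20, 30, seed=23)
        scaled = cs.WSSFieldSeries(field.vectors * 3.0, field.times,
                                   field.period)
        np.testing.assert_allclose(cs.tawss(scaled).values,
                                   3.0 * cs.tawss(field).values, rtol=1e-12)

    def test_zero_field_conventions(self):
        field = _field(np.zeros((2, 30, 3)))
        assert np.all(cs.osi(field).values == 0.0)
        assert np.all(np.isinf(cs.rrt(field).values))
        assert np.all(cs.transwss(field, np.array([[0, 0, 1.0]] * 2)).values
                      == 0.0)


class TestRefinementStability:
    def test_export_stride_changes_metrics_by_under_two_percent(
            self, small_instr_spec):
        # Same field sampled at 300 vs 30 instants.  The reversal amplitude
        # is kept below the default so the neighbour-angle integrand stays
        # short of its 0 -> pi discontinuity limit, where no finite
        # sampling rate converges at this rate.
        disturbance = dataclasses.replace(small_instr_spec.disturbance,
                                          reversal_amplitude=0.8)
        spec300 = dataclasses.replace(small_instr_spec, export_every=1,
                                      heterogeneity_sigma_log=0.0,
                                      disturbance=disturbance)
        spec30 = dataclasses.replace(small_instr_spec, export_every=10,
                                     heterogeneity_sigma_log=0.0,
                                     disturbance=disturbance)
        maps = {}
        for tag, spec in (("300", spec300), ("30", spec30)):
            rp = radius_profile(spec)
            mesh = cs.build_tube_mesh(rp, spec.vessel_length_mm,
                                      spec.n_axial, spec.n_circ)
            frame = cs.parameterize(mesh)
            wf = cs.make_waveform(spec)
            field = cs.quasi_steady_wss(mesh, frame, rp, wf, cs.FluidProps(),
                                        spec)
            field = cs.apply_downstream_disturbance(field, frame, spec)
            maps[tag] = compute_base_metrics(field, mesh.normals,
                                             cs.node_neighbors(mesh))
        for metric in ("TAWSS", "OSI", "tSS", "SAD"):
            a = maps["30"][metric].values
            b = maps["300"][metric].values
            scale = np.abs(b).max()
            assert np.abs(a - b).max() <= 0.02 * scale


class TestNormalizeDisplay:
    def test_theoretical_maxima(self):
        assert cs.normalize_display(
            cs.MetricMap("OSI", np.array([0.5, 0.25]))).values[0] == 1.0
        assert cs.normalize_display(
            cs.MetricMap("SAD", np.array([np.pi / 2]))).values[0] == 0.5

    def test_rrt_uses_observed_max(self):
        m = cs.MetricMap("RRT", np.array([1.0, 4.0, np.inf]))
        out = cs.normalize_display(m, observed_max=4.0)
        np.testing.assert_allclose(out.values, [0.25, 1.0, 1.0])

    def test_missing_divisor_rejected(self):
        with pytest.raises(ValueError):
            cs.normalize_display(cs.MetricMap("TAWSS", np.array([1.0])))
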