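"""Vertex selection, smoothing, weighted GR extraction, reliability gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gammares.errors import DegenerateDataError, NoResponseError
from gammares.response import (
    GammaResponse,
    NormalizedSpectrum,
    average_and_smooth,
    moving_average,
    reliability_test,
    select_max_vertices,
    subject_gate,
    weighted_gr,
)
from gammares.spectral import VertexNormalizedSpectra


def vns_from(power_2d, freqs=None):
    power_2d = np.asarray(power_2d, dtype=float)
    if freqs is None:
        freqs = np.linspace(30, 115, power_2d.shape[1])
    return VertexNormalizedSpectra(freqs=np.asarray(freqs, dtype=float), norm_power=power_2d)


def spectrum_from(powers, freqs):
    return NormalizedSpectrum(
        freqs=np.asarray(freqs, dtype=float),
        norm_power=np.asarray(powers, dtype=float),
        selected_vertices=np.array([0]),
    )


class TestSelectMaxVertices:
    def test_k_exceeds_supply_returns_all(self, rng):
        vns = vns_from(rng.normal(size=(10, 40)))
        assert list(select_max_vertices(vns, k=26)) == list(range(10))

    def test_band_mean_ranking_with_tie(self):
        # flat per-vertex spectra with band means [0.1, 0.9, 0.5, 0.9, 0.2]
        vals = [0.1, 0.9, 0.5, 0.9, 0.2]
        vns = vns_from(np.repeat(np.array(vals)[:, None], 50, axis=1))
        assert list(select_max_vertices(vns, k=2)) == [1, 3]

    def test_identical_vertices_tie_break_by_index(self, rng):
        row = rng.normal(size=40)
        vns = vns_from(np.repeat(row[None, :], 8, axis=0))
        assert list(select_max_vertices(vns, k=3)) == [0, 1, 2]

    def test_agrees_with_brute_force_on_random_spectra(self, rng):
        for _ in range(200):
            vns = vns_from(rng.normal(size=(rng.integers(2, 40), 60)))
            k = int(rng.integers(1, 30))
            got = list(select_max_vertices(vns, k=k))
            m = (vns.freqs >= 40) & (vns.freqs <= 80)
            means = vns.norm_power[:, m].mean(axis=1)
            # brute force: sort by (-mean, index), take first k, report sorted
            expect = sorted(sorted(range(len(means)), key=lambda i: (-means[i], i))[:k])
            assert got == expect

    def test_empty_band_rejected(self, rng):
        vns = vns_from(rng.normal(size=(3, 10)), freqs=np.linspace(100, 110, 10))
        with pytest.raises(ValueError):
            select_max_vertices(vns, band=(40.0, 80.0))


class TestSmoothing:
    def test_constant_preserved_including_edges(self):
        x = np.full(11, 3.25)
        np.testing.assert_allclose(moving_average(x), 3.25)

    def test_hand_computed_values(self):
        assert moving_average(np.array([0.0, 3.0, 0.0]))[1] == pytest.approx(1.0)
        assert moving_average(np.array([6.0, 3.0, 0.0, 1.0]))[0] == pytest.approx(4.5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0), window=4)

    def test_average_and_smooth_restricts_to_gamma_range(self, rng):
        vns = vns_from(rng.normal(size=(6, 200)), freqs=np.linspace(0, 250, 200))
        out = average_and_smooth(vns, [0, 2, 4])
        assert out.freqs.min() >= 30.0 and out.freqs.max() <= 115.0


class TestWeightedGR:
    def test_hand_computed_oracle(self):
        sp = spectrum_from([1, 2.5, 3, 2.5, 1], [40, 45, 50, 55, 60])
        wp, wf, pf, pp = weighted_gr(sp)
        assert wp == pytest.approx(8 / 3)
        assert wf == pytest.approx(50.0)
        assert (pf, pp) == (50.0, 3.0)

    def test_singleton_selection(self):
        sp = spectrum_from([0.1, 3.0, 0.2, 1.9], [40, 50, 60, 70])
        wp, wf, pf, pp = weighted_gr(sp)
        assert wp == pytest.approx(3.0) and wf == pytest.approx(50.0)

    def test_symmetric_spectrum_weighted_freq_equals_peak(self):
        f = np.linspace(40, 70, 31)
        p = np.exp(-((f - 55.0) ** 2) / 30.0)
        wp, wf, pf, pp = weighted_gr(spectrum_from(p, f))
        assert wf == pytest.approx(pf)

    def test_no_positive_peak_rejected(self):
        with pytest.raises(NoResponseError):
            weighted_gr(spectrum_from([-1.0, -0.5, -0.2], [40, 50, 60]))

    def test_agrees_with_brute_force_on_random_spectra(self, rng):
        # oracle: explicit loop over bins, strict > 2/3 threshold
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            f = np.sort(rng.uniform(30, 115, n))
            p = rng.normal(0.5, 1.0, n)
            sp = spectrum_from(p, f)
            inband = [(fi, pi) for fi, pi in zip(f, p) if 35 <= fi <= 90]
            if not inband or max(pi for _, pi in inband) <= 0:
                with pytest.raises(NoResponseError):
                    weighted_gr(sp)
                continue
            wp, wf, pf, pp = weighted_gr(sp)
            peak = max(pi for _, pi in inband)
            sel = [(fi, pi) for fi, pi in inband if pi > 2 / 3 * peak]
            assert wp == pytest.approx(sum(pi for _, pi in sel) / len(sel))
            assert wf == pytest.approx(sum(fi * pi for fi, pi in sel) / sum(pi for _, pi in sel))
            assert 2 / 3 * pp < wp <= pp

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    def test_scaling_property(self, seed, c):
        # positive gain scales weighted power, leaves frequencies unchanged
        rng = np.random.default_rng(seed)
        f = np.linspace(35, 90, 25)
        p = rng.uniform(0.01, 2.0, 25)
        a = weighted_gr(spectrum_from(p, f))
        b = weighted_gr(spectrum_from(c * p, f))
        assert b[0] == pytest.approx(c * a[0], rel=1e-9)
        assert b[1] == pytest.approx(a[1], rel=1e-9)
        assert b[2] == a[2]


class TestReliability:
    def test_exact_extreme_tail_n30(self):
        d = np.arange(1.0, 31.0)
        p, reliable = reliability_test(np.zeros(30), d)
        assert p == pytest.approx(2 * 2.0**-30, rel=1e-12)
        assert reliable

    def test_exact_extreme_tail_n10_not_reliable(self):
        d = np.arange(1.0, 11.0)
        p, reliable = reliability_test(np.zeros(10), d)
        assert p == pytest.approx(2 / 1024, rel=1e-12)
        assert not reliable  # 0.00195 >= 1e-4

    def test_symmetry_under_exchange(self, rng):
        b = rng.uniform(0, 1, 20)
        s = b + rng.normal(0.3, 0.5, 20)
        p1, _ = reliability_test(b, s)
        p2, _ = reliability_test(s, b)
        assert p1 == pytest.approx(p2)

    def test_all_zero_differences_rejected(self):
        x = np.ones(10)
        with pytest.raises(DegenerateDataError):
            reliability_test(x, x.copy())

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            reliability_test(np.zeros(10), np.ones(11))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            reliability_test(np.zeros(5), np.ones(5))


def _resp(condition, power, reliable, velocity=0.0, visit=0):
    return GammaResponse(condition, velocity, power, 55.0, 55.0, power, 1e-6 if reliable else 1e-3, reliable, visit)


class TestSubjectGate:
    def test_included_when_max_condition_reliable_both_visits(self):
        visits = {
            0: {"static": _resp("static", 1.0, False), "slow": _resp("slow", 3.0, True)},
            1: {"static": _resp("static", 1.1, False), "slow": _resp("slow", 2.5, True)},
        }
        assert subject_gate(visits)

    def test_excluded_when_one_visit_unreliable(self):
        visits = {
            0: {"static": _resp("static", 1.0, True), "slow": _resp("slow", 3.0, True)},
            1: {"static": _resp("static", 1.0, True), "slow": _resp("slow", 3.0, False)},
        }
        assert not subject_gate(visits)

    def test_max_condition_may_differ_between_visits(self):
        # per-visit maximum rule: slow max in visit 0, medium max in visit 1
        visits = {
            0: {"slow": _resp("slow", 3.0, True), "medium": _resp("medium", 2.0, False)},
            1: {"slow": _resp("slow", 2.0, False), "medium": _resp("medium", 3.0, True)},
        }
        assert subject_gate(visits)

    def test_mismatched_condition_sets_rejected(self):
        visits = {
            0: {"slow": _resp("slow", 3.0, True)},
            1: {"medium": _resp("medium", 3.0, True)},
        }
        with pytest.raises(ValueError):
            subject_gate(visits)

    def test_all_no_response_excluded(self):
        visits = {0: {"slow": GammaResponse.no_response("slow", 1.2)}}
        assert not subject_gate(visits)
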