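"""PLF, Rayleigh Z, circular means, Watson U^2, PTR and rose histograms."""

import numpy as np
import pytest
from scipy import special

from phaseloop import (
    circular_mean,
    plf,
    ptr,
    rayleigh_critical,
    recenter,
    rose_histogram,
    summarize,
    watson_critical,
    watson_u2,
    wrap_phase,
    zplf,
    zplf_all,
)
from phaseloop.datasets import RESTING
from phaseloop.errors import (
    EmptyResultError,
    LengthError,
    ParameterError,
    UndefinedMeanError,
)


def watson_u2_pointwise(a, b):
    """Naive per-point Watson U^2 (no tie grouping) for untied samples."""
    a, b = np.asarray(a), np.asarray(b)
    n, m = a.size, b.size
    big_n = n + m
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.ones(n), np.zeros(m)])
    order = np.argsort(pooled)
    from_a = labels[order]
    i = np.cumsum(from_a)
    j = np.cumsum(1 - from_a)
    d = i / n - j / m
    return (n * m) / big_n**2 * (np.sum(d**2) - np.sum(d) ** 2 / big_n)


class TestPLF:
    def test_identical_phases_give_unity(self):
        assert plf(np.full(50, 1.3)) == pytest.approx(1.0)

    def test_antipodal_pair_cancels(self):
        assert plf([0.0, np.pi]) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_for_random_samples(self, rng):
        for _ in range(20):
            r = plf(rng.uniform(-np.pi, np.pi, rng.integers(1, 200)))
            assert 0.0 <= r <= 1.0

    def test_von_mises_resultant_matches_bessel_ratio(self, rng):
        """Monte-Carlo resultant length vs the closed form I1(k)/I0(k)."""
        kappa = 2.0
        draws = rng.vonmises(0.0, kappa, 10_000)
        expected = special.iv(1, kappa) / special.iv(0, kappa)
        assert plf(draws) == pytest.approx(expected, abs=0.02)

    def test_empty_sample_raises(self):
        with pytest.raises(LengthError):
            plf([])


class TestZPLF:
    def test_direct_formula(self):
        assert zplf(100, 0.3) == pytest.approx(9.0)
        assert zplf(1234, 0.0) == 0.0

    def test_published_row_consistent_with_rounded_plf(self):
        """n = 3491, PLF printed as 0.104 -> Z = 37.76, within 0.2 of the
        published 37.831 (which used the unrounded PLF)."""
        n = RESTING["n_trials"][("yw", "peak")][1]
        r = RESTING["plf"][("yw", "peak")][1]
        z = RESTING["zplf"][("yw", "peak")][1]
        assert zplf(n, r) == pytest.approx(z, abs=0.2)

    def test_zplf_all_of_single_value_is_identity(self):
        assert zplf_all([4.25]) == 4.25

    def test_zplf_all_empty_raises(self):
        with pytest.raises(LengthError):
            zplf_all([])

    def test_summarize_invariant(self, rng):
        phases = rng.vonmises(1.0, 1.5, 300)
        s = summarize(phases)
        assert s.zplf == pytest.approx(s.n * s.plf**2, rel=1e-12)
        assert -np.pi < s.mean_angle <= np.pi


class TestRayleighCritical:
    def test_alpha_point_05(self):
        assert rayleigh_critical(0.05) == pytest.approx(-np.log(0.05))

    def test_alpha_one_gives_zero(self):
        assert rayleigh_critical(1.0) == 0.0

    def test_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            rayleigh_critical(0.0)
        with pytest.raises(ParameterError):
            rayleigh_critical(1.5)


class TestCircularMean:
    def test_repeated_angle(self):
        assert circular_mean([np.pi / 2, np.pi / 2]) == pytest.approx(np.pi / 2)

    def test_wraps_around_pi(self):
        assert circular_mean([3.1, -3.1]) == pytest.approx(np.pi, abs=1e-9)

    def test_antipodal_pair_undefined(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean([0.5, 0.5 - np.pi])

    def test_recenter_single_angle(self):
        assert recenter([1.2]) == pytest.approx([0.0])

    def test_recentered_sample_has_zero_mean_direction(self, rng):
        phases = rng.vonmises(2.5, 1.0, 500)
        centered = recenter(phases)
        z = np.mean(np.exp(1j * centered))
        assert abs(np.angle(z)) < 1e-9


class TestWatsonU2:
    def test_hand_enumerated_example(self):
        res = watson_u2([0.1, 1.0], [0.5, 2.0])
        assert res.u2 == pytest.approx(0.0625)
        assert not res.significant

    def test_matches_pointwise_formula_without_ties(self, rng):
        a = rng.uniform(-np.pi, np.pi, 37)
        b = rng.uniform(-np.pi, np.pi, 51)
        assert watson_u2(a, b).u2 == pytest.approx(watson_u2_pointwise(a, b), rel=1e-12)

    def test_symmetry(self, rng):
        a = rng.vonmises(0.0, 1.0, 40)
        b = rng.vonmises(0.5, 2.0, 60)
        assert watson_u2(a, b).u2 == pytest.approx(watson_u2(b, a).u2, rel=1e-12)

    def test_joint_rotation_invariance(self, rng):
        a = rng.vonmises(0.0, 1.0, 40)
        b = rng.vonmises(0.5, 2.0, 60)
        base = watson_u2(a, b).u2
        for shift in rng.uniform(-np.pi, np.pi, 5):
            rotated = watson_u2(wrap_phase(a + shift), wrap_phase(b + shift)).u2
            assert rotated == pytest.approx(base, abs=1e-9)

    def test_recentering_then_rotating_is_stable(self, rng):
        """Recentered samples give a rotation-invariant variance comparison."""
        a = rng.vonmises(0.0, 1.0, 30)
        b = rng.vonmises(1.0, 3.0, 30)
        base = watson_u2(recenter(a), recenter(b)).u2
        for shift in rng.uniform(-np.pi, np.pi, 5):
            again = watson_u2(
                recenter(wrap_phase(a + shift)), recenter(wrap_phase(b + shift))
            ).u2
            assert again == pytest.approx(base, abs=1e-9)

    def test_tied_values_grouped(self):
        """Ties advance both cumulative counts before d is recorded."""
        a = [0.5, 0.5, 1.0]
        b = [0.5, 2.0]
        res = watson_u2(a, b)
        # hand enumeration: groups (0.5 x3: i=2/3, j=1/2 -> d=1/6, weight 3),
        # (1.0: i=1, j=1/2 -> d=1/2), (2.0: d=0)
        d_vals = np.array([1 / 6, 1 / 6, 1 / 6, 1 / 2, 0.0])
        expect = (3 * 2) / 25 * (np.sum(d_vals**2) - np.sum(d_vals) ** 2 / 5)
        assert res.u2 == pytest.approx(expect, rel=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(LengthError):
            watson_u2([], [0.1])


class TestWatsonCritical:
    def test_published_level(self):
        assert round(watson_critical(0.05), 3) == 0.187

    def test_one_percent_level_from_series_inversion(self):
        assert round(watson_critical(0.01), 3) == 0.268

    def test_monotone_decreasing_in_alpha(self):
        assert watson_critical(0.01) > watson_critical(0.05) > watson_critical(0.2)

    def test_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            watson_critical(0.7)


class TestPTR:
    def test_identical_epochs_average_to_the_epoch(self):
        period = np.cos(2 * np.pi * np.arange(2500) / 250.0)
        events = [600, 850, 1100, 1350]  # 250-sample spacing: identical epochs
        res = ptr(period, events, fs=500.0, half_window=500)
        assert res.waveform.size == 1001
        assert res.n_trials == 4
        epoch = period[100:1101]
        assert np.allclose(res.waveform, epoch, atol=1e-12)

    def test_edge_events_excluded_and_counted(self):
        x = np.zeros(3000)
        res = ptr(x, [10, 1500, 2995], fs=500.0, half_window=500)
        assert res.n_trials == 1
        assert res.n_excluded == 2

    def test_no_usable_events_raises(self):
        with pytest.raises(EmptyResultError):
            ptr(np.zeros(800), [100], fs=500.0, half_window=500)


class TestRoseHistogram:
    def test_total_count_conserved(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 999)
        edges, counts = rose_histogram(phases, bins=24)
        assert edges.size == 25
        assert counts.sum() == 999
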