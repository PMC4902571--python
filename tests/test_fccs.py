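"""PIE gating, multi-tau correlation, diffusion fitting, f_c and
population statistics."""

import numpy as np
import pytest

from oligocount import fccs, synthetic
from oligocount.containers import GREEN, RED, PhotonStream


def make_stream(times, micro, origin, channel=RED):
    return PhotonStream(
        arrival_times=np.asarray(times, dtype=float),
        microtimes=np.asarray(micro, dtype=float),
        pulse_origin=np.asarray(origin),
        channel=channel,
        meta={"duration": 1.0},
    )


def direct_multi_tau(a, b, bin_width, m, max_lag):
    """Independent brute-force oracle implementing the same estimator
    definition with explicit Python loops."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    lags, G = [], []
    dt = bin_width
    level = 0
    while True:
        k_range = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        done = False
        for k in k_range:
            tau = k * dt
            if tau > max_lag or k >= len(a):
                done = True
                break
            n = len(a) - k
            num = sum(a[i] * b[i + k] for i in range(n)) / n
            mean_a = sum(a[:n]) / n
            mean_b = sum(b[k:]) / n
            G.append(num / (mean_a * mean_b) - 1.0)
            lags.append(tau)
        if done or len(a) < 4 * m:
            break
        even = (len(a) // 2) * 2
        a = [a[i] + a[i + 1] for i in range(0, even, 2)]
        b = [b[i] + b[i + 1] for i in range(0, even, 2)]
        dt *= 2
        level += 1
    return np.array(lags), np.array(G)


class TestGatePhotons:
    def test_gating_rules(self, small_pie):
        # red photons: 20 ns after a 488 pulse -> rejected; 20 ns after a
        # 561 pulse -> kept
        red = make_stream([0.1, 0.2], [20.0, 20.0], [488, 561])
        green = make_stream([0.15], [3.0], [488], channel=GREEN)
        traces = fccs.gate_photons(green, red, small_pie, bin_width=0.5, duration=1.0)
        assert traces.rejected_counts[RED] == 1
        assert traces.red.sum() == 1
        assert traces.green.sum() == 1

    def test_crosstalk_removed_from_simulation(self, small_pie):
        cfg = synthetic.MembraneSimConfig(
            species=[synthetic.SpeciesConfig()],
            co_diffusing_fraction=0.0,
            duration=3.0,
            crosstalk=0.10,
            background_rate=(0.0, 0.0),
        )
        green, red, truth = synthetic.simulate_dual_color_streams(cfg, small_pie, seed=2)
        assert truth["n_crosstalk_red"] > 0
        ct = red.labels == synthetic.LABEL_CROSSTALK
        reject = (red.pulse_origin == 488) & (red.microtimes < small_pie.gate_window)
        # every crosstalk photon lies inside the gate and is removed
        assert np.all(reject[ct])
        traces = fccs.gate_photons(green, red, small_pie, duration=3.0)
        assert traces.rejected_counts[RED] >= int(ct.sum())
        assert traces.red.sum() <= red.n_photons - ct.sum()

    def test_codiffusing_traces_correlate(self, small_pie):
        cfg = synthetic.MembraneSimConfig(
            species=[synthetic.SpeciesConfig()],
            co_diffusing_fraction=1.0,
            duration=10.0,
            background_rate=(0.0, 0.0),
        )
        green, red, _ = synthetic.simulate_dual_color_streams(cfg, small_pie, seed=3)
        traces = fccs.gate_photons(green, red, small_pie, bin_width=1e-3, duration=10.0)
        r = np.corrcoef(traces.green, traces.red)[0, 1]
        assert r > 0.5


class TestMultiTau:
    def test_constant_signal_no_fluctuations(self):
        a = np.full(4096, 7.0)
        curve = fccs.multi_tau_correlate(a, a, 1e-4, m=16, max_lag=0.05)
        assert np.allclose(curve.G, 0.0, atol=1e-12)

    def test_matches_direct_sum_oracle(self, rng):
        """Optimized correlator equals the brute-force O(n^2) oracle to
        1e-12 on a 10^4-bin Poisson trace, auto and cross."""
        a = rng.poisson(3.0, size=10_000).astype(float)
        b = rng.poisson(2.0, size=10_000).astype(float)
        for x, y in ((a, a), (a, b)):
            curve = fccs.multi_tau_correlate(x, y, 1e-4, m=16, max_lag=0.08)
            lags_o, G_o = direct_multi_tau(x, y, 1e-4, 16, 0.08)
            assert np.allclose(curve.lags, lags_o, atol=0)
            assert np.allclose(curve.G, G_o, atol=1e-12)
        # white noise: G at positive lags consistent with zero
        curve = fccs.multi_tau_correlate(a, a, 1e-4, m=16, max_lag=0.08)
        assert np.abs(curve.G).max() < 0.1

    def test_amplitude_tracks_occupancy(self, small_pie):
        """G_gg(0) ~ 1/N for N particles in the observation area."""
        density = 5.0 / (np.pi * 0.25**2)  # N_eff = 5
        cfg = synthetic.MembraneSimConfig(
            species=[synthetic.SpeciesConfig(density=density)],
            co_diffusing_fraction=0.0,
            duration=20.0,
            background_rate=(0.0, 0.0),
        )
        green, red, truth = synthetic.simulate_dual_color_streams(cfg, small_pie, seed=4)
        traces = fccs.gate_photons(green, red, small_pie, duration=20.0)
        curve = fccs.multi_tau_correlate(traces.green, traces.green, 2e-4, 16, 0.5)
        fit = fccs.fit_2d_diffusion(curve.lags, curve.G, 0.25)
        assert truth["n_in_focus_green"] == pytest.approx(5.0, rel=0.01)
        assert fit.G0 == pytest.approx(0.2, rel=0.25)

    def test_zero_mean_trace_rejected(self):
        z = np.zeros(4096)
        with pytest.raises(ValueError):
            fccs.multi_tau_correlate(z, z, 1e-4)

    def test_decay_time_scales_inversely_with_D(self, small_pie):
        """Autocorrelation half-decay lag halves when D doubles."""
        halves = []
        for D in (0.25, 0.5):
            cfg = synthetic.MembraneSimConfig(
                species=[synthetic.SpeciesConfig(diffusion_coeff=D)],
                co_diffusing_fraction=0.0,
                duration=30.0,
                background_rate=(0.0, 0.0),
            )
            green, red, _ = synthetic.simulate_dual_color_streams(
                cfg, small_pie, seed=8
            )
            traces = fccs.gate_photons(green, red, small_pie, duration=30.0)
            curve = fccs.multi_tau_correlate(traces.green, traces.green, 2e-4, 16, 1.0)
            fit = fccs.fit_2d_diffusion(curve.lags, curve.G, 0.25)
            halves.append(fit.tau_D)
        assert halves[0] / halves[1] == pytest.approx(2.0, rel=0.4)
        # closed form: tau_D = w^2/(4D) = 31 ms at D = 0.5
        assert halves[1] == pytest.approx(0.25**2 / (4 * 0.5), rel=0.35)


class TestFit2DDiffusion:
    def test_exact_curve_inverted(self):
        lags = np.geomspace(2e-4, 1.0, 80)
        G = 0.2 / (1 + lags / 0.031)
        fit = fccs.fit_2d_diffusion(lags, G, waist=0.25)
        assert fit.G0 == pytest.approx(0.2, rel=1e-6)
        assert fit.tau_D == pytest.approx(0.031, rel=1e-6)
        assert fit.D == pytest.approx(0.25**2 / (4 * 0.031), rel=1e-6)

    def test_non_decaying_curve_flagged(self):
        lags = np.geomspace(2e-4, 1.0, 40)
        fit = fccs.fit_2d_diffusion(lags, np.full(40, 0.01), waist=0.25)
        assert not fit.ok
        assert np.isnan(fit.D)

    def test_fixed_tau_amplitude_fit(self):
        lags = np.geomspace(2e-4, 1.0, 60)
        G = 0.05 / (1 + lags / 0.04) - 0.002
        fit = fccs.fit_2d_diffusion(lags, G, waist=0.25, fix_tau=0.04)
        assert fit.G0 == pytest.approx(0.05, rel=1e-6)
        assert fit.offset == pytest.approx(-0.002, abs=1e-9)


class TestFractionCorrelated:
    def test_full_overlap(self):
        fc, flags = fccs.fraction_correlated(0.2, 0.2, 0.2)
        assert fc == pytest.approx(1.0)
        assert not flags

    def test_independent_species(self):
        fc, flags = fccs.fraction_correlated(-0.001, 0.2, 0.25)
        assert fc == 0.0
        assert "negative_cross_amplitude" in flags

    def test_max_denominator_uses_larger_auto(self):
        fc, _ = fccs.fraction_correlated(0.05, 0.1, 0.2)
        assert fc == pytest.approx(0.25)

    def test_undefined_when_auto_nonpositive(self):
        fc, flags = fccs.fraction_correlated(0.05, 0.0, 0.2)
        assert np.isnan(fc)
        assert flags == ["undefined_autocorrelation"]


class TestAnalyzeCell:
    def test_five_segment_protocol_runs(self, small_pie):
        cfg = synthetic.MembraneSimConfig(
            species=[synthetic.SpeciesConfig()],
            co_diffusing_fraction=0.5,
            duration=75.0,
        )
        green, red, _ = synthetic.simulate_dual_color_streams(cfg, small_pie, seed=10)
        cell = fccs.analyze_cell(green, red, small_pie, waist=0.25)
        assert len(cell.segment_fc) == 5
        assert 0.2 < cell.f_c < 0.8
        assert 0.1 < cell.D_green < 1.0

    def test_short_acquisition_warns(self, small_pie):
        cfg = synthetic.MembraneSimConfig(
            species=[synthetic.SpeciesConfig()],
            co_diffusing_fraction=0.0,
            duration=30.0,
        )
        green, red, _ = synthetic.simulate_dual_color_streams(cfg, small_pie, seed=11)
        with pytest.warns(UserWarning, match="segments"):
            cell = fccs.analyze_cell(green, red, small_pie, waist=0.25)
        assert "short_acquisition" in cell.flags


class TestPopulation:
    @staticmethod
    def cells_from(values):
        return [
            fccs.CellSummary(f_c=v, D_green=0.4, D_red=0.4, segment_fc=[v] * 5)
            for v in values
        ]

    def test_identical_cells(self):
        pop = fccs.summarize_population(self.cells_from([0.2] * 6))
        assert pop["f_c"]["median"] == 0.2
        assert pop["f_c"]["q75"] - pop["f_c"]["q25"] == 0.0

    def test_outlier_flagged(self):
        vals = [0.10, 0.11, 0.12, 0.13, 0.14, 0.15, 0.16, 0.90]
        pop = fccs.summarize_population(self.cells_from(vals))
        assert 0.90 in pop["f_c"]["outliers"]

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            fccs.summarize_population(self.cells_from([0.1] * 4))

    def test_dimer_vs_multimer_conditions_significant(self, rng):
        """30 cells/condition at true f_c 0.13 vs 0.19 separate at
        p < 0.001 by the two-sample t test."""
        a = self.cells_from(rng.normal(0.13, 0.02, size=30))
        b = self.cells_from(rng.normal(0.19, 0.02, size=30))
        res = fccs.compare_populations(a, b)
        assert res["p_value"] < 1e-3
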