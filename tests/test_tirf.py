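"""Spot detection, filtering, trace extraction and step counting."""

import numpy as np
import pytest

from oligocount import synthetic, tirf
from oligocount.containers import FluorescenceTrace, ImageStack
from oligocount.pipeline import make_acquisition


def staircase(levels, seg_len=100, noise_sd=0.0, rng=None):
    y = np.concatenate([np.full(seg_len, lv, dtype=float) for lv in levels])
    if noise_sd and rng is not None:
        y = y + rng.normal(0, noise_sd, y.size)
    return FluorescenceTrace(spot_id=0, intensities=y, frame_rate=20.0)


class TestDetectSpots:
    def test_pure_noise_yields_no_candidates(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stack = ImageStack(
                frames=rng.normal(0, 3.0, size=(60, 48, 48)),
                pixel_size=0.16,
                frame_rate=20.0,
            )
            hits += len(tirf.detect_spots(stack, psf_sigma=0.15, threshold_sd=5)) > 0
        assert hits == 0

    def test_subdiffraction_pair_is_one_candidate(self):
        acq = synthetic.AcquisitionParams(
            field_size=(4.8, 4.8), n_frames=60, unit_brightness=400.0,
            noise_model=synthetic.NoiseModel(read_sd=2.0, shot=False),
        )
        far = np.array([10_000])
        pair = [
            synthetic.SpotAssembly((2.4, 2.4), 1, np.array([True]), far),
            synthetic.SpotAssembly((2.45, 2.4), 1, np.array([True]), far),
        ]
        stack = synthetic.render_movie(pair, acq, seed=1)
        cands = tirf.detect_spots(stack, psf_sigma=acq.psf_sigma, threshold_sd=5)
        assert len(cands) == 1

    def test_short_stack_rejected(self):
        stack = ImageStack(np.zeros((10, 32, 32)), 0.16, 20.0)
        with pytest.raises(ValueError):
            tirf.detect_spots(stack, psf_sigma=0.15)


class TestFilterSpots:
    @staticmethod
    def cand(sid, x, y, peak=100.0, width=0.15):
        return tirf.SpotCandidate(sid, (x / 0.16, y / 0.16), (x, y), peak, width)

    def test_close_pair_both_rejected(self):
        cands = [self.cand(0, 1.0, 1.0), self.cand(1, 1.3, 1.0), self.cand(2, 5.0, 5.0)]
        accepted, rejected = tirf.filter_spots(cands, min_separation=0.5)
        assert [c.spot_id for c in accepted] == [2]
        assert all(reason == "overlapping" for _, reason in rejected)

    def test_bright_outlier_rejected(self):
        cands = [self.cand(i, 1.0 + i, 1.0, peak=100 + i) for i in range(8)]
        cands.append(self.cand(9, 1.0, 5.0, peak=5000.0))
        accepted, rejected = tirf.filter_spots(
            cands, min_separation=0.5, brightness_cap=5
        )
        reasons = {c.spot_id: r for c, r in rejected}
        assert reasons.get(9) == "bright_irregular"
        assert len(accepted) == 8

    def test_aggregates_rejected_normals_kept(self):
        """Injected aggregates (10x brightness, 2x width) are filtered while
        normal spots survive."""
        rng = np.random.default_rng(0)
        cands = [
            self.cand(i, *rng.uniform(1, 40, 2), peak=rng.normal(100, 10))
            for i in range(95)
        ]
        aggs = [
            self.cand(100 + i, *rng.uniform(45, 60, 2), peak=1000.0, width=0.30)
            for i in range(5)
        ]
        accepted, rejected = tirf.filter_spots(cands + aggs, min_separation=0.5)
        acc_ids = {c.spot_id for c in accepted}
        assert sum(1 for i in range(5) if 100 + i in acc_ids) == 0
        n_normal_lost = sum(
            1 for c, r in rejected if c.spot_id < 100 and r == "bright_irregular"
        )
        assert n_normal_lost / 95 <= 0.05


class TestExtractTraces:
    def test_recovers_noiseless_staircase(self):
        acq = synthetic.AcquisitionParams(
            field_size=(4.8, 4.8), n_frames=120, unit_brightness=400.0,
            noise_model=synthetic.NoiseModel(read_sd=0.0, shot=False),
        )
        asm = synthetic.SpotAssembly((2.4, 2.4), 1, np.array([True]), np.array([60]))
        stack = synthetic.render_movie([asm], acq, seed=0)
        cand = tirf.SpotCandidate(0, (15.0, 15.0), (2.4, 2.4), 400.0, 0.15)
        traces, skipped = tirf.extract_traces(stack, [cand], psf_sigma=acq.psf_sigma)
        assert not skipped
        y = traces[0].intensities
        assert y[:60].mean() == pytest.approx(400.0, rel=0.03)
        assert abs(y[80:].mean()) < 4.0

    def test_edge_spot_skipped(self):
        stack = ImageStack(np.zeros((60, 32, 32)), 0.16, 20.0)
        cand = tirf.SpotCandidate(0, (1.0, 1.0), (0.16, 0.16), 10.0, 0.15)
        traces, skipped = tirf.extract_traces(stack, [cand], psf_sigma=0.15)
        assert not traces and skipped[0][1] == "edge"


class TestCountSteps:
    def test_noiseless_two_step_exact(self):
        tr = staircase([100.0, 50.0, 0.0])
        call = tirf.count_steps(tr)
        assert call.category == "two_step"
        assert call.n_steps == 2
        assert list(call.step_frames) == [100, 200]

    def test_flat_noise_rejected_poor_fit(self, rng):
        tr = staircase([0.0, 0.0, 0.0], noise_sd=5.0, rng=rng)
        call = tirf.count_steps(tr)
        assert call.category == "rejected"
        assert call.reject_reason == "poor_fit"

    def test_upward_changes_not_counted(self, rng):
        """A blinking-like recovery does not add to the step count."""
        tr = staircase([100.0, 0.0, 100.0, 0.0], noise_sd=2.0, rng=rng)
        call = tirf.count_steps(tr)
        assert call.n_steps == 2

    def test_affine_invariance(self, rng):
        y = staircase([100.0, 50.0, 0.0], noise_sd=10.0, rng=rng).intensities
        base = tirf.count_steps(FluorescenceTrace(0, y, 20.0))
        scaled = tirf.count_steps(FluorescenceTrace(0, 7.3 * y + 900.0, 20.0), baseline=900.0)
        assert base.n_steps == scaled.n_steps
        assert list(base.step_frames) == list(scaled.step_frames)

    def test_accuracy_at_snr5(self, roundtrip_acq):
        """At unit steps 5 noise SDs deep, >= 90% of 1-4 fluorophore traces
        get their exact observable step count; 2<->1 confusion <= 5%."""
        rng = np.random.default_rng(1)
        ks = rng.integers(1, 5, size=500)
        traces = synthetic.simulate_trace_batch(ks, roundtrip_acq, rng=rng)
        calls = [tirf.count_steps(t) for t in traces]
        true = np.array([t.truth["n_steps_observed"] for t in traces])
        obs = np.array([c.n_steps if c.category != "rejected" else 0 for c in calls])
        scorable = true >= 1
        assert (obs[scorable] == true[scorable]).mean() >= 0.90
        two = true == 2
        assert (obs[two] == 1).mean() <= 0.05

    def test_monotone_in_fluorophore_count(self, roundtrip_acq):
        """More fluorophores never lowers the mean detected step count."""
        rng = np.random.default_rng(2)
        means = []
        for k in (1, 2, 4):
            traces = synthetic.simulate_trace_batch(
                np.full(150, k), roundtrip_acq, rng=rng
            )
            calls = [tirf.count_steps(t) for t in traces]
            means.append(np.mean([c.n_steps for c in calls]))
        assert means[0] < means[1] < means[2]

    def test_nonfinite_rejected(self):
        tr = FluorescenceTrace(0, np.array([1.0, np.nan] * 100), 20.0)
        with pytest.raises(ValueError):
            tirf.count_steps(tr)

    def test_reversed_trace_segmentation_symmetry(self):
        """On noiseless data the segmentation finds the same breakpoints on
        the time-reversed trace (steps become upward changes)."""
        y = staircase([90.0, 60.0, 30.0]).intensities
        fwd = tirf._optimal_partition(y, penalty=10.0)
        rev = tirf._optimal_partition(y[::-1].copy(), penalty=10.0)
        assert sorted(y.size - np.array(rev)) == fwd


class TestBuildHistogram:
    def test_fig_like_fractions(self):
        calls = [
            tirf.StepCall(i, 1, [], [], "one_step") for i in range(94)
        ] + [tirf.StepCall(94 + i, 2, [], [], "two_step") for i in range(6)]
        hist = tirf.build_histogram(calls)
        assert hist.fraction_tuple() == pytest.approx((0.94, 0.06, 0.0))
        assert sum(hist.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_quarter_quarter_half_with_wilson_ci(self):
        calls = (
            [tirf.StepCall(i, 1, [], [], "one_step") for i in range(250)]
            + [tirf.StepCall(i, 2, [], [], "two_step") for i in range(250, 500)]
            + [tirf.StepCall(i, 4, [], [], "multistep") for i in range(500, 1000)]
        )
        hist = tirf.build_histogram(calls)
        assert hist.fraction_tuple() == pytest.approx((0.25, 0.25, 0.50))
        lo, hi = hist.ci["multistep"]
        assert (hi - lo) / 2 == pytest.approx(0.031, abs=0.005)

    def test_single_call_wide_ci(self):
        hist = tirf.build_histogram([tirf.StepCall(0, 1, [], [], "one_step")])
        assert hist.fractions["one_step"] == 1.0
        lo, hi = hist.ci["one_step"]
        assert hi - lo > 0.5

    def test_all_rejected_errors(self):
        calls = [tirf.StepCall(0, 0, [], [], "rejected", "poor_fit")]
        with pytest.raises(ValueError):
            tirf.build_histogram(calls)
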