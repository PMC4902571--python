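"""End-to-end orchestration: declarative run configuration, simulate ->
analyze -> fit -> report, with seeded reproducibility and a run manifest.

Also hosts the fit-then-forward round trip used to validate the
photobleaching pipeline against published step-category histograms: a
mixture is fitted to printed category fractions, forward-simulated as noisy
traces, pushed through the automated step detector, and the recovered
histogram is compared with the input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from oligocount import fccs, io, stoichiometry, synthetic, tirf

DEFAULTS = {
    "p_dark": 0.30,
    "baseline_two_step": 0.03,
    "beam_waist": 0.25,
    "gate_window_ns": 50.0,
    "frame_rate_hz": 20.0,
}


@dataclass
class RunConfig:
    mode: str  # tirf | fccs | both
    seed: int
    out_dir: str
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    _SIM_KEYS_TIRF = {
        "mixture", "p_dark", "density", "merge_radius", "n_spots",
        "n_frames", "frame_rate", "bleach_rate", "unit_brightness",
        "snr", "render_movie", "field_size",
    }
    _SIM_KEYS_FCCS = {
        "co_diffusing_fraction", "diffusion_coeff", "density", "brightness",
        "duration", "n_cells", "background_rate", "crosstalk", "box_size",
    }
    _ANALYSIS_KEYS = {
        "penalty_scale", "min_step_sd", "max_steps", "censored_policy",
        "support", "coloc_two_step", "baseline_two_step", "p_dark",
        "waist", "bin_width", "max_lag", "m", "segment_length", "detrend",
        "fc_convention", "model_censoring",
    }

    def __post_init__(self) -> None:
        if self.mode not in ("tirf", "fccs", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        allowed_sim = set()
        if self.mode in ("tirf", "both"):
            allowed_sim |= self._SIM_KEYS_TIRF
        if self.mode in ("fccs", "both"):
            allowed_sim |= self._SIM_KEYS_FCCS
        unknown = set(self.simulation) - allowed_sim
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        unknown = set(self.analysis) - self._ANALYSIS_KEYS
        if unknown:
            raise ValueError(f"unknown analysis keys: {sorted(unknown)}")
        if self.mode in ("tirf", "both") and "mixture" not in self.simulation:
            raise ValueError("tirf runs require a simulation.mixture block")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {"mode", "seed", "out_dir", "simulation", "analysis"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def make_acquisition(
    n_frames: int = 500,
    frame_rate: float = 20.0,
    bleach_rate: float = 0.005,
    unit_brightness: float = 50.0,
    snr: float = 5.0,
    field_size: tuple[float, float] = (13.0, 13.0),
) -> synthetic.AcquisitionParams:
    """Acquisition settings for trace-level round trips: Gaussian read noise
    with read_sd = unit_brightness / snr, so one bleaching step is exactly
    ``snr`` noise SDs deep."""
    return synthetic.AcquisitionParams(
        frame_rate=frame_rate,
        n_frames=n_frames,
        field_size=field_size,
        unit_brightness=unit_brightness,
        noise_model=synthetic.NoiseModel(read_sd=unit_brightness / snr, shot=False),
        bleach_rate=bleach_rate,
    )


def p_step_for(acq: synthetic.AcquisitionParams) -> float:
    """Probability a visible fluorophore produces an observable step within
    the movie (geometric hazard, drop visible while bleach frame < n_frames)."""
    return 1.0 - (1.0 - acq.bleach_rate) ** (acq.n_frames - 1)


def simulate_step_calls(
    mixture: synthetic.OligomerMixture,
    acq: synthetic.AcquisitionParams,
    n_spots: int,
    seed: int,
    coloc_two_step: float = 0.0,
    count_kwargs: dict | None = None,
) -> list[tirf.StepCall]:
    """Forward-simulate traces from a mixture (plus colocalized-pair mass)
    and run the automated step counter on each."""
    rng = np.random.default_rng(seed)
    pmf = stoichiometry.visible_count_pmf(mixture, coloc_two_step)
    ks = rng.choice(np.arange(1, pmf.size + 1), size=n_spots, p=pmf)
    traces = synthetic.simulate_trace_batch(ks, acq, rng=rng)
    kwargs = count_kwargs or {}
    return [tirf.count_steps(tr, **kwargs) for tr in traces]


def tirf_roundtrip(
    target_fractions: tuple[float, float, float],
    support: tuple[int, ...],
    n_spots: int,
    seed: int,
    p_dark: float = 0.30,
    coloc_two_step: float = 0.03,
    acq: synthetic.AcquisitionParams | None = None,
    n_fit_spots: int = 2000,
    model_censoring: bool = True,
    count_kwargs: dict | None = None,
) -> dict:
    """Fit-then-forward validation against a printed step histogram.

    Fits a mixture on ``support`` to the printed (one, two, multi) fractions
    — with the colocalization baseline and, when ``model_censoring`` is on,
    the finite-movie bleaching probability in the forward model — then
    simulates ``n_spots`` noisy traces from the fitted mixture and recovers
    the histogram through the automated detector.
    """
    if acq is None:
        acq = make_acquisition()
    p_step = p_step_for(acq) if model_censoring else 1.0
    hist_in = io.histogram_from_fractions(target_fractions, n_fit_spots)
    fit = stoichiometry.fit_mixture(
        hist_in,
        p_dark=p_dark,
        support=support,
        coloc_two_step=coloc_two_step,
        p_step=p_step,
    )
    mixture = synthetic.OligomerMixture(fit.weights, p_dark=p_dark)
    calls = simulate_step_calls(
        mixture, acq, n_spots, seed, coloc_two_step, count_kwargs
    )
    hist_out = tirf.build_histogram(calls)
    return {
        "fit": fit,
        "histogram": hist_out,
        "fractions_in": target_fractions,
        "fractions_out": hist_out.fraction_tuple(),
        "p_step": p_step,
    }


def simulate_fccs_cells(
    n_cells: int,
    seed: int,
    co_diffusing_fraction: float,
    diffusion_coeff: float = 0.4,
    duration: float = 75.0,
    density: float = 20.0,
    background_rate: float = 1000.0,
    crosstalk: float = 0.0,
    waist: float = 0.25,
    box_size: float = 3.0,
    brightness: float = 4000.0,
) -> list[fccs.CellSummary]:
    """Simulate and analyze a population of cells with one diffusing species."""
    pie = synthetic.PIEConfig()
    cells = []
    for i in range(n_cells):
        config = synthetic.MembraneSimConfig(
            species=[
                synthetic.SpeciesConfig(
                    diffusion_coeff=diffusion_coeff,
                    density=density,
                    brightness=(brightness, brightness),
                )
            ],
            co_diffusing_fraction=co_diffusing_fraction,
            box_size=box_size,
            beam_waist=(waist, waist),
            duration=duration,
            background_rate=(background_rate, background_rate),
            crosstalk=crosstalk,
        )
        green, red, _ = synthetic.simulate_dual_color_streams(
            config, pie, seed=seed + 1000 * i
        )
        cells.append(fccs.analyze_cell(green, red, pie, waist=waist))
    return cells


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages, write every artifact, and return a
    manifest (inputs, seed, output hashes). Identical config + seed gives
    byte-identical numerical outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "outputs": {},
        "results": {},
        "status": "running",
    }

    try:
        if config.mode in ("tirf", "both"):
            sim = config.simulation
            ana = config.analysis
            mixture = synthetic.OligomerMixture(
                {int(k): float(v) for k, v in sim["mixture"].items()},
                p_dark=sim.get("p_dark", DEFAULTS["p_dark"]),
            )
            acq = make_acquisition(
                n_frames=sim.get("n_frames", 500),
                frame_rate=sim.get("frame_rate", DEFAULTS["frame_rate_hz"]),
                bleach_rate=sim.get("bleach_rate", 0.005),
                unit_brightness=sim.get("unit_brightness", 50.0),
                snr=sim.get("snr", 5.0),
            )
            calls = simulate_step_calls(
                mixture,
                acq,
                n_spots=sim.get("n_spots", 1000),
                seed=config.seed,
                coloc_two_step=ana.get("coloc_two_step", 0.0),
            )
            hist = tirf.build_histogram(calls)
            fit = stoichiometry.fit_mixture(
                hist,
                p_dark=ana.get("p_dark", DEFAULTS["p_dark"]),
                support=tuple(ana.get("support", stoichiometry.DEFAULT_SUPPORT)),
                coloc_two_step=ana.get("coloc_two_step", 0.0),
                p_step=p_step_for(acq) if ana.get("model_censoring", True) else 1.0,
            )
            io.step_calls_to_csv(out / "step_calls.csv", calls)
            io.histogram_to_json(out / "step_histogram.json", hist)
            (out / "mixture_fit.json").write_text(
                json.dumps(
                    {
                        "weights": fit.weights,
                        "p_dark": fit.p_dark,
                        "log_likelihood": fit.log_likelihood,
                        "converged": fit.converged,
                        "degenerate": fit.degenerate,
                        "sensitivity": {str(k): v for k, v in fit.sensitivity.items()},
                    },
                    indent=2,
                )
            )
            manifest["results"]["tirf"] = {
                "fractions": hist.fractions,
                "n_spots_analyzed": hist.n_spots_analyzed,
                "weights": fit.weights,
            }

        if config.mode in ("fccs", "both"):
            sim = config.simulation
            ana = config.analysis
            cells = simulate_fccs_cells(
                n_cells=sim.get("n_cells", 5),
                seed=config.seed + 77_000,
                co_diffusing_fraction=sim.get("co_diffusing_fraction", 0.0),
                diffusion_coeff=sim.get("diffusion_coeff", 0.4),
                duration=sim.get("duration", 75.0),
                density=sim.get("density", 20.0),
                background_rate=sim.get("background_rate", 1000.0),
                crosstalk=sim.get("crosstalk", 0.0),
                waist=ana.get("waist", DEFAULTS["beam_waist"]),
            )
            pop = fccs.summarize_population(cells)
            (out / "population.json").write_text(json.dumps(pop, indent=2))
            manifest["results"]["fccs"] = {
                "median_fc": pop["f_c"]["median"],
                "median_D_green": pop["D_green"]["median"],
                "median_D_red": pop["D_red"]["median"],
                "n_cells": len(cells),
            }

        manifest["status"] = "complete"
    except Exception as exc:  # manifest records partial completion
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    for artifact in sorted(out.glob("*")):
        if artifact.name != "manifest.json" and artifact.is_file():
            manifest["outputs"][artifact.name] = _hash_file(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_report(manifest: dict) -> str:
    """Human-readable summary of a completed run manifest."""
    if not manifest or "results" not in manifest or not manifest["results"]:
        raise ValueError("manifest has no results to report")
    lines = ["oligocount run report", "=" * 21, f"seed: {manifest['seed']}"]
    tirf_res = manifest["results"].get("tirf")
    if tirf_res:
        lines.append("")
        lines.append("Photobleaching step categories (fraction of analyzed spots):")
        for cat, frac in tirf_res["fractions"].items():
            lines.append(f"  {cat:>9}: {frac:.3f}")
        lines.append(f"  spots analyzed: {tirf_res['n_spots_analyzed']}")
        lines.append("Fitted oligomer mixture weights:")
        for n, w in tirf_res["weights"].items():
            lines.append(f"  {n}-mer: {w:.3f}")
    fccs_res = manifest["results"].get("fccs")
    if fccs_res:
        lines.append("")
        lines.append("PIE-FCCS population medians:")
        lines.append(f"  f_c      : {fccs_res['median_fc']:.3f}")
        lines.append(f"  D (green): {fccs_res['median_D_green']:.3f} um^2/s")
        lines.append(f"  D (red)  : {fccs_res['median_D_red']:.3f} um^2/s")
        lines.append(f"  cells    : {fccs_res['n_cells']}")
    if manifest.get("status") != "complete":
        lines.append("")
        lines.append(f"WARNING: run status = {manifest.get('status')}")
    return "\n".join(lines) + "\n"
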