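"""Ground-truthed synthetic data: TIRF spot fields, traces, movies and
pulsed-interleaved two-color photon streams.

The generators embody the statistical structure the downstream analyses
assume: immobile oligomeric assemblies placed by a homogeneous Poisson
process on the membrane (with diffraction-limited merging producing random
colocalization), per-fluorophore dark states from incomplete chromophore
maturation, single irreversible geometric-hazard bleaching, and — for FCCS —
2D Brownian diffusion of labeled complexes through a Gaussian observation
profile with interleaved pulsed excitation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from oligocount.containers import GREEN, RED, FluorescenceTrace, ImageStack, PhotonStream

# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class OligomerMixture:
    """Distribution of assembly sizes plus the per-fluorophore dark probability.

    ``weights`` maps subunit count n (positive int) to its population
    fraction; ``p_dark`` is the probability that any one fluorophore never
    matured and is invisible (default 0.30, the midpoint of the 25-35% range
    reported for EGFP).
    """

    weights: dict[int, float]
    p_dark: float = 0.30

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("mixture must have at least one component")
        self.weights = {int(n): float(w) for n, w in self.weights.items()}
        if any(n < 1 for n in self.weights):
            raise ValueError("subunit counts must be positive integers")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total})")
        if not 0.0 <= self.p_dark <= 1.0:
            raise ValueError("p_dark must be in [0, 1]")

    @property
    def sizes(self) -> np.ndarray:
        return np.array(sorted(self.weights), dtype=int)

    @property
    def probs(self) -> np.ndarray:
        return np.array([self.weights[n] for n in sorted(self.weights)])


@dataclass
class ColocalizationModel:
    """Surface density (molecules/um^2) and the unresolvable-pair radius (um)."""

    density: float
    merge_radius: float = 0.1

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be nonnegative")
        if self.merge_radius <= 0:
            raise ValueError("merge_radius must be positive")


@dataclass
class NoiseModel:
    read_sd: float = 10.0
    shot: bool = True


@dataclass
class AcquisitionParams:
    """TIRF acquisition settings (20 Hz, 500-800 frame movies by default)."""

    frame_rate: float = 20.0
    n_frames: int = 500
    field_size: tuple[float, float] = (13.0, 13.0)
    pixel_size: float = 0.16
    psf_sigma: float = 0.15
    unit_brightness: float = 50.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    bleach_rate: float = 0.005
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 < self.bleach_rate < 1.0:
            raise ValueError("bleach_rate must be in (0, 1)")
        if min(self.field_size) <= 0 or self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("geometry parameters must be positive")


@dataclass
class SpotAssembly:
    """Ground-truth record for one diffraction-limited spot."""

    position: tuple[float, float]
    n_total: int
    visible_flags: np.ndarray
    bleach_frames: np.ndarray
    origin: str = "true_oligomer"  # or "colocalized"

    def __post_init__(self) -> None:
        self.visible_flags = np.asarray(self.visible_flags, dtype=bool)
        self.bleach_frames = np.asarray(self.bleach_frames, dtype=int)
        if self.visible_flags.sum() != self.bleach_frames.size:
            raise ValueError("one bleach frame per visible fluorophore")
        if self.visible_flags.size != self.n_total:
            raise ValueError("visible_flags must have n_total entries")
        if self.bleach_frames.size and self.bleach_frames.min() < 1:
            raise ValueError("bleach_frames must be strictly positive")

    @property
    def n_visible(self) -> int:
        return int(self.visible_flags.sum())


@dataclass
class PIEConfig:
    """Pulsed-interleaved excitation timing (nanoseconds).

    The red (561 nm) pulse train is delayed by ``interleave_delay`` relative
    to the green (488 nm) train; photons arriving within ``gate_window`` of
    the wrong laser's pulse are rejected during gating.
    """

    pulse_period: float = 100.0
    interleave_delay: float = 50.0
    gate_window: float = 50.0

    def __post_init__(self) -> None:
        if self.interleave_delay <= 0:
            raise ValueError("interleave_delay must be positive")
        if self.gate_window > self.interleave_delay:
            raise ValueError("gate_window must not exceed interleave_delay")
        if self.pulse_period < self.interleave_delay:
            raise ValueError("pulse_period must be >= interleave_delay")


@dataclass
class SpeciesConfig:
    """One diffusing labeled species in the membrane simulation.

    ``density`` is the surface density of label-bearing complexes per color
    (um^-2); ``brightness`` is the detected photon rate (per second) of one
    fluorophore at the beam center, per color; ``occupancy`` is the
    probability each color's fluorophore is present and mature.
    """

    diffusion_coeff: float = 0.4
    density: float = 20.0
    brightness: tuple[float, float] = (4000.0, 4000.0)
    occupancy: tuple[float, float] = (1.0, 1.0)
    name: str = "species"

    def __post_init__(self) -> None:
        if self.diffusion_coeff <= 0:
            raise ValueError("diffusion_coeff must be positive")
        if self.density < 0:
            raise ValueError("density must be nonnegative")
        if not all(0.0 <= o <= 1.0 for o in self.occupancy):
            raise ValueError("occupancies must be in [0, 1]")


@dataclass
class MembraneSimConfig:
    """Two-color membrane FCCS simulation settings.

    ``co_diffusing_fraction`` is the fraction of each color's population that
    resides in dual-labeled complexes: per species, ``f * N_c`` particles
    carry both colors and ``(1 - f) * N_c`` carry only green (and likewise
    red), so the ideal fraction correlated equals ``f``.
    """

    species: list[SpeciesConfig] = field(default_factory=lambda: [SpeciesConfig()])
    co_diffusing_fraction: float = 0.0
    box_size: float = 3.0
    beam_waist: tuple[float, float] = (0.25, 0.25)
    duration: float = 75.0
    background_rate: tuple[float, float] = (1000.0, 1000.0)
    crosstalk: float = 0.0
    time_step: float = 2e-4
    fluorescence_lifetime_ns: float = 2.5

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species is required")
        if not 0.0 <= self.co_diffusing_fraction <= 1.0:
            raise ValueError("co_diffusing_fraction must be in [0, 1]")
        if not 0.0 <= self.crosstalk <= 1.0:
            raise ValueError("crosstalk must be in [0, 1]")
        if self.duration <= 0 or self.box_size <= 0 or self.time_step <= 0:
            raise ValueError("duration, box_size and time_step must be positive")


# ---------------------------------------------------------------------------
# spot fields, traces, movies
# ---------------------------------------------------------------------------


def expected_pair_fraction(density: float, radius: float, p_dark: float) -> float:
    """Small-density estimate of the fraction of visible spots that show two
    visible fluorophores purely from random colocalization of monomers.

    For a homogeneous Poisson field at density lambda, the fraction of spots
    that are unresolvable pairs is ~ lambda*pi*r^2/2, and both members are
    visible with probability (1 - p_dark)^2. Valid while lambda*pi*r^2 << 1.
    """
    if density < 0 or radius <= 0:
        raise ValueError("density must be >= 0 and radius > 0")
    if not 0.0 <= p_dark <= 1.0:
        raise ValueError("p_dark must be in [0, 1]")
    crowding = density * math.pi * radius**2
    if crowding > 0.5:
        raise ValueError(
            f"lambda*pi*r^2 = {crowding:.3f} > 0.5: small-density approximation invalid"
        )
    return 0.5 * crowding * (1.0 - p_dark) ** 2


def pair_fraction_monte_carlo(
    density: float,
    radius: float,
    p_dark: float,
    area: float,
    seed: int,
) -> dict:
    """Monte-Carlo estimate of the random-colocalization two-step fraction.

    Drops a homogeneous Poisson field of monomers on ``area`` um^2, merges
    points closer than ``radius`` into single spots (connected components),
    applies independent dark states, and returns the fraction of spots
    showing exactly two visible fluorophores relative to all assemblies —
    the same normalization as :func:`expected_pair_fraction`. Fully
    vectorized so fields of ~1 mm^2 are practical.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    rng = np.random.default_rng(seed)
    side = math.sqrt(area)
    n = rng.poisson(density * area)
    pos = rng.uniform(0, side, size=(n, 2))
    tree = cKDTree(pos)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size:
        adj = coo_matrix(
            (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_clusters, labels = connected_components(adj, directed=False)
    else:
        n_clusters, labels = n, np.arange(n)
    cluster_size = np.bincount(labels, minlength=n_clusters)
    visible = np.bincount(
        labels, weights=(rng.random(n) >= p_dark).astype(float), minlength=n_clusters
    ).astype(int)
    return {
        "two_visible_fraction": float((visible == 2).mean()),
        "conditional_two_visible_fraction": float(
            (visible == 2).sum() / max((visible >= 1).sum(), 1)
        ),
        "n_assemblies": int(n_clusters),
        "n_pairs": int((cluster_size == 2).sum()),
    }


def _merge_clusters(positions: np.ndarray, radius: float) -> list[np.ndarray]:
    """Group points into connected clusters under a pairwise distance cutoff."""
    n = positions.shape[0]
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(positions)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    clusters: dict[int, list[int]] = {}
    for idx, r in enumerate(roots):
        clusters.setdefault(r, []).append(idx)
    return [np.array(members) for members in clusters.values()]


def sample_spot_field(
    mixture: OligomerMixture,
    coloc: ColocalizationModel,
    acq: AcquisitionParams,
    seed: int,
    keep_invisible: bool = False,
) -> list[SpotAssembly]:
    """Place oligomeric assemblies by a homogeneous Poisson process, merge
    unresolvable neighbors into single spots, and assign per-fluorophore
    dark states and bleach frames.

    Assemblies whose fluorophores are all dark are dropped (invisible)
    unless ``keep_invisible`` is set, which retains them so that fractions
    can be computed relative to the full assembly count.
    """
    rng = np.random.default_rng(seed)
    w, h = acq.field_size
    area = w * h
    n_assemblies = rng.poisson(coloc.density * area)
    if n_assemblies == 0:
        return []
    positions = rng.uniform([0, 0], [w, h], size=(n_assemblies, 2))
    sizes = rng.choice(mixture.sizes, size=n_assemblies, p=mixture.probs)

    clusters = _merge_clusters(positions, coloc.merge_radius)
    spots: list[SpotAssembly] = []
    for members in clusters:
        n_total = int(sizes[members].sum())
        visible = rng.random(n_total) >= mixture.p_dark
        n_vis = int(visible.sum())
        if n_vis == 0 and not keep_invisible:
            continue
        bleach = rng.geometric(acq.bleach_rate, size=n_vis)
        spots.append(
            SpotAssembly(
                position=tuple(positions[members].mean(axis=0)),
                n_total=n_total,
                visible_flags=visible,
                bleach_frames=bleach,
                origin="true_oligomer" if members.size == 1 else "colocalized",
            )
        )
    return spots


def simulate_trace_batch(
    visible_counts: np.ndarray,
    acq: AcquisitionParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bleach_frames: list[np.ndarray] | None = None,
) -> list[FluorescenceTrace]:
    """Vectorized trace simulation for many spots at once.

    Each spot carries ``visible_counts[i]`` visible fluorophores; every
    fluorophore bleaches irreversibly at an independent geometric time with
    per-frame hazard ``acq.bleach_rate``. Intensity per frame is
    ``unit_brightness`` per not-yet-bleached fluorophore plus baseline, with
    optional Poisson shot noise on the signal and Gaussian read noise.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    visible_counts = np.asarray(visible_counts, dtype=int)
    if np.any(visible_counts < 1):
        raise ValueError("every spot must have at least one visible fluorophore")
    n_spots = visible_counts.size
    kmax = int(visible_counts.max())
    t = np.arange(acq.n_frames)

    if bleach_frames is None:
        bf = rng.geometric(acq.bleach_rate, size=(n_spots, kmax)).astype(float)
    else:
        bf = np.full((n_spots, kmax), np.inf)
        for i, frames in enumerate(bleach_frames):
            bf[i, : len(frames)] = frames
    # mask fluorophores beyond each spot's count
    mask = np.arange(kmax)[None, :] < visible_counts[:, None]
    bf = np.where(mask, bf, 0.0)  # padded entries contribute nothing

    traces: list[FluorescenceTrace] = []
    chunk = max(1, int(2_000_000 / (kmax * acq.n_frames)))
    for lo in range(0, n_spots, chunk):
        hi = min(lo + chunk, n_spots)
        # fluorophore k is emitting at frame t while t < bleach_frame
        alive = bf[lo:hi, :, None] > t[None, None, :]
        signal = acq.unit_brightness * alive.sum(axis=1).astype(float)
        if acq.noise_model.shot:
            signal = rng.poisson(np.maximum(signal, 0.0)).astype(float)
        noisy = signal + acq.baseline
        if acq.noise_model.read_sd > 0:
            noisy = noisy + rng.normal(0.0, acq.noise_model.read_sd, size=noisy.shape)
        for i in range(hi - lo):
            idx = lo + i
            k = visible_counts[idx]
            frames_i = np.sort(bf[idx, :k]).astype(int)
            censored = bool(frames_i[-1] >= acq.n_frames)
            traces.append(
                FluorescenceTrace(
                    spot_id=idx,
                    intensities=noisy[i],
                    frame_rate=acq.frame_rate,
                    truth={
                        "n_visible": int(k),
                        "bleach_frames": frames_i,
                        "n_steps_observed": int((frames_i < acq.n_frames).sum()),
                        "censored": censored,
                    },
                )
            )
    return traces


def simulate_trace(
    assembly: SpotAssembly,
    acq: AcquisitionParams,
    seed: int | None = None,
    spot_id: int = 0,
) -> FluorescenceTrace:
    """Simulate one spot's photobleaching trace from its ground-truth record."""
    if assembly.n_visible == 0:
        raise ValueError("assembly has no visible fluorophores")
    trace = simulate_trace_batch(
        np.array([assembly.n_visible]),
        acq,
        seed=seed,
        bleach_frames=[assembly.bleach_frames],
    )[0]
    trace.spot_id = spot_id
    trace.position = assembly.position
    trace.truth["origin"] = assembly.origin
    return trace


def render_movie(
    assemblies: list[SpotAssembly],
    acq: AcquisitionParams,
    seed: int | None = None,
) -> ImageStack:
    """Render a TIRF movie: Gaussian PSFs of unbleached fluorophores on a
    pixel grid, plus shot and read noise."""
    rng = np.random.default_rng(seed)
    w_um, h_um = acq.field_size
    W = int(round(w_um / acq.pixel_size))
    H = int(round(h_um / acq.pixel_size))
    if W < 4 or H < 4:
        raise ValueError("field too small for the chosen pixel size")
    sigma_px = acq.psf_sigma / acq.pixel_size
    half = max(3, int(math.ceil(4 * sigma_px)))
    frames = np.zeros((acq.n_frames, H, W))

    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    for asm in assemblies:
        x_um, y_um = asm.position
        if not (0 <= x_um <= w_um and 0 <= y_um <= h_um):
            raise ValueError("assembly outside the field of view")
        cx, cy = x_um / acq.pixel_size, y_um / acq.pixel_size
        ix, iy = int(round(cx)), int(round(cy))
        dx, dy = cx - ix, cy - iy
        psf = np.exp(-((xx - dx) ** 2 + (yy - dy) ** 2) / (2 * sigma_px**2))
        psf *= acq.unit_brightness / (2 * math.pi * sigma_px**2)
        x0, x1 = max(0, ix - half), min(W, ix + half + 1)
        y0, y1 = max(0, iy - half), min(H, iy + half + 1)
        px0, py0 = x0 - (ix - half), y0 - (iy - half)
        patch = psf[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]
        for bf in asm.bleach_frames:
            t_end = min(int(bf), acq.n_frames)
            if t_end > 0:
                frames[:t_end, y0:y1, x0:x1] += patch

    if acq.noise_model.shot:
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(float)
    frames += acq.baseline
    if acq.noise_model.read_sd > 0:
        frames = frames + rng.normal(0.0, acq.noise_model.read_sd, size=frames.shape)
    return ImageStack(frames=frames, pixel_size=acq.pixel_size, frame_rate=acq.frame_rate)


# ---------------------------------------------------------------------------
# PIE two-color photon streams
# ---------------------------------------------------------------------------

LABEL_SIGNAL, LABEL_CROSSTALK, LABEL_BACKGROUND = 0, 1, 2


def _expand_photons(
    counts: np.ndarray, step_offset: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Turn per-step Poisson counts into uniformly placed macrotimes."""
    steps = np.repeat(np.arange(counts.size) + step_offset, counts)
    return (steps + rng.random(steps.size)) * dt


def simulate_dual_color_streams(
    config: MembraneSimConfig,
    pie: PIEConfig | None = None,
    seed: int | None = None,
) -> tuple[PhotonStream, PhotonStream, dict]:
    """Simulate pulse-tagged photon streams from 2D Brownian motion of
    labeled complexes through Gaussian beam profiles.

    Per species, a fraction ``co_diffusing_fraction`` of each color's
    population carries both labels; crosstalk photons from green emitters
    appear in the red channel with microtimes tied to the 488 nm pulse so
    that PIE gating can remove them. Returns (green stream, red stream,
    ground-truth record).
    """
    if pie is None:
        pie = PIEConfig()
    rng = np.random.default_rng(seed)
    box = config.box_size
    dt = config.time_step
    n_steps = int(round(config.duration / dt))
    w_g, w_r = config.beam_waist

    # Build the particle table: per-particle D, per-color brightness.
    D_list, bg_list, br_list = [], [], []
    n_in_focus_g = n_in_focus_r = 0.0
    f = config.co_diffusing_fraction
    for sp in config.species:
        n_c = int(round(sp.density * box * box))
        n_dual = int(round(f * n_c))
        n_single = n_c - n_dual
        occ_g, occ_r = sp.occupancy
        b_g, b_r = sp.brightness
        for count, has_g, has_r in (
            (n_dual, True, True),
            (n_single, True, False),
            (n_single, False, True),
        ):
            if count == 0:
                continue
            g_on = (rng.random(count) < occ_g) & has_g
            r_on = (rng.random(count) < occ_r) & has_r
            D_list.append(np.full(count, sp.diffusion_coeff))
            bg_list.append(np.where(g_on, b_g, 0.0))
            br_list.append(np.where(r_on, b_r, 0.0))
        n_in_focus_g += sp.density * occ_g * math.pi * w_g**2
        n_in_focus_r += sp.density * occ_r * math.pi * w_r**2

    if D_list:
        D = np.concatenate(D_list)
        bright_g = np.concatenate(bg_list)
        bright_r = np.concatenate(br_list)
    else:
        D = bright_g = bright_r = np.zeros(0)
    n_particles = D.size
    if n_in_focus_g + n_in_focus_r < 0.5:
        warnings.warn("fewer than ~0.5 particles in focus on average", stacklevel=2)

    sigma_step = np.sqrt(2.0 * D * dt).astype(np.float32)
    pos = rng.uniform(0, box, size=(n_particles, 2)).astype(np.float32)
    center = np.float32(box / 2.0)

    cat_times: dict[str, list[np.ndarray]] = {k: [] for k in ("g", "r", "ct", "bgg", "bgr")}
    chunk = max(1, int(1.5e7 / max(1, n_particles)))
    for lo in range(0, n_steps, chunk):
        hi = min(lo + chunk, n_steps)
        m = hi - lo
        if n_particles:
            steps = rng.standard_normal((m, n_particles, 2), dtype=np.float32)
            steps *= sigma_step[None, :, None]
            np.cumsum(steps, axis=0, out=steps)
            steps += pos[None]
            steps %= box
            pos = steps[-1].copy()
            # beam at box center: wrapped coordinates are already the
            # minimum image, |x - center| <= box/2
            steps -= center
            r2 = np.einsum("ijk,ijk->ij", steps, steps)
            prof_g = np.exp(-2.0 * r2 / (w_g * w_g))
            rate_g = prof_g @ bright_g * dt
            if w_r == w_g:
                prof_r = prof_g
            else:
                prof_r = np.exp(-2.0 * r2 / (w_r * w_r))
            rate_r = prof_r @ bright_r * dt
            rate_ct = config.crosstalk * (prof_r @ bright_g) * dt
        else:
            rate_g = rate_r = rate_ct = np.zeros(m)
        bg_gr, bg_rr = config.background_rate
        draws = {
            "g": rng.poisson(rate_g),
            "r": rng.poisson(rate_r),
            "ct": rng.poisson(rate_ct) if config.crosstalk > 0 else np.zeros(m, dtype=int),
            "bgg": rng.poisson(bg_gr * dt, size=m),
            "bgr": rng.poisson(bg_rr * dt, size=m),
        }
        for key, counts in draws.items():
            cat_times[key].append(_expand_photons(counts, lo, dt, rng))

    times = {k: np.concatenate(v) if v else np.zeros(0) for k, v in cat_times.items()}

    def signal_micro(n: int) -> np.ndarray:
        mt = rng.exponential(config.fluorescence_lifetime_ns, size=n)
        return np.minimum(mt, pie.gate_window * 0.999)

    def bg_fields(n: int) -> tuple[np.ndarray, np.ndarray]:
        origin = rng.choice([488, 561], size=n)
        gap = min(pie.interleave_delay, pie.pulse_period - pie.interleave_delay)
        return rng.uniform(0, max(gap, 1e-9), size=n), origin

    def assemble(parts: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]], channel: str) -> PhotonStream:
        if parts:
            t = np.concatenate([p[0] for p in parts])
            mt = np.concatenate([p[1] for p in parts])
            po = np.concatenate([p[2] for p in parts])
            lab = np.concatenate([np.full(p[0].size, p[3], dtype=np.int8) for p in parts])
        else:
            t = mt = po = lab = np.zeros(0)
        order = np.argsort(t, kind="stable")
        return PhotonStream(
            arrival_times=t[order],
            microtimes=mt[order],
            pulse_origin=po[order],
            channel=channel,
            pulse_period=pie.pulse_period,
            labels=lab[order],
            meta={"duration": config.duration, "seed": seed},
        )

    n_g, n_r, n_ct = times["g"].size, times["r"].size, times["ct"].size
    bg_mt_g, bg_po_g = bg_fields(times["bgg"].size)
    bg_mt_r, bg_po_r = bg_fields(times["bgr"].size)
    green = assemble(
        [
            (times["g"], signal_micro(n_g), np.full(n_g, 488), LABEL_SIGNAL),
            (times["bgg"], bg_mt_g, bg_po_g, LABEL_BACKGROUND),
        ],
        GREEN,
    )
    red = assemble(
        [
            (times["r"], signal_micro(n_r), np.full(n_r, 561), LABEL_SIGNAL),
            (times["ct"], signal_micro(n_ct), np.full(n_ct, 488), LABEL_CROSSTALK),
            (times["bgr"], bg_mt_r, bg_po_r, LABEL_BACKGROUND),
        ],
        RED,
    )
    truth = {
        "co_diffusing_fraction": f,
        "diffusion_coeffs": {sp.name: sp.diffusion_coeff for sp in config.species},
        "n_in_focus_green": n_in_focus_g,
        "n_in_focus_red": n_in_focus_r,
        "n_signal_green": n_g,
        "n_signal_red": n_r,
        "n_crosstalk_red": n_ct,
        "seed": seed,
    }
    return green, red, truth
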