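# Methods

## Photobleaching model

Each spot is an assembly of `n` subunits at a fixed position. A fluorophore
is visible with probability `1 − p_dark` (independent across subunits;
`p_dark` defaults to 0.30, the midpoint of the 25–35% range reported for
EGFP maturation failure). Each visible fluorophore bleaches once,
irreversibly, at a geometric per-frame hazard (default 0.005/frame at
20 Hz, i.e. a ~10 s mean bleaching time, chosen to visually match published
example traces; config-exposed). Blinking is off by default — the analyses
assume clean monotone staircases — but an upward transition in a real trace
is simply not counted as a step, which is the detector-side guard.

Trace intensity is `unit_brightness` (default 50 counts/frame) per
unbleached fluorophore plus optional Poisson shot noise and Gaussian read
noise. For trace-level round trips the helper `pipeline.make_acquisition`
uses pure Gaussian noise with `read_sd = unit_brightness/snr` so that "SNR
5" means a unit step exactly five noise SDs deep. Movie rendering
(`render_movie`) integrates Gaussian PSFs (σ = 0.15 µm, pixel 0.16 µm) and
applies shot plus read noise; it exists so the detector can be validated
end-to-end against known positions.

Spot fields are homogeneous Poisson processes at the configured surface
density (1–5 molecules/µm² is the regime of interest). Points closer than
`merge_radius` (default 0.1 µm — diffraction-limited co-occupancy; no
published value exists) merge into one spot, which is how random
colocalization enters. The small-density closed form for the colocalized
two-step fraction, `(λπr²/2)(1 − p_dark)²`, is normalized to **all**
assemblies, including those whose fluorophores are all dark. The observable
(visible-conditioned) fraction is larger by a factor `1/P(visible) ≈ 1.4`
at `p_dark = 0.3`; `pair_fraction_monte_carlo` reports both so the
convention is explicit. The closed form refuses densities with
`λπr² > 0.5`, where the pairs-only approximation breaks down.

## Step counting

Traces are segmented by penalized least squares (optimal-partitioning
dynamic program, piecewise-constant means, penalty
`penalty_scale · σ² · log n` per changepoint with `penalty_scale = 3`,
minimum segment length 2). The noise σ comes from the median absolute first
difference, making every threshold scale-free: step calls are invariant
under affine intensity rescaling. Only downward changes of at least
`min_step_sd · σ` (default 3σ) count as steps. Traces with no retained step
are rejected (`poor_fit`). A trace whose final level sits more than 2σ
above baseline is flagged censored; by default it is classified by the
steps observed (rejecting censored spots would bias against large
oligomers, whose probability of fully bleaching within the movie decays as
`p_step^k`), and a `censored_policy="reject"` option restores the stricter
behavior. At SNR 5 the detector assigns the exact observable step count to
≥ 90% of 1–4-fluorophore traces; residual errors are dominated by genuinely
near-simultaneous bleach events.

## Stoichiometry inversion

`predict_categories` marginalizes the binomial dark-state kernel over the
mixture, adds the colocalization mass `coloc_two_step` to the two-visible
class, and optionally thins each visible fluorophore by `p_step` — the
probability that it bleaches inside the movie,
`1 − (1 − hazard)^(n_frames − 1)` (≈ 0.918 for the defaults). The thinning
term makes the forward model self-consistent with finite movies: without it
a fit-then-forward round trip on a multimer-rich histogram under-recovers
the multistep fraction by several points purely through censoring.
`fit_mixture` maximizes the multinomial likelihood of the (one, two, multi)
counts over the weight simplex with a deterministic multi-start SLSQP.
Three observed categories cannot uniquely pin more than three weights; ties
in likelihood with distinct weights set a `degenerate` flag rather than
pretending multimer sizes are resolved, and every fit carries a p_dark
sensitivity sweep over 0.25–0.35. The default support {1, 2, 4, 6} reflects
the dimer/"multimer of dimers" hypothesis space. Baseline subtraction moves
the monomer-control two-step fraction (default 3 points) from the two-step
to the one-step category, clipping at zero with a warning.

## PIE-FCCS simulation

Labeled complexes perform 2D Brownian motion (step σ = √(2D·dt), dt =
0.2 ms, periodic 3 µm box) through Gaussian observation profiles
`exp(−2r²/w²)` with waist `w = 0.25 µm` per color (no axial term:
everything is membrane-confined). Photon counts per time step are Poisson
with rate proportional to per-particle brightness (4 kHz at beam center)
summed over particles; macrotimes are uniform within the step, microtimes
exponential with a 2.5 ns fluorescence lifetime after the originating
pulse. The pulse trains repeat every 100 ns with the red (561 nm) train
delayed 50 ns; crosstalk photons from green emitters land in the red
channel with 488-pulse microtimes, so PIE gating removes them exactly.
Background (default 1 kHz/channel) is uniform with random pulse origin.

`co_diffusing_fraction` f is defined per color: each species contributes
`f·N_c` dual-labeled and `(1 − f)·N_c` single-labeled particles of each
color, so the ideal fraction correlated equals f exactly under the
max-denominator convention. Default surface density 20 complexes/µm² per
color puts ≈ 3.9 particles in the observation area (amplitudes ≈ 0.26),
a realistic low-expression FCCS regime.

What the generator does **not** emulate: photophysics (triplet flicker,
afterpulsing), anomalous or confined diffusion, vesicle transits, axial
drift, and detector dead time. Passing recovery tests therefore demonstrate
correctness of the gating/correlation/fitting chain, not robustness to
every artifact of live-cell data.

## Correlation and fitting

The multi-tau correlator evaluates lags 1..2m at the base bin width
(0.2 ms) and m+1..2m after each 2× rebinning (m = 16, max lag 1 s), with
symmetric normalization by the overlapping-segment means. Analysis follows
the five 15 s segment protocol: each segment is gated, linearly detrended
(photobleaching guard; segments losing > 50% intensity are dropped), and
correlated; curves are averaged across segments.

Fits use `G(τ) = G0/(1 + τ/τ_D) + B` with a free constant offset `B`.
Correlations estimated from 15 s segments sit on a small negative baseline
because the segment mean is estimated from the same data (the 2D model's
slowly decaying tail makes this non-negligible); forcing the model through
zero biases τ_D low by ~20%, while the offset term reduces the residual
bias of the recovered D to a few percent across D = 0.1–1 µm²/s. Fits of
the averaged curves are unweighted: per-lag SEs from five
segments are too noisy for stable inverse-variance weighting. The
cross-correlation amplitude is fitted with τ_D fixed to the mean of the two
autocorrelation times (amplitude + offset, a linear fit): a free fit of a
near-zero cross curve has an unidentifiable τ_D and a positively biased
amplitude. `f_c = G_x(0)/max(G_gg(0), G_rr(0))` by default; the denominator
convention (max/green/red) is config-exposed because the literature varies.
Negative cross amplitudes clip to zero (flagged); f_c above 1 is flagged
and clipped at 1.5.

Slow diffusion is the protocol's resolution limit: at D = 0.1 µm²/s the
diffusion time (156 ms) is only two orders of magnitude below the segment
length, and per-cell estimates scatter accordingly even though the median
stays within a few percent.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduces outputs
byte-for-byte. The validation suite uses 5000-spot round trips for the
photobleaching histograms, 9–11 replicate cells (75 s each) for the FCCS
recoveries, and 0.25 mm² fields for the colocalization Monte Carlo; the
acceptance script scales these to 20 replicates and 1 mm². Bootstrap
intervals are percentile intervals over spots (B ≥ 200, seeded).

## Design choices where the design was open

- Automated change-point counting replaces by-eye step assignment; the
  published analyses counted manually, so the algorithm, penalty and
  minimum step size here are package choices, stated above.
- Censored traces are kept and classified by observed steps (see above);
  the alternative is one flag away.
- The baseline correction operates on category fractions, not spot counts;
  a count-removal variant exists behind `subtract_baseline`'s metadata for
  comparison.
- Spots are treated as immobile; no tracking or drift correction is
  implemented (the intended use regime anchors receptors to the
  coverslip).
- p_dark is an input, never estimated from the data being fitted;
  sensitivity to it is reported instead.
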