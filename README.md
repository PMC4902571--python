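# oligocount

Single-molecule stoichiometry of membrane receptors from two complementary
assays:

1. **TIRF photobleaching step counting.** A receptor fused to a fluorescent
   protein appears as a diffraction-limited spot whose intensity decays in
   discrete steps as individual fluorophores bleach. The number of downward
   steps lower-bounds the number of subunits in the spot. Because a fraction
   `p_dark` of fluorescent-protein tags never matures (≈25–35% for EGFP), an
   n-mer shows k ≤ n steps with

   ```
   P(k | n) = C(n, k) (1 − p_dark)^k p_dark^(n−k) / (1 − p_dark^n),
   ```

   and random colocalization of non-interacting molecules (two emitters
   within one diffraction-limited spot) adds spurious two-step events at a
   rate ≈ (λπr²/2)(1 − p_dark)² for surface density λ and merge radius r.
   `oligocount` detects spots, filters aggregates and overlaps, counts steps
   by penalized change-point segmentation, and inverts the one/two/multistep
   histogram into oligomer-mixture weights by constrained maximum likelihood,
   with the monomer-control baseline correction.

2. **PIE-FCCS.** Two spectrally distinct labels on co-expressed receptor
   populations are excited by interleaved pulsed lasers 50 ns apart; each
   photon's originating laser is identified from its microtime, so
   bleed-through and direct excitation can be gated out. Auto- and
   cross-correlations of the gated intensity traces are computed with a
   multi-tau correlator and fitted with a 2D membrane-diffusion model
   `G(τ) = G0/(1 + τ/τ_D)`, `D = w²/(4τ_D)`. The fraction of co-diffusing
   molecules is reported as `f_c = G_x(0)/max(G_gg(0), G_rr(0))`.

A fully seeded synthetic-data module generates TIRF movies, per-spot traces
and pulse-tagged dual-color photon streams with known ground truth, so every
analysis stage is testable without experimental recordings.

## Worked example

Simulate a mostly monomeric receptor population, count steps, and fit the
mixture:

```python
import numpy as np
from oligocount import pipeline, stoichiometry, synthetic, tirf

mixture = synthetic.OligomerMixture({1: 0.94, 2: 0.06}, p_dark=0.30)
acq = pipeline.make_acquisition()          # 20 Hz, 500 frames, SNR 5
calls = pipeline.simulate_step_calls(mixture, acq, n_spots=2000, seed=7)
hist = tirf.build_histogram(calls)
print({k: round(v, 3) for k, v in hist.fractions.items()})

fit = stoichiometry.fit_mixture(
    hist, p_dark=0.30, support=(1, 2),
    p_step=pipeline.p_step_for(acq),
)
print({n: round(w, 3) for n, w in fit.weights.items()})
```

```
{'one_step': 0.977, 'two_step': 0.023, 'multistep': 0.0}
{1: 0.953, 2: 0.047}
```

The observed one-step fraction (97.7%) exceeds the true monomer weight
because a dark fluorophore (or an unbleached one in a finite movie) demotes
some dimers to a single observed step; the maximum-likelihood inversion
undoes both effects and recovers the underlying weights (95.3% monomer
against 94% truth on this 2000-spot draw).

The same end-to-end run is available from a shell:

```bash
oligocount run --config examples/run_tirf.yaml
oligocount report --manifest out/manifest.json
```

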