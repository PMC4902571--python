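"""Binomial dark-fraction stoichiometry model.

A spot containing n fluorophore-tagged subunits shows k <= n bleaching steps
because each tag independently fails to mature with probability p_dark.
Conditioned on the spot being visible at all,

    P(k | n) = C(n, k) (1 - p_dark)^k p_dark^(n - k) / (1 - p_dark^n).

This module marginalizes that kernel over an oligomer-size mixture, adds the
random-colocalization contribution measured with a monomer control, and
inverts observed step-category histograms into mixture weights by
constrained maximum likelihood. An optional finite-movie term (the
probability that a visible fluorophore actually bleaches before the movie
ends) makes the forward model match step counts observed in movies of finite
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from oligocount.synthetic import OligomerMixture
from oligocount.tirf import CATEGORIES, StepCall, StepHistogram

DEFAULT_SUPPORT = (1, 2, 4, 6)


@dataclass
class StepDistribution:
    """Visible-step pmf for one oligomer size, and its category collapse."""

    n: int
    p_dark: float
    pmf: np.ndarray  # P(k), k = 1..n
    categories: tuple[float, float, float]  # (one, two, multi)


@dataclass
class MixtureFit:
    weights: dict[int, float]
    p_dark: float
    log_likelihood: float
    converged: bool
    coloc_two_step: float = 0.0
    p_step: float = 1.0
    degenerate: bool = False
    ci: dict[int, tuple[float, float]] = field(default_factory=dict)
    sensitivity: dict[float, dict[int, float]] = field(default_factory=dict)


def step_count_pmf(n: int, p_dark: float) -> StepDistribution:
    """Distribution of visible-fluorophore counts for an n-mer, conditioned
    on at least one fluorophore being visible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p_dark < 1.0:
        raise ValueError("p_dark must be in [0, 1); p_dark = 1 leaves nothing visible")
    k = np.arange(1, n + 1)
    pmf = stats.binom.pmf(k, n, 1.0 - p_dark) / (1.0 - p_dark**n)
    one = float(pmf[0])
    two = float(pmf[1]) if n >= 2 else 0.0
    multi = float(pmf[2:].sum()) if n >= 3 else 0.0
    return StepDistribution(n=n, p_dark=p_dark, pmf=pmf, categories=(one, two, multi))


def visible_count_pmf(
    mixture: OligomerMixture,
    coloc_two_step: float = 0.0,
) -> np.ndarray:
    """Pmf over visible-fluorophore counts k >= 1 (index 0 of the returned
    array is k = 1), marginalized over the mixture, with the random
    colocalization mass added at k = 2 and renormalized."""
    n_max = int(max(mixture.weights))
    if coloc_two_step > 0:
        n_max = max(n_max, 2)
    vis = np.zeros(n_max + 1)
    for n, w in mixture.weights.items():
        vis[1 : n + 1] += w * step_count_pmf(n, mixture.p_dark).pmf
    if coloc_two_step > 0:
        vis[2] += coloc_two_step
        vis /= vis.sum()
    return vis[1:]


def observed_step_pmf(
    mixture: OligomerMixture,
    coloc_two_step: float = 0.0,
    p_step: float = 1.0,
) -> np.ndarray:
    """Pmf over observed step counts j >= 1 for the full forward model.

    Visible counts k are drawn from the mixture's binomial-dark kernel, with
    extra probability mass ``coloc_two_step`` assigned to k = 2 for random
    colocalization of independent monomers; each visible fluorophore then
    yields an observable step with probability ``p_step`` (finite-movie
    bleaching; 1.0 recovers the ideal model). The result is conditioned on
    j >= 1 (spots with no observed step are not scored).
    """
    if not 0.0 <= coloc_two_step <= 0.2:
        raise ValueError("coloc_two_step must be in [0, 0.2]")
    if not 0.0 < p_step <= 1.0:
        raise ValueError("p_step must be in (0, 1]")
    vis_k = visible_count_pmf(mixture, coloc_two_step)
    n_max = vis_k.size
    # thin each visible fluorophore by p_step
    obs = np.zeros(n_max + 1)
    for k in range(1, n_max + 1):
        if vis_k[k - 1] == 0:
            continue
        j = np.arange(0, k + 1)
        obs[: k + 1] += vis_k[k - 1] * stats.binom.pmf(j, k, p_step)
    obs[0] = 0.0
    total = obs.sum()
    if total <= 0:
        raise ValueError("no probability mass on observable steps")
    obs /= total
    return obs[1:]


def predict_categories(
    mixture: OligomerMixture,
    coloc_two_step: float = 0.0,
    p_step: float = 1.0,
) -> tuple[float, float, float]:
    """Expected (one, two, multi) step-category fractions under the forward
    model (binomial dark states + colocalization + optional finite-movie
    bleaching)."""
    pmf = observed_step_pmf(mixture, coloc_two_step, p_step)
    one = float(pmf[0])
    two = float(pmf[1]) if pmf.size >= 2 else 0.0
    multi = float(pmf[2:].sum()) if pmf.size >= 3 else 0.0
    return (one, two, multi)


def subtract_baseline(hist: StepHistogram, baseline_two_step: float) -> StepHistogram:
    """Apply the monomer-control correction: reduce the two-step fraction by
    the baseline measured for a monomeric control at comparable density,
    reassigning that mass to the one-step category (clipped at zero)."""
    if not 0.0 <= baseline_two_step < 1.0:
        raise ValueError("baseline must be in [0, 1)")
    fr = dict(hist.fractions)
    removed = min(baseline_two_step, fr["two_step"])
    if removed < baseline_two_step:
        warnings.warn(
            "baseline exceeds observed two-step fraction; clipping at zero",
            stacklevel=2,
        )
    fr["two_step"] -= removed
    fr["one_step"] += removed
    meta = dict(hist.meta)
    meta["baseline_subtracted"] = baseline_two_step
    meta["baseline_removed"] = removed
    return StepHistogram(
        counts=dict(hist.counts),
        fractions=fr,
        n_spots_analyzed=hist.n_spots_analyzed,
        n_spots_rejected=hist.n_spots_rejected,
        ci=dict(hist.ci),
        meta=meta,
    )


def _category_counts(hist: StepHistogram) -> np.ndarray:
    return np.array([hist.counts[c] for c in CATEGORIES], dtype=float)


def _neg_loglik(weights: np.ndarray, support, p_dark, coloc, p_step, counts) -> float:
    w = np.clip(weights, 1e-12, None)
    w = w / w.sum()
    mixture = OligomerMixture(dict(zip(support, w)), p_dark=p_dark)
    probs = np.clip(predict_categories(mixture, coloc, p_step), 1e-12, None)
    return -float(np.dot(counts, np.log(probs)))


def fit_mixture(
    hist: StepHistogram,
    p_dark: float = 0.30,
    support: tuple[int, ...] = DEFAULT_SUPPORT,
    coloc_two_step: float = 0.0,
    p_step: float = 1.0,
    sensitivity_grid: tuple[float, ...] = (0.25, 0.35),
    n_starts: int = 24,
) -> MixtureFit:
    """Maximum-likelihood oligomer-mixture weights on a fixed size support.

    Maximizes the multinomial likelihood of the (one, two, multi) counts
    under :func:`predict_categories`, over the weight simplex, with a
    deterministic multi-start (fixed low-discrepancy grid + SLSQP). Three
    observed categories cannot uniquely resolve more than three weights;
    when distinct optima tie in likelihood the fit is flagged degenerate.
    A sensitivity sweep over p_dark is attached to every fit.
    """
    support = tuple(sorted(int(n) for n in support))
    if not support:
        raise ValueError("support must be non-empty")
    counts = _category_counts(hist)
    if counts.sum() < 50:
        warnings.warn("fewer than 50 spots: mixture fit will be unstable", stacklevel=2)

    def solve(pd: float) -> tuple[dict[int, float], float, bool, bool]:
        k = len(support)
        starts = [np.full(k, 1.0 / k)]
        for i in range(k):
            e = np.full(k, 0.05 / max(k - 1, 1))
            e[i] = 0.95
            starts.append(e)
        rng = np.random.default_rng(12345)  # fixed: deterministic multi-start
        starts.extend(rng.dirichlet(np.ones(k), size=max(0, n_starts - len(starts))))
        best, best_x, solutions = np.inf, None, []
        for x0 in starts:
            res = optimize.minimize(
                _neg_loglik,
                x0,
                args=(support, pd, coloc_two_step, p_step, counts),
                method="SLSQP",
                bounds=[(0.0, 1.0)] * k,
                constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
                options={"maxiter": 200, "ftol": 1e-12},
            )
            if res.fun < best - 1e-9:
                best, best_x = res.fun, res.x
            if res.success:
                solutions.append((res.fun, res.x))
        if best_x is None:
            return dict.fromkeys(support, np.nan), np.nan, False, True
        w = np.clip(best_x, 0.0, None)
        w /= w.sum()
        # degenerate if another optimum ties in likelihood but differs in weights
        degenerate = any(
            f <= best + 1e-6 and np.max(np.abs(x / max(x.sum(), 1e-12) - w)) > 0.02
            for f, x in solutions
        )
        weights = {int(n): float(x) for n, x in zip(support, w.round(10))}
        return weights, -best, True, degenerate

    weights, loglik, ok, degenerate = solve(p_dark)
    if degenerate:
        warnings.warn(
            "likelihood is flat over the mixture support: weights are not "
            "uniquely identified by three categories",
            stacklevel=2,
        )
    sensitivity = {pd: solve(pd)[0] for pd in sensitivity_grid}
    return MixtureFit(
        weights=weights,
        p_dark=p_dark,
        log_likelihood=loglik,
        converged=ok,
        coloc_two_step=coloc_two_step,
        p_step=p_step,
        degenerate=degenerate,
        sensitivity=sensitivity,
    )


def bootstrap_histogram(
    calls: list[StepCall],
    B: int = 500,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> dict:
    """Nonparametric bootstrap over spots: percentile CIs for the category
    fractions and, when ``fit_kwargs`` is given, for the fitted mixture
    weights."""
    from oligocount.tirf import build_histogram

    if B < 200:
        raise ValueError("B must be >= 200 for stable percentile intervals")
    rng = np.random.default_rng(seed)
    usable = [c for c in calls if c.category != "rejected"]
    if not usable:
        raise ValueError("no non-rejected calls to resample")
    cats = np.array([CATEGORIES.index(c.category) for c in usable])
    n = cats.size
    frac_samples = np.empty((B, 3))
    weight_samples: list[dict[int, float]] = []
    for b in range(B):
        resampled = cats[rng.integers(0, n, size=n)]
        fr = np.bincount(resampled, minlength=3) / n
        frac_samples[b] = fr
        if fit_kwargs is not None:
            counts = np.bincount(resampled, minlength=3)
            hist = StepHistogram(
                counts=dict(zip(CATEGORIES, counts.tolist())),
                fractions=dict(zip(CATEGORIES, fr.tolist())),
                n_spots_analyzed=n,
                n_spots_rejected=0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                weight_samples.append(fit_mixture(hist, **fit_kwargs).weights)
    out: dict = {
        "fractions": {
            cat: tuple(np.percentile(frac_samples[:, i], [2.5, 97.5]))
            for i, cat in enumerate(CATEGORIES)
        }
    }
    if weight_samples:
        support = sorted(weight_samples[0])
        arr = np.array([[ws[s] for s in support] for ws in weight_samples])
        out["weights"] = {
            s: tuple(np.percentile(arr[:, i], [2.5, 97.5]))
            for i, s in enumerate(support)
        }
    return out
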