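"""Adaptive staircases, psychometric and sensitivity-function fitting, and
maximum-likelihood combination of thresholds across visual-field regions.

These tools are shared by the simulated model observer and by any
user-supplied human sensitivity tables.

* A three-down one-up staircase converges on the stimulus level producing
  (1/2)**(1/3) ~ 79.4% correct responses in a 2AFC task.  Steps are
  multiplicative (symmetric up/down factors, so the convergence point is the
  79.4% point), large (x1.5) until two reversals and finer (x1.26) after.
* Psychometric functions are cumulative normals in log stimulus level with
  the lower asymptote fixed at 0.5 (2AFC, no lapses), fit by least squares
  weighted by the binomial standard deviation of each level's proportion
  correct; the discrimination threshold is the 75%-correct point.
* The disparity sensitivity function (DSF) is a three-parameter log
  parabola: peak gain ``gamma_max`` (the peak of sensitivity = 1/threshold),
  peak frequency ``f_max`` (cycles/degree), and full bandwidth at half
  height ``beta`` (octaves):

      DSF(f) = log10(gamma_max)
               - log10(2) * ((log10 f - log10 f_max) / (log10(2**beta)/2))**2

* The MLE-optimal full-field threshold from independent regional estimates
  follows inverse-variance weighting: 1/T_opt**2 = sum_v 1/T_v**2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Staircase",
    "PsychometricFit",
    "DSFParams",
    "fit_psychometric",
    "fit_dsf",
    "dsf_log10",
    "dsf_sensitivity",
    "mle_combine",
    "simulate_staircase",
    "staircase_convergence_rate",
    "agreement_metrics",
    "CONVERGENCE_P",
]

#: Asymptotic percent-correct point of a symmetric 3-down-1-up staircase.
CONVERGENCE_P = 0.5 ** (1.0 / 3.0)  # ~0.7937


@dataclass
class Staircase:
    """Three-down one-up staircase state with multiplicative steps.

    The level (peak-to-trough disparity, arcmin) decreases by the step
    factor only after three consecutive correct responses and increases
    after any error.  The factor shrinks from ``factor_initial`` to
    ``factor_final`` once ``coarse_reversals`` reversals have occurred.
    """

    level: float = 20.0
    factor_initial: float = 1.5
    factor_final: float = 1.26
    coarse_reversals: int = 2
    min_level: float = 1e-3
    max_level: float = 240.0
    consecutive_correct: int = 0
    reversals: list = field(default_factory=list)
    history: list = field(default_factory=list)
    _last_direction: int = 0

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise ValueError("staircase level must be positive")

    @property
    def factor(self) -> float:
        if len(self.reversals) >= self.coarse_reversals:
            return self.factor_final
        return self.factor_initial

    def _move(self, direction: int) -> None:
        if self._last_direction and direction != self._last_direction:
            self.reversals.append(self.level)
        self._last_direction = direction
        f = self.factor
        new = self.level * f if direction > 0 else self.level / f
        self.level = float(np.clip(new, self.min_level, self.max_level))

    def update(self, correct: bool) -> "Staircase":
        """Record one trial outcome and apply the 3-down-1-up rule."""
        self.history.append((self.level, bool(correct)))
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= 3:
                self.consecutive_correct = 0
                self._move(-1)
        else:
            self.consecutive_correct = 0
            self._move(+1)
        return self


def simulate_staircase(prob_correct, n_trials: int, rng: np.random.Generator,
                       start_level: float = 20.0, **kwargs) -> Staircase:
    """Drive a staircase with a stationary observer ``prob_correct(level)``."""
    sc = Staircase(level=start_level, **kwargs)
    for _ in range(n_trials):
        sc.update(rng.random() < prob_correct(sc.level))
    return sc


def staircase_convergence_rate(threshold: float = 1.0, slope: float = 0.3,
                               n_trials: int = 12000, burn_in: int = 1000,
                               seed: int = 0,
                               start_level: float = 20.0) -> float:
    """Post-burn-in fraction correct of a simulated stationary 2AFC observer.

    The observer's probability correct is a cumulative normal in log level
    (``0.5 + 0.5 * Phi((ln x - ln threshold)/slope)``); for a 3-down-1-up
    rule with symmetric steps this fraction approaches (1/2)**(1/3).
    """
    rng = np.random.default_rng(seed)

    def p(level: float) -> float:
        return 0.5 + 0.5 * stats.norm.cdf(
            (math.log(level) - math.log(threshold)) / slope)

    sc = simulate_staircase(p, n_trials, rng, start_level=start_level)
    outcomes = np.array([c for _, c in sc.history[burn_in:]], dtype=float)
    return float(outcomes.mean())


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-normal fit in log-disparity with 2AFC lower asymptote.

    ``threshold75`` is the level at 75% correct (equal to ``exp(mu)`` since
    the curve is ``0.5 + 0.5*Phi((ln x - mu)/sigma)``); ``goodness`` is the
    weighted residual sum of squares; ``converged`` is False for degenerate
    data, in which case the threshold is pinned at the nearest tested bound.
    """

    mu: float
    sigma_pf: float
    threshold75: float
    goodness: float
    converged: bool = True


def _psychometric(logx: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return 0.5 + 0.5 * stats.norm.cdf((logx - mu) / sigma)


def psychometric_loss(trials, mu: float, sigma: float) -> float:
    """Weighted least-squares loss used by :func:`fit_psychometric`.

    Exposed so an independent minimizer can verify the fit on fixtures.
    """
    logx, p, w = _binned(trials)
    return float(np.sum(((p - _psychometric(logx, mu, sigma)) * w) ** 2))


#: Width of the level-grouping bins for psychometric fits, in natural-log
#: units (~0.25 octave).  Staircases with multiplicative steps visit many
#: nearly unique levels; grouping them stabilizes the per-level
#: proportions that the weighted fit consumes.
_LEVEL_BIN_WIDTH = 0.25 * math.log(2.0)


def _binned(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    levels = np.asarray([t[0] for t in trials], dtype=float)
    correct = np.asarray([t[1] for t in trials], dtype=float)
    if np.any(levels <= 0):
        raise ValueError("levels must be positive")
    log_levels = np.log(levels)
    bins = np.round(log_levels / _LEVEL_BIN_WIDTH).astype(int)
    uniq = np.unique(bins)
    n = np.empty(uniq.size)
    k = np.empty(uniq.size)
    center = np.empty(uniq.size)
    for i, b in enumerate(uniq):
        sel = bins == b
        n[i] = sel.sum()
        k[i] = correct[sel].sum()
        center[i] = log_levels[sel].mean()
    p = k / n
    # binomial SD of the proportion, continuity-corrected away from 0/1
    p_tilde = (k + 0.5) / (n + 1.0)
    sd = np.sqrt(p_tilde * (1.0 - p_tilde) / n)
    return center, p, 1.0 / sd


def fit_psychometric(trials, starts=None) -> PsychometricFit:
    """Fit a 2AFC cumulative normal to (level, correct) trials.

    Weighted least squares on the per-level proportions, weights equal to
    the reciprocal binomial standard deviation.  Requires at least two
    distinct levels; data that never straddle 75% correct are flagged as
    non-converged with the threshold pinned at the nearest tested level.
    ``starts`` overrides the default multi-start grid with explicit
    ``(mu0, sigma0)`` pairs (used by bootstrap refits, where the original
    fit is a good initializer).
    """
    logx, p, w = _binned(trials)
    if logx.size < 2:
        raise ValueError("need >= 2 distinct levels")

    lo, hi = logx.min(), logx.max()
    span = max(hi - lo, 1e-6)
    degenerate = bool(p.min() >= 0.75) or bool(p.max() <= 0.75)

    def resid(params):
        mu, log_sigma = params
        return (p - _psychometric(logx, mu, math.exp(log_sigma))) * w

    if starts is None:
        starts = [(mu0, s0) for mu0 in np.linspace(lo, hi, 5)
                  for s0 in (span / 8.0, span / 2.0)]
    best = None
    for mu0, s0 in starts:
        sol = optimize.least_squares(
            resid, x0=[float(np.clip(mu0, lo - 3 * span, hi + 3 * span)),
                       math.log(float(np.clip(s0, 1e-3, 10 * span + 1.0)))],
            bounds=([lo - 3 * span, math.log(1e-4)],
                    [hi + 3 * span, math.log(10 * span + 1.0)]))
        if best is None or sol.cost < best.cost:
            best = sol
    mu, sigma = best.x[0], math.exp(best.x[1])
    goodness = float(2 * best.cost)

    if degenerate:
        pinned = lo if p.min() >= 0.75 else hi
        return PsychometricFit(mu=float(pinned), sigma_pf=float(sigma),
                               threshold75=float(math.exp(pinned)),
                               goodness=goodness, converged=False)
    # report within half a log-unit of the tested levels; thresholds are
    # not meaningful further out than the staircases actually probed
    mu_clipped = float(np.clip(mu, lo - 0.5, hi + 0.5))
    return PsychometricFit(mu=mu_clipped, sigma_pf=float(sigma),
                           threshold75=float(math.exp(mu_clipped)),
                           goodness=goodness, converged=True)


@dataclass(frozen=True)
class DSFParams:
    """Log-parabola disparity-sensitivity-function parameters.

    ``gamma_max``: peak gain (units of the supplied sensitivities, e.g.
    1/arcmin); ``f_max``: peak frequency in cycles/degree; ``beta``: full
    bandwidth at half height in octaves.
    """

    gamma_max: float
    f_max: float
    beta: float


def dsf_log10(f, params: DSFParams) -> np.ndarray:
    """log10 sensitivity predicted by the log parabola at frequency ``f``."""
    f = np.asarray(f, dtype=float)
    half_bw = math.log10(2.0 ** params.beta) / 2.0
    dev = (np.log10(f) - math.log10(params.f_max)) / half_bw
    return math.log10(params.gamma_max) - math.log10(2.0) * dev**2


def dsf_sensitivity(f, params: DSFParams) -> np.ndarray:
    """Sensitivity (linear units) predicted by the log parabola."""
    return 10.0 ** dsf_log10(f, params)


def fit_dsf(frequencies, sensitivities, starts=None) -> DSFParams:
    """Least-squares log-parabola fit to (frequency, sensitivity) samples.

    The fit is performed on log10 sensitivity (the parabola's natural
    space), with multiple starts over a peak-frequency grid to avoid local
    minima.  The peak frequency is constrained to within one octave of the
    sampled frequency band: a peak further out is not identifiable from
    the data and shows up only as an extrapolated parabola limb with a
    runaway gain.  Requires at least three positive samples.
    """
    f = np.asarray(frequencies, dtype=float)
    s = np.asarray(sensitivities, dtype=float)
    ok = np.isfinite(f) & np.isfinite(s) & (f > 0) & (s > 0)
    f, s = f[ok], s[ok]
    if f.size < 3:
        raise ValueError("need >= 3 positive (frequency, sensitivity) pairs")
    y = np.log10(s)
    lf = np.log10(f)

    def resid(params):
        lg, lfm, beta = params
        half_bw = math.log10(2.0) * beta / 2.0
        return y - (lg - math.log10(2.0) * ((lf - lfm) / half_bw) ** 2)

    octave = math.log10(2.0)
    if starts is None:
        starts = [(y.max(), lfm0, beta0)
                  for lfm0 in np.linspace(lf.min() - 0.3, lf.max() + 0.3, 7)
                  for beta0 in (1.0, 2.5, 5.0)]
    best = None
    for lg0, lfm0, beta0 in starts:
        sol = optimize.least_squares(
            resid,
            x0=[float(np.clip(lg0, -6.0, 12.0)),
                float(np.clip(lfm0, lf.min() - octave, lf.max() + octave)),
                float(np.clip(beta0, 0.05, 30.0))],
            bounds=([-6.0, lf.min() - octave, 0.05],
                    [12.0, lf.max() + octave, 30.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    lg, lfm, beta = best.x
    return DSFParams(gamma_max=float(10.0 ** lg), f_max=float(10.0 ** lfm),
                     beta=float(beta))


def mle_combine(*thresholds: float) -> float:
    """MLE-optimal combined threshold, ``(sum_v 1/T_v**2) ** (-1/2)``.

    Infinite thresholds (unmeasurable regions) contribute nothing; any
    non-positive threshold is an error.  The optimal combination is never
    worse than the best single region.
    """
    ts = np.asarray(thresholds, dtype=float)
    if ts.size == 0:
        raise ValueError("need at least one threshold")
    if np.any(np.isnan(ts)) or np.any(ts <= 0):
        raise ValueError("thresholds must be positive (or +inf)")
    inv_sq = np.where(np.isinf(ts), 0.0, 1.0 / ts**2)
    total = inv_sq.sum()
    if total == 0.0:
        return float("inf")
    return float(total ** -0.5)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def agreement_metrics(model_sens: pd.DataFrame, human_sens: pd.DataFrame,
                      n_boot: int = 1000, seed: int = 0) -> dict:
    """Model-vs-human agreement with a between-participant noise ceiling.

    Both tables use the long schema ``{observer, region, frequency_cpd,
    sensitivity}`` (the model table may omit ``observer``).  Returns the
    Pearson ``r`` and ``r**2`` between model and participant-mean
    sensitivities on the matched condition grid, plus the noise ceiling:
    the squared, Fisher-z-averaged, bootstrapped 95% CI of the mean
    leave-one-out between-participant correlation.
    """
    cond = ["region", "frequency_cpd"]
    model = model_sens.set_index(cond)["sensitivity"].sort_index()
    pivot = human_sens.pivot_table(index=cond, columns="observer",
                                   values="sensitivity").sort_index()
    if pivot.shape[1] < 2:
        raise ValueError("need >= 2 participants for the noise ceiling")
    if not model.index.equals(pivot.index):
        raise ValueError("model and human condition grids do not match")

    mean_h = pivot.mean(axis=1)
    r = float(np.corrcoef(model.values, mean_h.values)[0, 1])

    observers = list(pivot.columns)
    loo = []
    for obs in observers:
        others = pivot.drop(columns=obs).mean(axis=1)
        loo.append(np.corrcoef(pivot[obs].values, others.values)[0, 1])
    loo = np.asarray(loo)

    rng = np.random.default_rng(seed)
    if np.allclose(loo, loo[0]):
        ci = (float(loo[0] ** 2), float(loo[0] ** 2))
    else:
        boots = np.empty(n_boot)
        for b in range(n_boot):
            sample = rng.choice(loo, size=loo.size, replace=True)
            boots[b] = np.tanh(_fisher_z(sample).mean())
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo ** 2), float(hi ** 2))
    return {
        "r": r,
        "r2": r * r,
        "noise_ceiling": ci,
        "between_participant_r": float(np.tanh(_fisher_z(loo).mean())),
    }
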