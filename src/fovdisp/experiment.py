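"""Model-as-observer experiments: staircase-driven threshold measurement
across visual-field conditions, DSF summaries, MLE comparison, and
parameter/architecture sweeps.

The protocol mirrors the psychophysical design: four field conditions
(0-3, 3-9, 9-21 and 0-21 degrees of eccentricity) crossed with six
corrugation frequencies, each threshold measured by randomly interleaved
three-down one-up staircases whose pooled trials are fit with a weighted
cumulative normal.  A ``scale`` factor shrinks the number of staircases and
trials for desk-scale runs; the full protocol is 24 staircases x 75 trials
per condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelObserver, make_observer
from .psychophysics import (
    DSFParams,
    fit_dsf,
    fit_psychometric,
    mle_combine,
    Staircase,
)
from .stimulus import PROTOCOL_FREQUENCIES, StimulusSpec

__all__ = [
    "Protocol",
    "bootstrap_experiment",
    "ConditionResult",
    "ExperimentResult",
    "REGIONS",
    "run_condition",
    "run_experiment",
    "run_sweep",
    "mle_report",
    "dsf_table",
]

#: Annular field conditions in degrees of eccentricity.
REGIONS = {
    "fovea": (0.0, 3.0),
    "mid": (3.0, 9.0),
    "far": (9.0, 21.0),
    "full": (0.0, 21.0),
}

_SUB_REGIONS = ("fovea", "mid", "far")


@dataclass(frozen=True)
class Protocol:
    """Experimental protocol (defaults: the full human protocol)."""

    frequencies: tuple[float, ...] = PROTOCOL_FREQUENCIES
    regions: tuple[str, ...] = ("fovea", "mid", "far", "full")
    n_staircases: int = 24
    n_trials: int = 75
    start_level: float = 20.0
    max_level: float = 240.0

    def scaled(self, scale: float) -> "Protocol":
        """Shrink the protocol for desk-scale runs.

        The staircase count shrinks linearly with ``scale``; the trials
        per staircase shrink with its square root so each staircase still
        descends from the clearly-visible start level into the threshold
        region (scale 0.2 gives 5 staircases x 34 trials).
        """
        return replace(
            self,
            n_staircases=max(2, int(round(self.n_staircases * scale))),
            n_trials=max(15, int(round(self.n_trials * math.sqrt(scale)))),
        )


@dataclass
class ConditionResult:
    """Threshold estimate for one (region, frequency) condition.

    ``trials`` holds the (level, correct) pairs grouped by staircase, so
    uncertainty can be bootstrapped after the fact with the staircase as
    the resampling unit (trials within a staircase are serially
    dependent through the adaptive rule).
    """

    region: str
    frequency: float
    threshold: float
    sensitivity: float
    converged: bool
    n_trials: int
    trials: list | None = None


@dataclass
class ExperimentResult:
    """Thresholds, DSF fits and the MLE comparison for one model run."""

    table: pd.DataFrame
    dsf: dict[str, DSFParams]
    protocol: Protocol
    trials: dict = field(default_factory=dict)

    def sensitivities(self, region: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[self.table.region == region].sort_values("frequency")
        return sub.frequency.to_numpy(), sub.sensitivity.to_numpy()


def _trial_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_condition(observer: ModelObserver, region: str, frequency: float,
                  protocol: Protocol, seed: int) -> ConditionResult:
    """Measure one threshold with interleaved staircases on the model.

    Each trial draws a random tilt (45/135), synthesizes a fresh seeded
    stereogram at the staircase's current peak-to-trough disparity, runs
    the model's tilt decision, and updates the staircase; all trials are
    pooled for the psychometric fit and the threshold is the 75% point.
    """
    inner, outer = REGIONS[region]
    root = np.random.SeedSequence(entropy=seed)
    model_rng = np.random.default_rng(root.spawn(1)[0])
    trial_stream = np.random.default_rng(root.spawn(1)[0])

    stairs = [
        Staircase(level=protocol.start_level, max_level=protocol.max_level)
        for _ in range(protocol.n_staircases)
    ]
    for _ in range(protocol.n_trials):
        for sc in stairs:
            tilt = 45.0 if trial_stream.random() < 0.5 else 135.0
            spec = StimulusSpec(
                corrugation_frequency=frequency,
                peak_to_trough_disparity=sc.level,
                tilt=tilt,
                annulus_inner=inner,
                annulus_outer=outer,
                field_radius=observer.field_radius_deg,
                pixels_per_degree=observer.pixels_per_degree,
                rng_seed=int(trial_stream.integers(2**31)),
                phase=float(trial_stream.uniform(0.0, 2.0 * np.pi)),
            )
            from .stimulus import make_stimulus

            pair = make_stimulus(spec)
            response = observer.respond(pair, model_rng)
            sc.update(response.decision == tilt)

    by_staircase = [list(sc.history) for sc in stairs]
    trials = [t for sc in by_staircase for t in sc]
    fit = fit_psychometric(trials)
    threshold = float(fit.threshold75)
    return ConditionResult(region=region, frequency=frequency,
                           threshold=threshold,
                           sensitivity=1.0 / threshold,
                           converged=fit.converged, n_trials=len(trials),
                           trials=by_staircase)


def run_experiment(observer: ModelObserver, protocol: Protocol,
                   seed: int) -> ExperimentResult:
    """Run all (region, frequency) conditions and fit per-region DSFs."""
    root = np.random.SeedSequence(entropy=seed)
    rows = []
    trials_by_condition: dict = {}
    for region in protocol.regions:
        for frequency in protocol.frequencies:
            cond_seed = _trial_seed(root.spawn(1)[0])
            res = run_condition(observer, region, frequency, protocol,
                                cond_seed)
            row = {k: v for k, v in vars(res).items() if k != "trials"}
            rows.append(row)
            trials_by_condition[(region, frequency)] = res.trials
    table = pd.DataFrame(rows)

    dsf: dict[str, DSFParams] = {}
    for region in protocol.regions:
        sub = table[table.region == region]
        try:
            dsf[region] = fit_dsf(sub.frequency, sub.sensitivity)
        except ValueError:
            warnings.warn(f"DSF fit skipped for region {region!r}")
    return ExperimentResult(table=table, dsf=dsf, protocol=protocol,
                            trials=trials_by_condition)


def mle_report(result: ExperimentResult) -> pd.DataFrame:
    """Per-frequency MLE-optimal thresholds from the three sub-regions.

    Rows with any missing sub-region are skipped with a warning.  The
    returned frame carries the measured full-field threshold (when
    present) next to the optimal combination.
    """
    t = result.table
    rows = []
    for frequency in sorted(t.frequency.unique()):
        sub = t[t.frequency == frequency]
        by_region = {r.region: r.threshold for r in sub.itertuples()}
        missing = [r for r in _SUB_REGIONS if r not in by_region]
        if missing:
            warnings.warn(
                f"frequency {frequency}: missing regions {missing}; "
                "row skipped")
            continue
        t_opt = mle_combine(*(by_region[r] for r in _SUB_REGIONS))
        rows.append({
            "frequency": frequency,
            "T_fovea": by_region["fovea"],
            "T_mid": by_region["mid"],
            "T_far": by_region["far"],
            "T_full_measured": by_region.get("full", np.nan),
            "T_full_optimal": t_opt,
            "sensitivity_optimal": 1.0 / t_opt,
        })
    report = pd.DataFrame(rows)
    if len(report) >= 3:
        result.dsf["mle_optimal"] = fit_dsf(report.frequency,
                                            report.sensitivity_optimal)
    return report


def bootstrap_experiment(result: ExperimentResult, n_boot: int = 200,
                         seed: int = 0) -> dict:
    """Bootstrap sensitivities and DSF parameters by resampling staircases.

    Because trials within a staircase are serially dependent (the
    adaptive rule decides each level from the previous outcomes), the
    resampling unit is the whole staircase: staircases are drawn with
    replacement within each condition, their trials pooled, the
    psychometric function refit (initialized at the original solution),
    and the per-region DSF refit on the resulting sensitivities.  Returns
    ``{"sensitivity": {(region, freq): array}, "dsf": {region: {"f_max":
    array, "gamma_max": array}}}`` with one entry per bootstrap draw.
    """
    rng = np.random.default_rng(seed)
    sens_boot: dict = {key: np.empty(n_boot) for key in result.trials}
    starts_cache: dict = {}
    for key, staircases in result.trials.items():
        if not staircases:
            sens_boot.pop(key)
            continue
        pooled = [t for sc in staircases for t in sc]
        base = fit_psychometric(pooled)
        starts_cache[key] = [(base.mu, max(base.sigma_pf, 1e-3))]
        n_sc = len(staircases)
        for b in range(n_boot):
            idx = rng.integers(n_sc, size=n_sc)
            sample = [t for i in idx for t in staircases[i]]
            try:
                fit = fit_psychometric(sample, starts=starts_cache[key])
                sens_boot[key][b] = 1.0 / fit.threshold75
            except ValueError:
                sens_boot[key][b] = np.nan

    regions = sorted({r for r, _ in sens_boot})
    dsf_boot: dict = {}
    for region in regions:
        freqs = sorted(f for r, f in sens_boot if r == region)
        if len(freqs) < 3 or region not in result.dsf:
            continue
        base = result.dsf[region]
        start = [(math.log10(base.gamma_max), math.log10(base.f_max),
                  base.beta)]
        fm = np.empty(n_boot)
        gm = np.empty(n_boot)
        for b in range(n_boot):
            sens = [sens_boot[(region, f)][b] for f in freqs]
            try:
                fit = fit_dsf(freqs, sens, starts=start)
                fm[b], gm[b] = fit.f_max, fit.gamma_max
            except ValueError:
                fm[b] = gm[b] = np.nan
        dsf_boot[region] = {"f_max": fm, "gamma_max": gm}
    return {"sensitivity": sens_boot, "dsf": dsf_boot}


def dsf_table(result: ExperimentResult) -> pd.DataFrame:
    """Tidy frame of fitted DSF parameters per region."""
    rows = [
        {"region": region, "gamma_max": p.gamma_max, "f_max": p.f_max,
         "beta": p.beta}
        for region, p in result.dsf.items()
    ]
    return pd.DataFrame(rows)


def run_sweep(axis: str, values, protocol: Protocol, seed: int,
              pixels_per_degree: float = 4.0,
              base_kwargs: dict | None = None
              ) -> dict[object, ExperimentResult]:
    """Re-run the experiment while sweeping one model axis.

    ``axis`` is one of ``cr`` (compression ratio), ``rf_sigma`` (cortical
    receptive-field scale factor), ``noise`` (noise scale factor) or
    ``variant`` (architecture name).  Returns one
    :class:`ExperimentResult` per swept value, all sharing the seed so
    differences reflect the swept parameter.
    """
    if axis not in ("cr", "rf_sigma", "noise", "variant"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    base = dict(base_kwargs or {})
    out: dict[object, ExperimentResult] = {}
    for value in values:
        kwargs = dict(base)
        if axis == "cr":
            kwargs["cr"] = float(value)
            observer = make_observer(pixels_per_degree=pixels_per_degree,
                                     **kwargs)
        elif axis == "rf_sigma":
            kwargs["rf_scale"] = float(value)
            observer = make_observer(pixels_per_degree=pixels_per_degree,
                                     **kwargs)
        elif axis == "noise":
            kwargs["noise_scale"] = float(value)
            observer = make_observer(pixels_per_degree=pixels_per_degree,
                                     **kwargs)
        else:
            observer = make_observer(variant=str(value),
                                     pixels_per_degree=pixels_per_degree,
                                     **kwargs)
        out[value] = run_experiment(observer, protocol, seed)
    return out
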