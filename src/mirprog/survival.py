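"""Survival analysis: Kaplan-Meier, Cox models and time-dependent ROC.

Relapse-free survival is administratively censored at 10 years.  Marker
performance is assessed two ways: the hazard ratio from a Cox
proportional-hazards model (Efron tie handling), and the
cumulative-case / dynamic-control time-dependent ROC of Heagerty,
Lumley and Pepe, whose sensitivity and specificity at horizon t are
obtained by Bayes inversion of Kaplan-Meier survival within marker
strata:

    sens(c, t) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
    spec(c, t) = S(t | X <= c) P(X <= c) / S(t)

Markers are compared by a subject-level bootstrap: each resample yields
a paired (standardized log-HR, AUC) estimate per marker, and marker
pairs are contrasted with a paired Student t test across resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats


@dataclass
class SurvivalOutcome:
    sample_id: str
    time: float  # years
    event: bool

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(f"{self.sample_id}: follow-up time must be finite and > 0")
        self.event = bool(self.event)


@dataclass
class CoxFit:
    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_95: pd.DataFrame  # columns lower, upper (on the HR scale)
    wald_p: pd.Series
    n_events: int
    converged: bool


@dataclass
class TdROCResult:
    horizon: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def outcomes_frame(outcomes: list[SurvivalOutcome]) -> pd.DataFrame:
    return pd.DataFrame({"time": [o.time for o in outcomes],
                         "event": [o.event for o in outcomes]},
                        index=[o.sample_id for o in outcomes])


def censor_at(outcomes: list[SurvivalOutcome], horizon: float = 10.0) -> list[SurvivalOutcome]:
    """Cap follow-up at ``horizon`` years; later events become censored."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    return [replace(o, time=min(o.time, horizon), event=o.event and o.time <= horizon)
            for o in outcomes]


def kaplan_meier(outcomes: list[SurvivalOutcome],
                 groups: np.ndarray | None = None) -> dict[object, pd.DataFrame]:
    """Product-limit survival estimate, optionally per group.

    Returns a mapping group label -> DataFrame with columns time, survival.
    With ``groups=None`` the single key is ``"all"``.
    """
    if not outcomes:
        raise ValueError("no subjects")
    df = outcomes_frame(outcomes)
    if groups is None:
        groups = np.array(["all"] * len(outcomes), dtype=object)
    groups = np.asarray(groups)
    curves: dict[object, pd.DataFrame] = {}
    for g in pd.unique(groups):
        sub = df[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(float),
                                  "survival": sf.iloc[:, 0].to_numpy(float)})
    return curves


def km_survival_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit S(t) for one stratum (fast path used inside the tdROC)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    ev_times = np.unique(time[event & (time <= t)])
    s = 1.0
    for u in ev_times:
        at_risk = np.sum(time >= u)
        d = np.sum(event & (time == u))
        s *= 1.0 - d / at_risk
    return float(s)


def cox_fit(covariates: pd.DataFrame, outcomes: list[SurvivalOutcome],
            standardize: bool = False) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) via partial likelihood.

    ``covariates`` is samples x covariates, indexed by sample id and
    aligned with ``outcomes``.  With ``standardize=True`` each covariate
    is scaled to unit variance first so hazard ratios of different
    markers are comparable.
    """
    df = outcomes_frame(outcomes)
    if not df["event"].any():
        raise ValueError("no events; Cox model undefined")
    X = covariates.loc[df.index].astype(float)
    if (X.std(ddof=0) == 0).any():
        bad = X.columns[(X.std(ddof=0) == 0)].tolist()
        raise ValueError(f"constant covariates: {bad}")
    if standardize:
        X = X / X.std(ddof=1)
    data = pd.concat([X, df], axis=1)
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model did not converge: {err}") from err
    summ = cph.summary
    return CoxFit(
        coefficients=summ["coef"].copy(),
        hazard_ratios=summ["exp(coef)"].copy(),
        ci_95=summ[["exp(coef) lower 95%", "exp(coef) upper 95%"]]
        .set_axis(["lower", "upper"], axis=1).copy(),
        wald_p=summ["p"].copy(),
        n_events=int(df["event"].sum()),
        converged=converged,
    )


def td_roc(marker: np.ndarray, outcomes: list[SurvivalOutcome], horizon: float,
            monotone: bool = True) -> TdROCResult:
    """Cumulative/dynamic time-dependent ROC at ``horizon`` years.

    Cases are subjects with an event by the horizon; controls are those
    event-free past it.  Sensitivity and specificity at each marker
    cutoff come from Kaplan-Meier survival within the two marker strata
    (Bayes inversion), and the AUC is the trapezoidal area under the
    curve after sorting by false-positive rate.  ``monotone`` applies a
    running maximum to the sensitivities so the reported curve is
    non-decreasing (a no-op without censoring).
    """
    marker = np.asarray(marker, dtype=float)
    df = outcomes_frame(outcomes)
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(bool)
    if marker.size != time.size:
        raise ValueError("marker and outcomes misaligned")
    if not np.any(event & (time <= horizon)):
        raise ValueError("no events before the horizon")

    s_all = km_survival_at(time, event, horizon)
    if s_all in (0.0, 1.0):
        raise ValueError("degenerate overall survival at the horizon")
    cutoffs = np.unique(marker)
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    n = marker.size
    for i, c in enumerate(cutoffs):
        hi = marker > c
        p_hi = hi.mean()
        s_hi = km_survival_at(time[hi], event[hi], horizon) if hi.any() else 1.0
        s_lo = km_survival_at(time[~hi], event[~hi], horizon) if (~hi).any() else 1.0
        sens[i] = (1.0 - s_hi) * p_hi / (1.0 - s_all)
        spec[i] = s_lo * (1.0 - p_hi) / s_all
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # sweep the curve by descending cutoff: (0,0) at the top cutoff up to (1,1);
    # under censoring the raw estimator can wiggle, so optionally enforce
    # monotonicity with a running maximum in this natural order
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    if monotone:
        fpr = np.maximum.accumulate(fpr)
        tpr = np.maximum.accumulate(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return TdROCResult(horizon, cutoffs, sens, spec, auc)


def compare_markers(markers: dict[str, np.ndarray], outcomes: list[SurvivalOutcome],
                    horizon: float, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Paired bootstrap comparison of markers by standardized Cox HR and tdROC AUC.

    Subjects are resampled with replacement; resamples with zero events
    (or a degenerate horizon) are redrawn.  Returns a tidy table with one
    row per marker pair, the mean paired differences, and paired-t
    p-values; the per-resample estimates are attached as ``.attrs["resamples"]``.
    """
    names = list(markers)
    if len(names) < 2:
        raise ValueError("need at least 2 markers")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(outcomes)
    rows = []
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        sub = [replace(outcomes[i], sample_id=f"b{j}") for j, i in enumerate(idx)]
        times = np.array([o.time for o in sub])
        events = np.array([o.event for o in sub])
        if not np.any(events & (times <= horizon)) or km_survival_at(times, events, horizon) == 0:
            redrawn += 1
            continue
        rec: dict[str, float] = {}
        ok = True
        for name in names:
            m = np.asarray(markers[name], dtype=float)[idx]
            if np.ptp(m) == 0:
                ok = False
                break
            cov = pd.DataFrame({name: m}, index=[o.sample_id for o in sub])
            try:
                fit = cox_fit(cov, sub, standardize=True)
            except RuntimeError:
                ok = False
                break
            rec[f"loghr_{name}"] = float(fit.coefficients.iloc[0])
            rec[f"auc_{name}"] = td_roc(m, sub, horizon).auc
        if not ok:
            redrawn += 1
            continue
        rows.append(rec)
        b += 1
    res = pd.DataFrame(rows)

    out = []
    for i, a in enumerate(names):
        for bname in names[i + 1:]:
            d_hr = res[f"loghr_{a}"] - res[f"loghr_{bname}"]
            d_auc = res[f"auc_{a}"] - res[f"auc_{bname}"]
            t_hr = stats.ttest_rel(res[f"loghr_{a}"], res[f"loghr_{bname}"])
            t_auc = stats.ttest_rel(res[f"auc_{a}"], res[f"auc_{bname}"])
            out.append({"marker_a": a, "marker_b": bname,
                        "mean_diff_loghr": float(d_hr.mean()),
                        "p_loghr": float(t_hr.pvalue) if np.isfinite(t_hr.pvalue) else 1.0,
                        "mean_diff_auc": float(d_auc.mean()),
                        "p_auc": float(t_auc.pvalue) if np.isfinite(t_auc.pvalue) else 1.0,
                        "n_boot": n_boot, "n_redrawn": redrawn})
    table = pd.DataFrame(out)
    table.attrs["resamples"] = res
    table.attrs["method"] = "subject-level bootstrap, paired t test across resamples"
    return table
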