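"""Naive-pooled compartmental model fitting and selection.

The workflow mirrors a classical naive-averaged analysis of sparse
intravenous concentration data: per-timepoint means across subjects form a
single dose-response curve per dose group, which is fitted to candidate
mammillary structures (1, 2 or 3 compartments, linear or Michaelis-Menten
clearance) by proportional-error weighted least squares,

    SSR = sum_i ((obs_i - pred_i) / pred_i)^2,

with predictions produced by the simulation module under the study's
30-second infusion.  Optimization runs in log-parameter space (positivity
for free, spans the orders of magnitude between volumes and rate
constants) from multiple seeded starts.  Candidates are ranked by AICc,
with near-ties (delta < 2) resolved toward fewer parameters.

Because a single 6-point mean curve cannot support the AICc small-sample
correction for the larger candidates, model selection is normally run on
the two dose-group curves jointly with shared parameters — which is also
what makes the Michaelis-Menten pair (Vm, Km) identifiable, since
saturable clearance only reveals itself across dose levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .pk_core import EffectSiteParams, PKParameters
from .simulation import DosingRegimen, peak, predict_plasma, simulate

__all__ = [
    "ModelStructure",
    "CANDIDATE_STRUCTURES",
    "FitDataset",
    "FitResult",
    "SelectionResult",
    "CVSummary",
    "FitConvergenceError",
    "naive_average",
    "fit_compartment_model",
    "select_model",
    "tune_effect_site",
    "cv_reduction",
]

END_OF_ADMINISTRATION_MIN = 0.75  # 30 s drug infusion + 15 s saline flush


class FitConvergenceError(RuntimeError):
    """No multistart run converged to a usable optimum."""


@dataclass(frozen=True)
class ModelStructure:
    """A candidate compartmental structure: 1/2/3 compartments × clearance."""

    n_compartments: int
    clearance: str  # "linear" | "mm"

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise ValueError("n_compartments must be 1, 2 or 3")
        if self.clearance not in ("linear", "mm"):
            raise ValueError("clearance must be 'linear' or 'mm'")

    @property
    def label(self) -> str:
        return f"{self.n_compartments}C-{'MM' if self.clearance == 'mm' else 'linear'}"

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["Vc"]
        if self.n_compartments >= 2:
            names += ["Vp", "Q12"]
        if self.n_compartments == 3:
            names += ["Vp2", "Q13"]
        names += ["Vm", "Km"] if self.clearance == "mm" else ["CL"]
        return tuple(names)

    def build(self, values: dict[str, float]) -> PKParameters:
        return PKParameters(n_peripheral=self.n_compartments - 1,
                            **{k: values[k] for k in self.param_names})


CANDIDATE_STRUCTURES = tuple(
    ModelStructure(n, c) for n in (1, 2, 3) for c in ("linear", "mm")
)

# wide default bounds in canonical units (L, L/min, mg/min, mg/L); they
# span both unit dialects of the shipped parameter table
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Vc": (1e-3, 5e3),
    "Vp": (1e-3, 5e4),
    "Q12": (1e-4, 5e3),
    "Vp2": (1e-3, 5e4),
    "Q13": (1e-4, 5e3),
    "Vm": (1e-3, 1e3),
    "Km": (1e-6, 1e3),
    "CL": (1e-4, 1e4),
}


@dataclass(frozen=True)
class FitDataset:
    """One observed mean concentration curve plus the regimen that made it.

    ``times`` in minutes from infusion start, ``conc`` in mg/L; pre-dose
    and zero-concentration rows must already be excluded (proportional
    weighting is undefined at zero).
    """

    times: np.ndarray
    conc: np.ndarray
    regimen: DosingRegimen

    @classmethod
    def from_series(cls, series: pd.DataFrame, regimen: DosingRegimen) -> "FitDataset":
        """Build from a (time_min, conc_ng_ml) table, dropping unusable rows."""
        col = "conc_ng_ml" if "conc_ng_ml" in series.columns else "mean_ng_ml"
        s = series[(series[col] > 0) & (series["time_min"] > 0)]
        return cls(times=s["time_min"].to_numpy(dtype=float),
                   conc=s[col].to_numpy(dtype=float) / 1000.0,
                   regimen=regimen)

    def __post_init__(self) -> None:
        if self.times.size != self.conc.size:
            raise ValueError("times and conc must have equal length")
        if np.any(self.conc <= 0):
            raise ValueError("zero/negative concentrations cannot be fitted "
                             "under proportional weighting")


@dataclass
class CVSummary:
    """Per-timepoint dispersion of a cohort plus the windowed average CV.

    ``window_cv_pct`` averages the per-timepoint CVs at sampling times
    falling 2-30 min after the end of drug administration.
    """

    table: pd.DataFrame
    window_cv_pct: float
    window_min: tuple[float, float] = (2.0, 30.0)
    flags: list[str] = field(default_factory=list)


def naive_average(cohort: pd.DataFrame,
                  end_of_administration: float = END_OF_ADMINISTRATION_MIN,
                  ) -> tuple[pd.DataFrame, CVSummary]:
    """Per-timepoint mean curve and CV summary for one dose group.

    Requires >= 2 subjects sampled on a common time grid.  Returns the
    mean series (time_min, mean_ng_ml, sd_ng_ml, cv_pct, n) and a
    :class:`CVSummary` whose windowed CV uses only sampling times 2-30 min
    post-administration.  A zero mean makes the CV at that time undefined
    (NaN, flagged), as for the pre-dose sample.
    """
    groups = cohort["dose_mg_per_kg"].unique() if "dose_mg_per_kg" in cohort.columns else [None]
    if len(groups) > 1:
        raise ValueError("cohort mixes dose groups; average each group separately")
    wide = cohort.pivot_table(index="time_min", columns="subject_id",
                              values="conc_ng_ml", aggfunc="first")
    if wide.shape[1] < 2:
        raise ValueError("naive averaging requires at least 2 subjects")
    if wide.isna().any().any():
        raise ValueError("subjects do not share a common sampling schedule")

    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean * 100.0, np.nan)
    table = pd.DataFrame({
        "time_min": wide.index.to_numpy(dtype=float),
        "mean_ng_ml": mean.to_numpy(),
        "sd_ng_ml": sd.to_numpy(),
        "cv_pct": cv,
        "n": wide.notna().sum(axis=1).to_numpy(),
    }).reset_index(drop=True)

    flags = []
    if np.isnan(cv).any():
        flags.append("CV undefined at timepoints with zero mean")
    post = table["time_min"] - end_of_administration
    in_window = (post >= 2.0) & (post <= 30.0) & ~np.isnan(table["cv_pct"])
    window_cv = float(table.loc[in_window, "cv_pct"].mean()) if in_window.any() else float("nan")
    summary = CVSummary(table=table, window_cv_pct=window_cv, flags=flags)
    mean_series = table[["time_min", "mean_ng_ml", "n"]].copy()
    return mean_series, summary


@dataclass
class FitResult:
    """Outcome of a multistart weighted-least-squares compartmental fit."""

    structure: ModelStructure
    params: PKParameters
    estimates: dict[str, float]
    objective: float
    aicc: float
    bic: float
    residuals: np.ndarray
    n_obs: int
    n_params: int
    converged: bool
    n_starts: int
    start_objectives: list[float]
    seed: Optional[int] = None
    warnings: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.structure.label

    def report(self) -> str:
        lines = [f"model {self.label}: objective {self.objective:.6g}, "
                 f"AICc {self.aicc:.4g}, BIC {self.bic:.4g}, n={self.n_obs}"]
        for k in self.structure.param_names:
            lines.append(f"  {k:>4} = {self.estimates[k]:.6g}")
        for w in self.warnings:
            lines.append(f"  WARNING: {w}")
        return "\n".join(lines)


def _information_criteria(ssr: float, n: int, p: int) -> tuple[float, float]:
    """(AICc, BIC) for a least-squares fit; k counts the error variance."""
    k = p + 1
    ssr = max(ssr, 1e-300)
    aic = n * math.log(ssr / n) + 2 * k
    bic = n * math.log(ssr / n) + k * math.log(n)
    if n - k - 1 >= 1:
        aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = float("inf")
    return aicc, bic


def _heuristic_start(structure: ModelStructure, datasets: Sequence[FitDataset],
                     bounds: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Data-driven starting values: dilution volume from Cmax, clearance
    from a trapezoidal AUC, distribution roughly central-sized."""
    d = datasets[0]
    dose = d.regimen.total_dose()
    cmax = float(np.max(d.conc))
    auc = float(np.trapezoid(d.conc, d.times)) + cmax  # rough tail allowance
    vc = dose / cmax
    start = {"Vc": vc, "Vp": 3.0 * vc, "Q12": 0.5 * vc,
             "Vp2": 5.0 * vc, "Q13": 0.1 * vc,
             "CL": dose / auc, "Vm": dose / 20.0, "Km": cmax / 3.0}
    return {k: float(np.clip(start[k], bounds[k][0] * 1.01, bounds[k][1] * 0.99))
            for k in structure.param_names}


def _residual_fn(structure: ModelStructure, datasets: Sequence[FitDataset],
                 solver_rtol: float):
    names = structure.param_names
    n_total = sum(d.times.size for d in datasets)

    def residuals(logx: np.ndarray) -> np.ndarray:
        values = dict(zip(names, np.exp(logx)))
        try:
            p = structure.build(values)
            out = []
            for d in datasets:
                pred = predict_plasma(p, d.regimen, d.times, rtol=solver_rtol)
                pred = np.maximum(pred, 1e-9)
                out.append((d.conc - pred) / pred)
            return np.concatenate(out)
        except Exception:
            # invalid parameter combination or solver breakdown: flat
            # high-cost residual steers the optimizer away
            return np.full(n_total, 1e6)

    return residuals


def fit_compartment_model(
    datasets: Union[FitDataset, Sequence[FitDataset]],
    structure: ModelStructure = ModelStructure(2, "mm"),
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    n_starts: int = 20,
    seed: int = 0,
    ls_tol: float = 1e-10,
    solver_rtol: float = 1e-7,
) -> FitResult:
    """Fit one candidate structure by proportional-error least squares.

    Multistart: one data-driven heuristic start plus seeded log-uniform
    draws within bounds; the best converged start is reported.  ``ls_tol``
    sets the optimizer's ftol/xtol/gtol and ``solver_rtol`` the ODE
    tolerance of the prediction path; the tight defaults suit one-off
    fits, while replicate studies may relax them.  Raises ``ValueError``
    for infeasible bounds and :class:`FitConvergenceError` when every
    start fails.
    """
    if isinstance(datasets, FitDataset):
        datasets = [datasets]
    n_obs = int(sum(d.times.size for d in datasets))
    names = structure.param_names
    p = len(names)
    if n_obs < p:
        raise ValueError(f"{n_obs} observations cannot identify {p} parameters")

    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    for k in names:
        lo, hi = b[k]
        if not (0 < lo < hi):
            raise ValueError(f"infeasible bounds for {k}: ({lo}, {hi})")
    lb = np.log([b[k][0] for k in names])
    ub = np.log([b[k][1] for k in names])

    rng = np.random.default_rng(seed)
    starts = [np.log(np.array([_heuristic_start(structure, datasets, b)[k] for k in names]))]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(lb, ub))

    fn = _residual_fn(structure, datasets, solver_rtol)
    best = None
    start_objectives: list[float] = []
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(fn, x0, bounds=(lb, ub), method="trf",
                                x_scale="jac", ftol=ls_tol, xtol=ls_tol, gtol=ls_tol)
        except Exception:
            start_objectives.append(float("inf"))
            continue
        obj = float(np.sum(sol.fun ** 2))
        start_objectives.append(obj)
        if np.isfinite(obj) and (best is None or obj < best[0]):
            best = (obj, sol)
    if best is None:
        raise FitConvergenceError(
            f"all {len(starts)} starts failed for {structure.label}")

    obj, sol = best
    values = dict(zip(names, np.exp(sol.x)))
    warnings = [f"{k} at bound" for k, xi, lo, hi in zip(names, sol.x, lb, ub)
                if xi - lo < 1e-6 or hi - xi < 1e-6]
    aicc, bic = _information_criteria(obj, n_obs, p)
    return FitResult(
        structure=structure,
        params=structure.build(values),
        estimates=values,
        objective=obj,
        aicc=aicc,
        bic=bic,
        residuals=sol.fun.copy(),
        n_obs=n_obs,
        n_params=p,
        converged=bool(sol.success),
        n_starts=len(starts),
        start_objectives=start_objectives,
        seed=seed,
        warnings=warnings,
    )


@dataclass
class SelectionResult:
    """Ranked candidate fits plus any candidates excluded for failure."""

    ranked: list[FitResult]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def best(self) -> FitResult:
        return self.ranked[0]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": f.label, "n_params": f.n_params, "objective": f.objective,
            "AICc": f.aicc, "BIC": f.bic,
        } for f in self.ranked])


def select_model(
    datasets: Union[FitDataset, Sequence[FitDataset]],
    candidates: Sequence[ModelStructure] = CANDIDATE_STRUCTURES,
    n_starts: int = 10,
    seed: int = 0,
    ls_tol: float = 1e-10,
    solver_rtol: float = 1e-7,
) -> SelectionResult:
    """Fit all candidates on the same data and rank by AICc.

    Near-ties (delta AICc < 2 from the leader) are broken toward fewer
    parameters; failed fits are excluded with a note.  The ranking is
    invariant to the order candidates are supplied in.
    """
    fits: list[FitResult] = []
    excluded: list[tuple[str, str]] = []
    for c in sorted(candidates, key=lambda s: s.label):
        try:
            fits.append(fit_compartment_model(datasets, c, n_starts=n_starts, seed=seed,
                                              ls_tol=ls_tol, solver_rtol=solver_rtol))
        except (FitConvergenceError, ValueError) as exc:
            excluded.append((c.label, str(exc)))
    if not fits:
        raise FitConvergenceError("no candidate could be fitted")
    fits.sort(key=lambda f: (f.aicc, f.n_params, f.label))
    best_aicc = fits[0].aicc
    leaders = [f for f in fits if f.aicc - best_aicc < 2.0]
    winner = min(leaders, key=lambda f: (f.n_params, f.aicc, f.label))
    ranked = [winner] + [f for f in fits if f is not winner]
    return SelectionResult(ranked=ranked, excluded=excluded)


def tune_effect_site(
    params: PKParameters,
    regimen: Optional[DosingRegimen] = None,
    t_target: float = 3.0,
    tol_min: float = 0.05,
    k_bracket: tuple[float, float] = (0.05, 30.0),
) -> EffectSiteParams:
    """Calibrate the linked effect-site rate constant to a peak-effect time.

    With k1e = ke0 = k the effect-site peak time decreases monotonically
    in k (a stiffer link tracks plasma faster), from arbitrarily late
    toward the plasma peak as k grows; a scalar root find places the
    simulated effect-site peak of the reference bolus (default:
    0.4 mg/kg x 75 kg over 30 s) at ``t_target`` within ``tol_min``.
    Raises ``ValueError`` if ``t_target`` precedes the plasma peak.
    """
    if regimen is None:
        regimen = DosingRegimen.per_kg_bolus(0.4, 75.0)
    horizon = max(6.0 * t_target, regimen.end_of_dosing + 5.0)

    res_cc = simulate(params, None, regimen, horizon, rtol=1e-7, atol=1e-9)
    t_cc, _ = peak(res_cc, "Cc")
    if t_target <= t_cc:
        raise ValueError(
            f"target peak time {t_target} min is not after the plasma peak "
            f"({t_cc:.2f} min); the first-order link cannot peak earlier")

    def peak_time(k: float) -> float:
        res = simulate(params, EffectSiteParams.linked(k), regimen, horizon,
                       rtol=1e-7, atol=1e-9)
        t_pk, _ = peak(res, "Ce")
        return t_pk

    lo, hi = k_bracket
    f_lo = peak_time(lo) - t_target
    while f_lo < 0 and lo > 1e-4:
        lo /= 4.0
        f_lo = peak_time(lo) - t_target
    f_hi = peak_time(hi) - t_target
    while f_hi > 0 and hi < 1e4:
        hi *= 4.0
        f_hi = peak_time(hi) - t_target
    if f_lo < 0 or f_hi > 0:
        raise ValueError("could not bracket the requested peak time")
    k = brentq(lambda kk: peak_time(kk) - t_target, lo, hi, xtol=1e-5, rtol=1e-6)
    if abs(peak_time(k) - t_target) > tol_min:
        raise ValueError("root finding did not reach the requested peak-time tolerance")
    return EffectSiteParams.linked(k)


def cv_reduction(cv_subjective: tuple[float, float],
                 cv_concentration: tuple[float, float]) -> int:
    """Percent reduction of subjective-response CV vs concentration CV.

    100 * (1 - mean(subjective) / mean(concentration)), rounded to the
    nearest integer percent; scale-invariant in its four inputs.
    """
    if any(v <= 0 for v in cv_subjective) or any(v <= 0 for v in cv_concentration):
        raise ValueError("all CVs must be strictly positive")
    ratio = (sum(cv_subjective) / len(cv_subjective)) / (
        sum(cv_concentration) / len(cv_concentration))
    return round(100.0 * (1.0 - ratio))
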