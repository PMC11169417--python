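"""Quantitative bioassay analytics for sodium-channel pharmacology.

Covers the analyses used to validate a channel blocker end to end:

* calcium-imaging responder metrics (dF/F0 with a 10% responder criterion
  and KCl viability gating),
* whole-cell patch-clamp current densities (pA/pF) and Boltzmann fits of
  voltage-dependent activation/inactivation (V1/2, slope factor k),
* concentration-response (Hill / 4-parameter logistic) IC50 estimation,
* behavioral time-course AUC (50% paw-withdrawal threshold, von Frey),
* the group statistics used alongside them (t test, one-way/two-way ANOVA,
  Sidak adjustment).

Conventions: inward currents are negative; activation curves rise with
depolarization, y = 1/(1+exp((V1/2 - V)/k)); steady-state inactivation
falls, y = 1/(1+exp((V - V1/2)/k)); k > 0 for both.  Gating parameters are
fit per cell and then averaged, not pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("scaffscreen.bioassay")

RESPONDER_THRESHOLD = 0.10     # dF/F0 increase that counts as a response
INHIBITION_CUTOFF_PCT = 50.0   # primary-screen hit threshold, % inhibition
CAPACITIVE_BLANK_MS = 1.0      # artifact blank at the start of each step

# Worked example: published group-mean peak current densities (pA/pF) of an
# oxindole-class Nav1.7 inhibitor concentration series in transfected HEK293
# cells (0 = vehicle control).  Converting to fractional inhibition relative
# to control and Hill-fitting recovers the low-micromolar IC50 reported from
# the per-cell analysis of the same experiment.
NAV17_HEK_GROUP_MEAN_DENSITIES_PA_PF = {
    0.0: -701.2, 0.1: -536.6, 1.0: -501.9, 2.0: -349.8,
    5.0: -108.7, 10.0: -80.1, 15.0: -89.3,
}

__all__ = [
    "ImagingTrace",
    "SweepProtocol",
    "SweepSet",
    "GatingFit",
    "DoseResponseFit",
    "BehaviorSeries",
    "delta_f_over_f0",
    "inhibition_rate",
    "peak_current_density",
    "boltzmann_fit",
    "conductance_transform",
    "estimate_reversal",
    "hill_fit",
    "trapezoid_auc",
    "group_stats",
    "sidak_adjust",
]


# --------------------------------------------------------------------------
# calcium imaging
# --------------------------------------------------------------------------

@dataclass
class ImagingTrace:
    """One neuron's fluorescence time course with defined epochs.

    Epochs are (start, stop) in seconds: ``baseline`` (stable F0 window),
    ``agonist`` (channel-agonist application) and ``kcl`` (depolarizing
    KCl pulse used to prove viability).  ``background`` is subtracted from
    F before anything else (scalar or per-frame).
    """

    time: np.ndarray
    F: np.ndarray
    baseline: tuple[float, float]
    agonist: tuple[float, float]
    kcl: tuple[float, float] | None = None
    background: float | np.ndarray = 0.0
    trace_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"trace {self.trace_id}: time must strictly increase")
        if not np.all(np.isfinite(self.F)):
            raise ValueError(f"trace {self.trace_id}: non-finite fluorescence")

    def _window(self, span: tuple[float, float]) -> np.ndarray:
        lo, hi = span
        mask = (self.time >= lo) & (self.time < hi)
        return np.where(mask)[0]


@dataclass(frozen=True)
class ImagingResult:
    trace_id: str
    dF_F0: float
    responder: bool
    viable: bool
    status: str  # OK | REJECTED:<reason>


def delta_f_over_f0(
    trace: ImagingTrace, threshold: float = RESPONDER_THRESHOLD
) -> ImagingResult:
    """Peak fractional fluorescence change over the agonist epoch.

    F0 is the mean of the baseline epoch after background subtraction;
    dF/F0 = (max agonist F - F0)/F0.  Responder iff dF/F0 >= threshold
    (default 10%); viable iff the KCl epoch meets the same criterion
    (no KCl epoch defined => viability cannot be established => not viable).
    A non-positive F0 or empty baseline rejects the trace with a reason.
    """
    F = trace.F - np.asarray(trace.background, dtype=float)
    base_idx = trace._window(trace.baseline)
    if base_idx.size == 0:
        return ImagingResult(trace.trace_id, np.nan, False, False, "REJECTED:empty_baseline")
    f0 = float(F[base_idx].mean())
    if f0 <= 0:
        return ImagingResult(trace.trace_id, np.nan, False, False, "REJECTED:nonpositive_F0")
    ag_idx = trace._window(trace.agonist)
    if ag_idx.size == 0:
        return ImagingResult(trace.trace_id, np.nan, False, False, "REJECTED:empty_agonist")
    dff = (float(F[ag_idx].max()) - f0) / f0
    viable = False
    if trace.kcl is not None:
        kcl_idx = trace._window(trace.kcl)
        if kcl_idx.size:
            viable = (float(F[kcl_idx].max()) - f0) / f0 >= threshold
    return ImagingResult(trace.trace_id, dff, dff >= threshold, viable, "OK")


def inhibition_rate(
    treated: list[ImagingTrace],
    control: list[ImagingTrace],
    threshold: float = RESPONDER_THRESHOLD,
    cutoff_pct: float = INHIBITION_CUTOFF_PCT,
) -> dict:
    """Treated response as % of control, plus the complementary inhibition.

    Both groups are viability-gated first (KCl criterion); group means of
    dF/F0 are compared.  Returns the exclusion accounting alongside so
    traces in = responders + non-responders + non-viable + rejected.
    """
    def summarize(traces):
        results = [delta_f_over_f0(t, threshold) for t in traces]
        ok = [r for r in results if r.status == "OK"]
        viable = [r for r in ok if r.viable]
        acct = {
            "total": len(results),
            "rejected": len(results) - len(ok),
            "non_viable": len(ok) - len(viable),
            "responders": sum(r.responder for r in viable),
            "non_responders": sum(not r.responder for r in viable),
        }
        return viable, acct

    treated_ok, treated_acct = summarize(treated)
    control_ok, control_acct = summarize(control)
    if not control_ok:
        raise ValueError("inhibition_rate: no viable control traces")
    if not treated_ok:
        raise ValueError("inhibition_rate: no viable treated traces")
    ctrl_mean = float(np.mean([r.dF_F0 for r in control_ok]))
    trt_mean = float(np.mean([r.dF_F0 for r in treated_ok]))
    pct_of_control = 100.0 * trt_mean / ctrl_mean
    return {
        "percent_of_control": pct_of_control,
        "inhibition_pct": 100.0 - pct_of_control,
        "is_hit": (100.0 - pct_of_control) > cutoff_pct,
        "treated_mean_dF_F0": trt_mean,
        "control_mean_dF_F0": ctrl_mean,
        "accounting": {"treated": treated_acct, "control": control_acct},
    }


# --------------------------------------------------------------------------
# patch clamp: I-V, gating, conductance
# --------------------------------------------------------------------------

@dataclass
class SweepProtocol:
    """Voltage-step protocol arithmetic (all mV / ms)."""

    holding_mv: float
    step_start_mv: float
    step_stop_mv: float
    step_increment_mv: float
    step_duration_ms: float

    @property
    def steps(self) -> np.ndarray:
        n = int(round((self.step_stop_mv - self.step_start_mv) / self.step_increment_mv)) + 1
        return self.step_start_mv + self.step_increment_mv * np.arange(n)


@dataclass
class SweepSet:
    """One cell's current traces, one sweep per commanded voltage step."""

    protocol: SweepProtocol
    time_ms: np.ndarray
    sweeps: dict[float, np.ndarray]  # step voltage (mV) -> current trace (pA)
    capacitance_pf: float
    cell_id: str = ""

    def __post_init__(self):
        if self.capacitance_pf <= 0:
            raise ValueError(f"cell {self.cell_id}: capacitance must be > 0 pF")


def peak_current_density(
    sweeps: SweepSet, blank_ms: float = CAPACITIVE_BLANK_MS
) -> pd.DataFrame:
    """Per-step peak current normalized to capacitance (pA/pF).

    The peak is the signed extremum (inward currents stay negative) inside
    the step epoch after a short capacitive-artifact blank.  Missing sweeps
    are flagged, not fatal.
    """
    rows = []
    t = np.asarray(sweeps.time_ms, dtype=float)
    for v in sweeps.protocol.steps:
        v = float(v)
        trace = sweeps.sweeps.get(v)
        if trace is None:
            rows.append({"voltage_mv": v, "peak_pa": np.nan,
                         "density_pa_pf": np.nan, "status": "MISSING"})
            continue
        trace = np.asarray(trace, dtype=float)
        mask = (t >= blank_ms) & (t <= sweeps.protocol.step_duration_ms)
        seg = trace[mask] if mask.any() else trace
        peak = seg[np.argmax(np.abs(seg))]  # signed extremum
        rows.append({
            "voltage_mv": v,
            "peak_pa": float(peak),
            "density_pa_pf": float(peak) / sweeps.capacitance_pf,
            "status": "OK",
        })
    return pd.DataFrame(rows)


@dataclass
class GatingFit:
    """Boltzmann gating parameters of one cell."""

    V_half: float
    k: float
    kind: str  # activation | inactivation
    converged: bool
    rmse: float


def _boltzmann(kind: str):
    if kind == "activation":
        return lambda v, vh, k: 1.0 / (1.0 + np.exp((vh - v) / k))
    if kind == "inactivation":
        return lambda v, vh, k: 1.0 / (1.0 + np.exp((v - vh) / k))
    raise ValueError(f"unknown gating kind {kind!r}")


def boltzmann_fit(
    voltages: np.ndarray, responses: np.ndarray, kind: str = "activation"
) -> GatingFit:
    """Least-squares Boltzmann fit of a normalized gating curve.

    activation: y = 1/(1+exp((V1/2 - V)/k)); inactivation mirrors the sign.
    Requires >= 5 points spanning the transition.  Non-convergence returns a
    flagged fit with parameters withheld (NaN).
    """
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(responses, dtype=float)
    if v.size < 5:
        raise ValueError("boltzmann_fit: need >=5 points")
    fun = _boltzmann(kind)
    # initial guess: V at half-max by interpolation, generic slope
    order = np.argsort(v)
    vs, ys = v[order], y[order]
    try:
        vh0 = float(np.interp(0.5, ys, vs)) if kind == "activation" else float(
            np.interp(0.5, ys[::-1], vs[::-1])
        )
    except Exception:  # noqa: BLE001
        vh0 = float(vs[len(vs) // 2])
    try:
        popt, _ = optimize.curve_fit(
            fun, v, y, p0=[vh0, 6.0],
            bounds=([v.min() - 50.0, 0.1], [v.max() + 50.0, 50.0]),
            maxfev=10000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        resid = y - fun(v, *popt)
        return GatingFit(
            V_half=float(popt[0]), k=float(popt[1]), kind=kind,
            converged=True, rmse=float(np.sqrt(np.mean(resid**2))),
        )
    except Exception as exc:  # noqa: BLE001 - flagged fit, parameters withheld
        logger.warning("boltzmann_fit (%s) failed to converge: %s", kind, exc)
        return GatingFit(V_half=np.nan, k=np.nan, kind=kind, converged=False, rmse=np.nan)


def estimate_reversal(iv: pd.DataFrame, n_tail: int = 3) -> float:
    """Reversal potential by linear extrapolation of the positive-limb I-V.

    Fits a line to the most-depolarized ``n_tail`` points and returns its
    zero-current crossing.
    """
    df = iv.dropna(subset=["density_pa_pf"]).sort_values("voltage_mv")
    tail = df.tail(n_tail)
    slope, intercept = np.polyfit(tail["voltage_mv"], tail["density_pa_pf"], 1)
    if slope == 0:
        raise ValueError("estimate_reversal: flat positive limb")
    return float(-intercept / slope)


def conductance_transform(
    iv: pd.DataFrame, v_rev: float, atol: float = 1e-9
) -> pd.DataFrame:
    """Chord conductance G(V) = I(V)/(V - Vrev), normalized to its maximum.

    The point at V = Vrev (division by zero) is dropped with a warning.
    """
    df = iv.dropna(subset=["density_pa_pf"]).copy()
    at_rev = np.isclose(df["voltage_mv"], v_rev, atol=atol)
    if at_rev.any():
        logger.warning("conductance_transform: dropping %d point(s) at V_rev", at_rev.sum())
        df = df[~at_rev]
    g = df["density_pa_pf"] / (df["voltage_mv"] - v_rev)
    gmax = g.abs().max()
    if gmax == 0:
        raise ValueError("conductance_transform: all-zero conductance")
    df["g_norm"] = (g / g.loc[g.abs().idxmax()]).astype(float)
    return df[["voltage_mv", "g_norm"]].reset_index(drop=True)


# --------------------------------------------------------------------------
# concentration-response
# --------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """4-parameter logistic (Hill) concentration-response fit."""

    IC50: float  # micromolar
    hill: float
    top: float
    bottom: float
    converged: bool
    rmse: float
    flagged_nonmonotone: bool = False


def _hill(c, ic50, hill, bottom, top):
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)


def hill_fit(
    concentrations_um: np.ndarray,
    inhibition: np.ndarray,
    fix_top: float | None = 1.0,
    fix_bottom: float | None = None,
    bottom_bounds: tuple[float, float] = (0.0, 0.5),
    monotone_tol: float = 0.15,
) -> DoseResponseFit:
    """Hill (4PL) fit of fractional inhibition vs concentration.

    By default the top plateau is fixed at 1 (complete block) and the bottom
    is free within [0, 0.5]; pass ``fix_top=None`` to free the top plateau,
    or ``fix_bottom`` to pin the bottom (e.g. 0.0 in parameter-recovery
    studies, where a free plateau truncated at its bound would bias IC50
    upward by a few percent).  Requires >= 4 concentrations with inhibition
    in [0, 1].  Data that decrease by more than ``monotone_tol`` anywhere
    flag the fit.
    """
    c = np.asarray(concentrations_um, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if c.size < 4:
        raise ValueError("hill_fit: need >=4 concentrations")
    if np.any(c <= 0):
        raise ValueError("hill_fit: concentrations must be positive")
    order = np.argsort(c)
    nonmono = bool(np.any(np.diff(y[order]) < -monotone_tol))
    ic50_0 = float(np.interp(0.5, y[order], c[order])) if y.max() > 0.5 else float(np.median(c))
    ic50_0 = min(max(ic50_0, c.min()), c.max())
    try:
        if fix_top is not None and fix_bottom is not None:
            fun = lambda cc, ic50, hill: _hill(cc, ic50, hill, fix_bottom, fix_top)  # noqa: E731
            popt, _ = optimize.curve_fit(
                fun, c, y, p0=[ic50_0, 1.0],
                bounds=([c.min() / 100, 0.1], [c.max() * 100, 10.0]),
                maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            ic50, hill, bottom, top = popt[0], popt[1], fix_bottom, fix_top
            resid = y - fun(c, *popt)
        elif fix_top is not None:
            fun = lambda cc, ic50, hill, bottom: _hill(cc, ic50, hill, bottom, fix_top)  # noqa: E731
            popt, _ = optimize.curve_fit(
                fun, c, y, p0=[ic50_0, 1.0, 0.0],
                bounds=([c.min() / 100, 0.1, bottom_bounds[0]],
                        [c.max() * 100, 10.0, bottom_bounds[1]]),
                maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            ic50, hill, bottom, top = popt[0], popt[1], popt[2], fix_top
            resid = y - fun(c, *popt)
        else:
            popt, _ = optimize.curve_fit(
                _hill, c, y, p0=[ic50_0, 1.0, 0.0, 1.0],
                bounds=([c.min() / 100, 0.1, bottom_bounds[0], 0.5],
                        [c.max() * 100, 10.0, bottom_bounds[1], 1.5]),
                maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            ic50, hill, bottom, top = popt
            resid = y - _hill(c, *popt)
        return DoseResponseFit(
            IC50=float(ic50), hill=float(hill), top=float(top), bottom=float(bottom),
            converged=True, rmse=float(np.sqrt(np.mean(resid**2))),
            flagged_nonmonotone=nonmono,
        )
    except Exception as exc:  # noqa: BLE001
        logger.warning("hill_fit failed to converge: %s", exc)
        return DoseResponseFit(
            IC50=np.nan, hill=np.nan, top=np.nan, bottom=np.nan,
            converged=False, rmse=np.nan, flagged_nonmonotone=nonmono,
        )


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass
class BehaviorSeries:
    """Paw-withdrawal thresholds over time for a group of animals."""

    time_h: np.ndarray                  # hours post-dose
    pwt_g: dict[str, np.ndarray]        # animal id -> PWT (g) per time point
    group: str = ""

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.time_h.size < 2:
            raise ValueError("BehaviorSeries: need >=2 time points for AUC")


def trapezoid_auc(series: BehaviorSeries) -> dict:
    """Trapezoidal AUC of PWT over the measurement window, per animal.

    Time points are sorted before integration.  Returns per-animal AUCs
    (g*h) plus the group mean +/- SEM.
    """
    order = np.argsort(series.time_h)
    t = series.time_h[order]
    aucs = {}
    for animal, pwt in series.pwt_g.items():
        pwt = np.asarray(pwt, dtype=float)
        if pwt.size != t.size:
            raise ValueError(f"animal {animal}: PWT length != time length")
        aucs[animal] = float(np.trapezoid(pwt[order], t))
    values = np.array(list(aucs.values()))
    return {
        "per_animal": aucs,
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else np.nan,
        "n": len(values),
    }


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment: p_adj = 1 - (1 - p)^m."""
    return float(1.0 - (1.0 - p) ** m)


def group_stats(groups: dict[str, np.ndarray], design: str = "t") -> dict:
    """The comparison battery used across the assays.

    design = "t": two-tailed unpaired Student's t test (exactly 2 groups);
    design = "anova": one-way ANOVA over all groups plus Sidak-adjusted
    pairwise t tests against the first (control) group.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("group_stats: need >=2 groups with >=2 observations each")
    if all(a.std(ddof=1) == 0 for a in arrays.values()):
        raise ValueError("group_stats: zero within-group variance in all groups")
    names = list(arrays)
    if design == "t":
        if len(arrays) != 2:
            raise ValueError("t design needs exactly 2 groups")
        a, b = arrays[names[0]], arrays[names[1]]
        res = stats.ttest_ind(a, b)
        return {"test": "t", "statistic": float(res.statistic),
                "df": float(a.size + b.size - 2), "p": float(res.pvalue)}
    if design == "anova":
        f, p = stats.f_oneway(*arrays.values())
        control = names[0]
        m = len(names) - 1
        pairwise = {}
        for other in names[1:]:
            res = stats.ttest_ind(arrays[control], arrays[other])
            pairwise[other] = {
                "p_raw": float(res.pvalue),
                "p_sidak": sidak_adjust(float(res.pvalue), m),
            }
        return {"test": "anova", "statistic": float(f), "p": float(p),
                "df_between": len(names) - 1,
                "df_within": sum(a.size for a in arrays.values()) - len(names),
                "pairwise_vs_control": pairwise}
    raise ValueError(f"unknown design {design!r}")


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA (type II) for e.g. treatment x time behavioral designs."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
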