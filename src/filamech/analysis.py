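"""Derived quantities of force-strain cycles.

Implements the full cycle-analysis chain used on both measured-style and
simulated traces: reference length at 5 pN, strain, the 100-150 pN window
fit giving stiffness kappa_f and effective length eps_e (x-intercept),
strain-window stiffness kappa_eps (optionally on the corrected strain
eps_c = eps - eps_e), hysteresis energies, per-cycle elongation increments
Delta eps_e, cross-filament regressions and cohort order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .core import Branch, ForceExtensionRecord, KBT_ROOM
from .protocols import ProtocolError, first_upward_crossing


class AnalysisError(RuntimeError):
    """A derived quantity's precondition failed for the whole filament."""


# ---------------------------------------------------------------------------
# strain and curves
# ---------------------------------------------------------------------------

def reference_length(record: ForceExtensionRecord, F_ref: float = 5.0,
                     smooth_frac: float = 0.02) -> float:
    """Original filament length L0: distance at the first 5 pN crossing.

    Defined on the first-cycle stretch branch; the same L0 normalises all
    cycles of that filament.  Interpolates linearly between samples.  The
    crossing is detected on a locally line-fitted force (Savitzky-Golay,
    order 1, window = ``smooth_frac`` of the trace so its physical width
    does not depend on the sampling density): the reference force is of
    the same order as typical trap noise, and a raw first crossing would
    fire on the first upward noise excursion.  The filter reproduces
    linear traces exactly, edges included.
    """
    F = record.F
    size = int(round(F.size * smooth_frac)) | 1  # odd window
    if size > 2 and F.size > size:
        F = savgol_filter(F, size, polyorder=1, mode="interp")
    # pretension check: the smoothed force must start below the reference
    # somewhere in the initial segment (a single noisy sample, or a fast
    # elastic rise crossing early, is not pretension)
    n0 = max(5, F.size // 20)
    if np.min(F[:n0]) >= F_ref:
        raise AnalysisError(
            f"trace starts at or above {F_ref} pN (pre-tension too high)")
    start = int(np.argmax(F < F_ref)) if F[0] >= F_ref else 0
    try:
        return first_upward_crossing(record.d[start:], F[start:], F_ref)
    except ProtocolError as exc:
        raise AnalysisError(str(exc)) from exc


@dataclass
class ForceStrainCurve:
    """A branch expressed in strain units: eps = (L - L0)/L0."""

    eps: np.ndarray
    F: np.ndarray
    L0: float
    branch: Branch
    cycle_index: int

    @classmethod
    def from_record(cls, record: ForceExtensionRecord, L0: float):
        if L0 <= 0:
            raise AnalysisError("L0 must be positive")
        eps = (record.d - L0) / L0
        return cls(eps, record.F, L0, record.branch, record.cycle_index)


@dataclass
class CycleMetrics:
    """Per-cycle derived quantities (NaN marks a failed fit precondition)."""

    cycle: int
    eps_max: float = np.nan
    eps_e: float = np.nan
    kappa_f: float = np.nan          # pN per unit strain, 100-150 pN window
    kappa_eps: float = np.nan        # pN per unit strain, fixed strain window
    kappa_eps_corrected: float = np.nan
    E_in: float = np.nan             # pN nm
    E_dis: float = np.nan            # pN nm
    E_rel: float = np.nan
    E_abs_per_len: float = np.nan    # kBT per micrometre
    delta_eps_e: float = np.nan


# ---------------------------------------------------------------------------
# window fits
# ---------------------------------------------------------------------------

def fit_force_window(curve: ForceStrainCurve, F_lo: float = 100.0,
                     F_hi: float = 150.0, min_samples: int = 5,
                     smooth: int = 11):
    """Linear fit to the elastic regime selected by a force window.

    Least squares on samples with F in [F_lo, F_hi]; the slope is the
    stretching stiffness kappa_f (pN per unit strain) and the x-intercept
    is the effective length eps_e in strain units.  Returns (NaN, NaN) if
    the window holds fewer than ``min_samples`` points.

    Window membership is decided on a lightly smoothed force (running mean
    over ``smooth`` samples): selecting on the raw noisy force would keep
    preferentially down-fluctuated points near the upper edge and
    up-fluctuated ones near the lower edge, attenuating the fitted slope
    (regression to the mean).  The regression itself uses the raw samples.
    On noiseless data the smoothing is inert and the fit is exact.
    """
    F_sel = curve.F
    if smooth > 1 and curve.F.size >= smooth:
        F_sel = uniform_filter1d(curve.F, size=smooth, mode="nearest")
    m = (F_sel >= F_lo) & (F_sel <= F_hi)
    if m.sum() < min_samples:
        return np.nan, np.nan
    slope, intercept = np.polyfit(curve.eps[m], curve.F[m], 1)
    if slope == 0:
        return np.nan, np.nan
    return float(slope), float(-intercept / slope)


def fit_strain_window(curve: ForceStrainCurve, eps_lo: float = 0.1,
                      eps_hi: float = 0.3, corrected: bool = False,
                      eps_e: float = 0.0, min_samples: int = 2) -> float:
    """Stiffness kappa_eps from a linear fit over a fixed strain window.

    With ``corrected`` the window is applied to the corrected strain
    eps_c = eps - eps_e, re-zeroing the axis by the accumulated plastic
    elongation.  Returns NaN when the window is underpopulated.
    """
    x = curve.eps - (eps_e if corrected else 0.0)
    m = (x >= eps_lo) & (x <= eps_hi)
    if m.sum() < min_samples:
        return np.nan
    return float(np.polyfit(x[m], curve.F[m], 1)[0])


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

@dataclass
class HysteresisEnergies:
    E_in: float
    E_dis: float
    E_rel: float
    E_abs_per_len: float   # kBT per micrometre


def _branch_area(d: np.ndarray, F: np.ndarray, lo: float, hi: float) -> float:
    """Integral of F dd over [lo, hi] with interpolated end points."""
    order = np.argsort(d, kind="stable")
    d, F = d[order], F[order]
    m = (d >= lo) & (d <= hi)
    dd = d[m]
    FF = F[m]
    if dd.size == 0 or dd[0] > lo:
        dd = np.concatenate(([lo], dd))
        FF = np.concatenate(([np.interp(lo, d, F)], FF))
    if dd[-1] < hi:
        dd = np.concatenate((dd, [hi]))
        FF = np.concatenate((FF, [np.interp(hi, d, F)]))
    return float(np.trapezoid(FF, dd))


def hysteresis_energy(stretch: ForceExtensionRecord,
                      relax: ForceExtensionRecord, L0: float,
                      kBT: float = KBT_ROOM) -> HysteresisEnergies:
    """Input, dissipated, relative and per-length dissipated energy of a cycle.

    Both branches are integrated with the trapezoid rule over their common
    distance support (non-overlapping tails excluded).  The absolute
    dissipated energy is reported per initial filament length, in kBT/um.
    """
    lo = max(stretch.d.min(), relax.d.min())
    hi = min(stretch.d.max(), relax.d.max())
    if hi <= lo:
        raise AnalysisError("branches share no common distance support")
    E_in = _branch_area(stretch.d, stretch.F, lo, hi)
    E_ret = _branch_area(relax.d, relax.F, lo, hi)
    E_dis = E_in - E_ret
    E_rel = E_dis / E_in if E_in > 0 else np.nan
    E_abs = E_dis / (kBT * (L0 / 1000.0))
    return HysteresisEnergies(E_in, E_dis, E_rel, E_abs)


# ---------------------------------------------------------------------------
# cohort-level statistics
# ---------------------------------------------------------------------------

def elongation_vs_maxstrain(metrics: pd.DataFrame, eps_threshold: float = 0.4,
                            min_points: int = 5):
    """Least-squares line of eps_e against eps_max above a strain threshold.

    Pools cycles (typically the 4th to 15th) across filaments; only points
    with eps_max > ``eps_threshold`` enter the fit.  Returns
    (slope, intercept), or (NaN, NaN) with too few points.
    """
    df = metrics.dropna(subset=["eps_max", "eps_e"])
    df = df[df["eps_max"] > eps_threshold]
    if len(df) < min_points:
        return np.nan, np.nan
    slope, intercept = np.polyfit(df["eps_max"], df["eps_e"], 1)
    return float(slope), float(intercept)


def cohort_summary(metrics: pd.DataFrame, column: str,
                   by: str = "cycle") -> pd.DataFrame:
    """Median and quartiles of a per-cycle metric across filaments.

    Percentiles use linear interpolation between order statistics.
    """
    def q(series, p):
        v = series.dropna().to_numpy()
        return np.percentile(v, p, method="linear") if v.size else np.nan

    g = metrics.groupby(by)[column]
    return pd.DataFrame({
        "median": g.apply(lambda s: q(s, 50)),
        "q25": g.apply(lambda s: q(s, 25)),
        "q75": g.apply(lambda s: q(s, 75)),
    })


def fd_binwidth(values) -> float:
    """Histogram bin width by the Freedman-Diaconis rule: 2 IQR n^(-1/3).

    Falls back to range/sqrt(n) (with a warning) when the IQR vanishes.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise AnalysisError("need at least two values")
    iqr = np.percentile(v, 75, method="linear") - np.percentile(v, 25,
                                                               method="linear")
    if iqr <= 0:
        warnings.warn("zero IQR: falling back to range/sqrt(n) bin width")
        return float((v.max() - v.min()) / np.sqrt(n))
    return float(2.0 * iqr * n ** (-1.0 / 3.0))


def dissipation_vs_delta_eps(metrics: pd.DataFrame):
    """Per-cycle pairs (Delta eps_e, E_rel) and their Spearman correlation.

    A positive association is the signature of dissipation by subunit
    sliding (elongation tracks dissipated energy); its absence is the
    unfolding signature.
    """
    df = metrics.dropna(subset=["delta_eps_e", "E_rel"])
    pairs = df[["delta_eps_e", "E_rel"]].reset_index(drop=True)
    if len(pairs) >= 2 and pairs["delta_eps_e"].nunique() > 1:
        rho = float(stats.spearmanr(pairs["delta_eps_e"], pairs["E_rel"])[0])
    else:
        rho = np.nan
    return pairs, rho


# ---------------------------------------------------------------------------
# per-filament pipeline
# ---------------------------------------------------------------------------

def analyze_filament(records, F_ref: float = 5.0, F_lo: float = 100.0,
                     F_hi: float = 150.0, eps_lo: float = 0.1,
                     eps_hi: float = 0.3, kBT: float = KBT_ROOM,
                     fit_branch: Branch = Branch.STRETCH) -> pd.DataFrame:
    """Full per-cycle metrics table for one filament's records.

    L0 comes from the first-cycle stretch at ``F_ref``; window fits use the
    stretch branch (the loading curve) by default.  A cycle whose fit
    precondition fails yields NaN metrics rather than aborting.
    """
    stretches = {r.cycle_index: r for r in records if r.branch is Branch.STRETCH}
    relaxes = {r.cycle_index: r for r in records if r.branch is Branch.RELAX}
    if 1 not in stretches:
        raise AnalysisError("no first-cycle stretch branch")
    L0 = reference_length(stretches[1], F_ref)

    rows = []
    prev_eps_e = np.nan
    for cycle in sorted(stretches):
        rec = stretches[cycle] if fit_branch is Branch.STRETCH else \
            relaxes.get(cycle, stretches[cycle])
        curve = ForceStrainCurve.from_record(rec, L0)
        met = CycleMetrics(cycle=cycle)
        met.eps_max = float((stretches[cycle].d.max() - L0) / L0)
        met.kappa_f, met.eps_e = fit_force_window(curve, F_lo, F_hi)
        met.kappa_eps = fit_strain_window(curve, eps_lo, eps_hi)
        if np.isfinite(met.eps_e):
            met.kappa_eps_corrected = fit_strain_window(
                curve, eps_lo, eps_hi, corrected=True, eps_e=met.eps_e)
            met.delta_eps_e = met.eps_e - prev_eps_e if np.isfinite(prev_eps_e) \
                else np.nan
            prev_eps_e = met.eps_e
        if cycle in relaxes:
            try:
                en = hysteresis_energy(stretches[cycle], relaxes[cycle], L0, kBT)
                met.E_in, met.E_dis = en.E_in, en.E_dis
                met.E_rel, met.E_abs_per_len = en.E_rel, en.E_abs_per_len
            except AnalysisError:
                pass
        rows.append(vars(met))
    df = pd.DataFrame(rows)
    df.attrs["L0"] = L0
    return df


def analyze_cohort(record_lists, **kwargs) -> pd.DataFrame:
    """Per-cycle metrics for a list of filaments, tagged by filament id."""
    frames = []
    for fid, records in enumerate(record_lists):
        df = analyze_filament(records, **kwargs)
        df.insert(0, "filament", fid)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
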