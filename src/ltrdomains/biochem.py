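"""Quantitative analytics for the biochemical validation experiments.

EMSA fraction-bound and Hill-transformation Kd estimation (unweighted OLS of
log10(theta/(1-theta)) on log10(concentration): the slope is the Hill
coefficient and the x-intercept gives Kd), chromatogram peak integration,
m6A/A ratio, and percent demethylation relative to a no-protein control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import BindingSeries, Chromatogram

THETA_CLAMP = 0.999


@dataclass
class KdEstimate:
    kd: float  # μM
    hill_n: float
    r_squared: float
    slope: float
    intercept: float
    n_lanes_used: int
    excluded_lanes: tuple[int, ...] = ()


@dataclass
class DemethylationResult:
    ratio_sample: float
    ratio_control: float
    percent: float
    replicate_mean: float | None = None
    replicate_sd: float | None = None


def mass_to_molar(mass_ng: float, volume_ul: float, mw_kda: float) -> float:
    """Concentration in μM from mass (ng) in a volume (μL) of protein of mw (kDa).

    Unit algebra: ng / (kDa · μL) = μM.
    """
    if mass_ng <= 0 or volume_ul <= 0 or mw_kda <= 0:
        raise ValueError("mass, volume and molecular weight must be positive")
    return mass_ng / (mw_kda * volume_ul)


def molar_to_mass(conc_um: float, volume_ul: float, mw_kda: float) -> float:
    """Inverse of :func:`mass_to_molar`."""
    if conc_um <= 0 or volume_ul <= 0 or mw_kda <= 0:
        raise ValueError("inputs must be positive")
    return conc_um * mw_kda * volume_ul


def fraction_bound(series: BindingSeries) -> np.ndarray:
    """θ = 1 − free/total per lane, clamped to [0, 1)."""
    if series.total_signal <= 0:
        raise ValueError("total signal must be positive")
    free = np.asarray(series.free_signal, dtype=float)
    theta = 1.0 - free / series.total_signal
    return np.clip(theta, 0.0, THETA_CLAMP)


def hill_fit(theta: np.ndarray, concentrations: np.ndarray) -> KdEstimate:
    """Hill-transformation Kd: OLS of log10(θ/(1−θ)) on log10(c).

    Lanes with θ outside (0, ``THETA_CLAMP``) — unbound or saturated beyond
    the logit's usable range — or with non-positive concentration are excluded
    from the regression and reported, never silently dropped.
    """
    theta = np.asarray(theta, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if theta.shape != conc.shape:
        raise ValueError("theta and concentrations must have the same shape")
    usable = (theta > 0.0) & (theta < THETA_CLAMP) & (conc > 0.0)
    excluded = tuple(int(i) for i in np.nonzero(~usable)[0])
    if excluded:
        warnings.warn(f"excluding lanes without usable fraction bound: {excluded}")
    if usable.sum() < 3:
        raise ValueError("need at least 3 usable lanes with theta in (0,1)")
    x = np.log10(conc[usable])
    y = np.log10(theta[usable] / (1.0 - theta[usable]))
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError("non-binding data: Hill slope is not positive")
    kd = 10.0 ** (-fit.intercept / fit.slope)
    return KdEstimate(
        kd=float(kd),
        hill_n=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_lanes_used=int(usable.sum()),
        excluded_lanes=excluded,
    )


def estimate_kd(series: BindingSeries) -> KdEstimate:
    """Convenience: fraction bound then Hill fit on a lane table."""
    theta = fraction_bound(series)
    return hill_fit(theta, np.asarray(series.concentrations))


def integrate_peaks(
    chromatogram: Chromatogram,
    windows: dict[str, tuple[float, float]],
    use_trace: bool = True,
) -> dict[str, float]:
    """Peak areas per label from retention-time windows.

    Trace input: trapezoidal integration of baseline-subtracted intensity in
    each window (baseline = median of the out-of-window trace).  Peak-list
    input (``use_trace=False``): sum of areas whose centers fall in the window.
    """
    spans = sorted(windows.values())
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValueError("windows must be non-overlapping")
    areas: dict[str, float] = {}
    if use_trace and chromatogram.rt:
        rt = np.asarray(chromatogram.rt)
        inten = np.asarray(chromatogram.intensity)
        out_of_window = np.ones_like(rt, dtype=bool)
        for lo, hi in windows.values():
            out_of_window &= ~((rt >= lo) & (rt <= hi))
        baseline = float(np.median(inten[out_of_window])) if out_of_window.any() else 0.0
        for label, (lo, hi) in windows.items():
            sel = (rt >= lo) & (rt <= hi)
            if not sel.any():
                warnings.warn(f"empty window for {label}")
                areas[label] = 0.0
                continue
            areas[label] = float(np.trapezoid(np.clip(inten[sel] - baseline, 0, None), rt[sel]))
    else:
        for label, (lo, hi) in windows.items():
            total = sum(a for _, center, a in chromatogram.peaks if lo <= center <= hi)
            if total == 0.0:
                warnings.warn(f"empty window for {label}")
            areas[label] = float(total)
    return areas


def m6a_ratio(areas: dict[str, float]) -> float:
    """m6A/A nucleoside peak-area ratio."""
    a = areas.get("A", 0.0)
    if a <= 0:
        raise ValueError("adenosine peak area must be positive")
    return areas.get("m6A", 0.0) / a


def demethylation_percent(ratio_sample: float, ratio_control: float) -> float:
    """Percent demethylation of the sample vs the no-protein control."""
    if ratio_control <= 0:
        raise ValueError("control ratio must be positive")
    if ratio_sample < 0:
        raise ValueError("ratios must be non-negative")
    return 100.0 * (1.0 - ratio_sample / ratio_control)


def demethylation_result(
    sample_ratios: list[float],
    control_ratios: list[float],
) -> DemethylationResult:
    """Replicate-aware demethylation summary (means, then percent of means)."""
    if not sample_ratios or not control_ratios:
        raise ValueError("need at least one replicate per condition")
    rs = float(np.mean(sample_ratios))
    rc = float(np.mean(control_ratios))
    percents = None
    sd = None
    if len(sample_ratios) == len(control_ratios) and len(sample_ratios) > 1:
        per = [demethylation_percent(s, c) for s, c in zip(sample_ratios, control_ratios)]
        percents = float(np.mean(per))
        sd = float(np.std(per, ddof=1))
    return DemethylationResult(
        ratio_sample=rs,
        ratio_control=rc,
        percent=demethylation_percent(rs, rc),
        replicate_mean=percents,
        replicate_sd=sd,
    )


DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "G": (2.9, 3.5),
    "A": (4.2, 4.8),
    "m6A": (5.7, 6.3),
}
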