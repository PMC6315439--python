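"""Validation arithmetic: densitometry, OD calibration and Pfaffl qPCR.

These are the numeric counterparts of the bench assays used to verify a
candidate protein: western-blot band densities normalized to a total-protein
loading control and compared across groups with a normality-gated test;
immunohistochemistry grey values converted to optical density through a
step-tablet calibration curve with background subtraction; and relative
transcript quantification by the Pfaffl efficiency-corrected ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

#: Combined sample size up to which the Mann–Whitney U null is enumerated exactly.
EXACT_MWU_MAX_N = 20


@dataclass
class QuantSample:
    """Grouped positive measurements (densities, OD units, Ct cycles)."""

    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("QuantSample needs at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values <= 0):
            raise ValueError("measurements must be positive")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class CalibrationCurve:
    """Step-tablet calibration: grey value -> optical density.

    Points are stored sorted by grey value; conversion is piecewise-linear
    through the points and clamped to the end ODs outside the calibrated
    range. ``background_od`` is subtracted from every converted value.
    """

    points: list[tuple[float, float]]
    background_od: float = 0.0

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("calibration needs at least 2 points")
        greys = [g for g, _ in self.points]
        diffs = np.diff(greys)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("grey values must be strictly monotone")
        self.points = sorted((float(g), float(od)) for g, od in self.points)


def normalize_band(band_density: float, loading_density: float) -> float:
    """Band density divided by its lane's loading-control (total protein) density."""
    if loading_density <= 0:
        raise ValueError(f"loading-control density must be > 0, got {loading_density}")
    return float(band_density) / float(loading_density)


def percent_change(disease: QuantSample, control: QuantSample) -> float:
    """100 x (mean(disease)/mean(control) - 1); sign encodes direction."""
    if control.mean == 0:
        raise ValueError("control mean is zero")
    return 100.0 * (disease.mean / control.mean - 1.0)


def _shapiro_normal(values: np.ndarray, alpha: float) -> bool:
    # Shapiro-Wilk is undefined for (near-)constant input; a degenerate
    # sample is treated as non-normal so the nonparametric branch is taken.
    if np.ptp(values) == 0:
        return False
    return stats.shapiro(values).pvalue > alpha


def compare_groups(
    a: QuantSample,
    b: QuantSample,
    normality_alpha: float = 0.05,
) -> tuple[str, float]:
    """Normality-gated two-group comparison.

    Both groups pass Shapiro–Wilk at ``normality_alpha`` -> two-tailed
    independent (Student) t-test; otherwise two-tailed Mann–Whitney U,
    exact for combined n <= 20. Groups below n = 3 skip the gate and go
    straight to the nonparametric branch.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    gate_possible = len(a) >= 3 and len(b) >= 3
    normal = (
        gate_possible
        and _shapiro_normal(a.values, normality_alpha)
        and _shapiro_normal(b.values, normality_alpha)
    )
    if normal:
        res = stats.ttest_ind(a.values, b.values, equal_var=True, alternative="two-sided")
        return "t-test", float(res.pvalue)
    total = len(a) + len(b)
    method = "exact" if total <= EXACT_MWU_MAX_N else "asymptotic"
    has_ties = len(np.unique(np.concatenate([a.values, b.values]))) < total
    if method == "exact" and has_ties:
        method = "asymptotic"  # exact null assumes no ties
    res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided", method=method)
    return "mann-whitney-u", float(res.pvalue)


def calibrate_od(
    tablet: Sequence[tuple[float, float]],
    background_od: float = 0.0,
) -> CalibrationCurve:
    """Build a calibration curve from (mean grey value, standard OD) steps."""
    return CalibrationCurve(points=list(tablet), background_od=float(background_od))


def apply_calibration(grey, curve: CalibrationCurve):
    """Convert grey value(s) to background-corrected OD.

    Piecewise-linear through the calibration points, clamped to the end ODs
    outside the calibrated grey range. Values may come out negative after
    background subtraction; they are reported as-is (a warning is emitted)
    so group statistics remain unbiased.
    """
    greys = np.array([g for g, _ in curve.points])
    ods = np.array([od for _, od in curve.points])
    out = np.interp(np.asarray(grey, dtype=float), greys, ods) - curve.background_od
    if np.any(np.asarray(out) < 0):
        warnings.warn("background-corrected OD is negative", stacklevel=2)
    if np.isscalar(grey) or np.ndim(grey) == 0:
        return float(out)
    return out


@dataclass
class PfafflInput:
    """Inputs of the Pfaffl efficiency-corrected expression ratio.

    Efficiencies lie in (1, 2] (2 = perfect doubling per cycle); each
    delta-Ct is mean Ct(control) - mean Ct(sample) in cycles.
    """

    E_target: float
    E_ref: float
    dCt_target: float
    dCt_ref: float

    def __post_init__(self) -> None:
        for label, e in (("E_target", self.E_target), ("E_ref", self.E_ref)):
            if not (1.0 < e <= 2.0):
                raise ValueError(f"{label} must lie in (1, 2], got {e}")
        for label, d in (("dCt_target", self.dCt_target), ("dCt_ref", self.dCt_ref)):
            if not math.isfinite(d):
                raise ValueError(f"{label} must be finite")


def pfaffl_ratio(inputs: PfafflInput) -> float:
    """Relative expression ratio E_target^dCt_target / E_ref^dCt_ref."""
    return inputs.E_target ** inputs.dCt_target / inputs.E_ref ** inputs.dCt_ref


def estimate_efficiency(fluorescence_by_cycle: Sequence[float]) -> float:
    """Amplification efficiency from exponential-phase fluorescence.

    Fits log10(fluorescence) against cycle number over every 4-point
    window, keeps the window with the highest R^2 (earliest on ties), and
    returns E = 10^slope. E > 2 is clipped to 2 with a warning (overshoot
    from noise); E <= 1 means no detectable amplification and raises.
    This is a simplified window fit, not the full window-of-linearity
    search of dedicated qPCR software.
    """
    values = np.asarray(fluorescence_by_cycle, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 cycles of fluorescence")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("fluorescence values must be positive and finite")
    logs = np.log10(values)
    cycles = np.arange(values.size, dtype=float)
    best_slope, best_r2 = None, -np.inf
    for start in range(values.size - 3):
        window = slice(start, start + 4)
        res = stats.linregress(cycles[window], logs[window])
        r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 0.0
        if r2 > best_r2 + 1e-12:
            best_r2, best_slope = r2, res.slope
    efficiency = float(10.0 ** best_slope)
    if 2.0 < efficiency <= 2.0 + 1e-9:
        return 2.0  # float round-off on a perfect doubling series
    if efficiency > 2.0:
        warnings.warn(f"estimated efficiency {efficiency:.3f} > 2; clipped to 2", stacklevel=2)
        return 2.0
    if efficiency <= 1.0:
        raise ValueError(f"estimated efficiency {efficiency:.3f} <= 1: no amplification")
    return efficiency
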