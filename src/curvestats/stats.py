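"""Summary statistics of mapped constant-curvature contours.

Aggregates the mapper's output into the quantities of interest: how often
contours of each curvature class occur, how the orientations of their end
elements are distributed (per curvature class and length bin), Gaussian
fits to those distributions, and trend fits — an exponential growth curve
M = S exp(K X) for the distribution peak versus curvature angle X, and
ordinary linear regressions for amplitude/width versus contour length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import linregress

from .mapping import CURVATURE_CLASSES, LENGTH_BINS
from .psychometrics import GaussianTuningFitter, TuningFit

__all__ = [
    "OrientationDistribution",
    "TrendFit",
    "occurrence_by_curvature",
    "end_orientation_distribution",
    "fit_distribution_gaussian",
    "fit_peak_trend",
    "fit_linear_trend",
]

ORIENTATION_BIN_DEG = 10.0


@dataclass
class OrientationDistribution:
    """Normalised end-element orientation histogram for one slice."""

    curvature_class_deg: float
    length_bin: str | None
    bin_centers_deg: np.ndarray
    normalized_frequency: np.ndarray
    n_records: int = 0
    n_class_records: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "curvature_class_deg": self.curvature_class_deg,
            "length_bin": self.length_bin or "all",
            "orientation_rel_deg": self.bin_centers_deg,
            "normalized_frequency": self.normalized_frequency,
        })


@dataclass(frozen=True)
class TrendFit:
    """Linear or exponential trend summary."""

    model: str                      # "linear" | "exponential"
    parameters: dict = field(default_factory=dict)
    r2: float = np.nan
    converged: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def occurrence_by_curvature(contours: pd.DataFrame) -> pd.Series:
    """Number of mapped contours per curvature class 0-40 deg."""
    counts = pd.Series(0, index=list(CURVATURE_CLASSES), name="n_contours")
    counts.index.name = "curvature_class_deg"
    if len(contours) == 0:
        return counts
    got = contours["curvature_class_deg"].dropna().astype(int).value_counts()
    for cls, n in got.items():
        if cls in counts.index:
            counts.loc[cls] += int(n)
    return counts


def _orientation_bins() -> tuple[np.ndarray, np.ndarray]:
    centers = np.arange(-90.0, 90.0 + ORIENTATION_BIN_DEG, ORIENTATION_BIN_DEG)
    edges = np.concatenate([centers - ORIENTATION_BIN_DEG / 2,
                            [centers[-1] + ORIENTATION_BIN_DEG / 2]])
    return centers, edges


def end_orientation_distribution(
    ends: pd.DataFrame,
    contours: pd.DataFrame,
    curvature_class_deg: float,
    length_bin: str | None = None,
) -> OrientationDistribution:
    """Histogram of end-element orientations, 10-deg bins over (-90, 90).

    Frequencies are normalised by the total number of end records of the
    whole curvature class, so across all length bins of one class the
    frequencies sum to 1 and slices of different classes are comparable
    regardless of how often their contours occur.
    """
    centers, edges = _orientation_bins()
    if len(ends) == 0 or len(contours) == 0:
        return OrientationDistribution(curvature_class_deg, length_bin,
                                       centers, np.zeros_like(centers))
    merged = ends.merge(
        contours[["contour_id", "curvature_class_deg", "length_bin"]],
        on="contour_id", how="left")
    in_class = merged[merged["curvature_class_deg"] == curvature_class_deg]
    total = len(in_class)
    sub = in_class if length_bin is None else in_class[in_class["length_bin"] == length_bin]
    hist, _ = np.histogram(sub["orientation_rel_deg"].to_numpy(float), bins=edges)
    freq = hist / total if total > 0 else hist.astype(float)
    return OrientationDistribution(curvature_class_deg, length_bin, centers,
                                   freq, n_records=len(sub), n_class_records=total)


def fit_distribution_gaussian(dist: OrientationDistribution, **kw) -> TuningFit:
    """Gaussian fit (A, M, SD, R^2) to a normalised orientation histogram.

    Uses the same fitter as the behavioural tuning curves, with chance
    level 0 (these are frequencies, not proportions correct). Requires at
    least 4 non-empty bins; flat or non-converged fits come back flagged.
    """
    nonzero = np.count_nonzero(dist.normalized_frequency)
    if nonzero < 4:
        raise ValueError(f"need >= 4 non-empty bins, got {nonzero}")
    est = GaussianTuningFitter(chance=0.0, **kw)
    est.fit(dist.bin_centers_deg, dist.normalized_frequency)
    return est.result_()


def _exp_growth(x, S, K):
    return S * np.exp(K * x)


def fit_peak_trend(peaks: pd.DataFrame | list[tuple[float, float]]) -> TrendFit:
    """Exponential growth fit M = S exp(K X) of peak orientation vs curvature.

    ``peaks`` is a DataFrame with columns (curvature_class_deg, M) or a
    list of (X, M) pairs; at least 3 points are required.
    """
    if isinstance(peaks, pd.DataFrame):
        xv = peaks["curvature_class_deg"].to_numpy(float)
        yv = peaks["M"].to_numpy(float)
    else:
        arr = np.asarray(peaks, dtype=float)
        xv, yv = arr[:, 0], arr[:, 1]
    if len(xv) < 3:
        raise ValueError("need at least 3 (curvature, peak) points")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_exp_growth, xv, yv,
                                p0=(max(yv[np.argmin(xv)], 1.0), 0.05),
                                maxfev=20_000)
    except RuntimeError:
        return TrendFit(model="exponential", parameters={}, r2=np.nan, converged=False)
    resid = yv - _exp_growth(xv, *popt)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return TrendFit(model="exponential",
                    parameters={"S": float(popt[0]), "K": float(popt[1])}, r2=r2)


def fit_linear_trend(x, y) -> TrendFit:
    """Ordinary least-squares line, for amplitude/width-vs-length summaries."""
    res = linregress(np.asarray(x, float), np.asarray(y, float))
    return TrendFit(model="linear",
                    parameters={"slope": float(res.slope),
                                "intercept": float(res.intercept)},
                    r2=float(res.rvalue**2))


def summarize_corpus(contours: pd.DataFrame, ends: pd.DataFrame,
                     min_bins: int = 4) -> dict:
    """Full statistics block for one corpus of mapped contours.

    Returns occurrence counts, per-class distributions (pooled over length
    bins), their Gaussian fits where enough bins are occupied, and the
    peak-vs-curvature exponential trend over the classes with usable fits.
    """
    counts = occurrence_by_curvature(contours)
    dists, fits, peaks = {}, {}, {}
    for cls in CURVATURE_CLASSES:
        dist = end_orientation_distribution(ends, contours, float(cls))
        dists[cls] = dist
        if np.count_nonzero(dist.normalized_frequency) >= min_bins:
            fits[cls] = fit_distribution_gaussian(dist)
        # distribution peak: the fitted mean when a clean fit exists,
        # otherwise the mode bin of the histogram
        if cls in fits and not fits[cls].degenerate:
            peaks[cls] = float(fits[cls].M)
        elif dist.normalized_frequency.sum() > 0:
            peaks[cls] = float(dist.bin_centers_deg[np.argmax(dist.normalized_frequency)])
    peak_df = pd.DataFrame(
        [{"curvature_class_deg": cls, "M": m} for cls, m in peaks.items()])
    trend = fit_peak_trend(peak_df) if len(peak_df) >= 3 else None
    return {"counts": counts, "distributions": dists, "fits": fits,
            "peaks": peaks, "trend": trend}
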