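"""Gaussian tuning fits to detection performance.

Detection data from a two-interval forced-choice task arrive as counts of
correct responses per (contour angle, end-element direction) condition.
Per contour angle, proportion correct as a function of end-element
direction X is summarised by a Gaussian tuning curve

    Y = A * exp(-0.5 * (X - M)^2 / SD^2)

whose amplitude A is the peak proportion correct, mean M the end direction
of best detection, and SD the tuning width. Fits are unconstrained
least squares with multi-start initialisation; flat or near-chance data
are flagged as degenerate rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TuningFit",
    "GaussianTuningFitter",
    "logit_transform",
    "fit_gaussian_tuning",
    "simulate_observer",
]


@dataclass(frozen=True)
class TuningFit:
    """Summary of one Gaussian tuning fit."""

    A: float
    M: float
    SD: float
    r2: float
    degenerate: bool = False
    converged: bool = True

    def predict(self, x) -> np.ndarray:
        return gaussian_tuning(np.asarray(x, dtype=float), self.A, self.M, self.SD)

    def to_dict(self) -> dict:
        return asdict(self)


def gaussian_tuning(x, A, M, SD):
    return A * np.exp(-0.5 * (x - M) ** 2 / SD**2)


def logit_transform(p: float, n: int) -> float:
    """Logit of a proportion with the conventional 1/(2n) clamp.

    Proportions of 0 or 1 from ``n`` trials are pulled to 1/(2n) and
    1 - 1/(2n) so the transform stays finite.
    """
    if n <= 0:
        raise ValueError(f"n must be a positive trial count, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    lo = 1.0 / (2.0 * n)
    pc = min(max(p, lo), 1.0 - lo)
    return float(np.log(pc / (1.0 - pc)))


class GaussianTuningFitter(BaseEstimator, RegressorMixin):
    """Least-squares Gaussian tuning curve, ``Y = A exp(-0.5 (X-M)^2 / SD^2)``.

    Parameters
    ----------
    chance : float, default 0.5
        Guessing level of the task; a fitted amplitude within
        ``degenerate_margin`` of chance flags the fit as degenerate. Use 0
        for frequency (rather than proportion-correct) data.
    n_restarts : int, default 5
        Jittered restarts around the data-driven initial point
        (M at the argmax, A at the max, SD at half the sampled range).
    degenerate_margin : float, default 0.05
    random_state : int, default 0
        Seeds the restart jitter; fits are deterministic.

    Attributes
    ----------
    A_, M_, SD_ : float
        Fitted parameters (SD_ is reported positive).
    r2_ : float
        Coefficient of determination on the training data.
    degenerate_ : bool
        True when the amplitude is within ``degenerate_margin`` of chance
        or the tuning width exceeds the sampled X range.
    converged_ : bool
        False when no restart converged; the data-driven initial point is
        then reported instead of raising.
    """

    def __init__(self, chance: float = 0.5, n_restarts: int = 5,
                 degenerate_margin: float = 0.05, random_state: int = 0):
        self.chance = chance
        self.n_restarts = n_restarts
        self.degenerate_margin = degenerate_margin
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be 1-d (one predictor: end direction)")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(X).size < 4:
            raise ValueError("need at least 4 distinct end-direction levels")

        rng = np.random.default_rng(self.random_state)
        span = float(X.max() - X.min())
        p0 = np.array([float(y.max()), float(X[np.argmax(y)]), max(span / 2.0, 1e-3)])

        best, best_sse = None, np.inf
        for k in range(max(self.n_restarts, 1)):
            start = p0.copy()
            if k > 0:
                start[0] *= rng.uniform(0.7, 1.3)
                start[1] += rng.uniform(-0.25, 0.25) * span
                start[2] *= rng.uniform(0.5, 2.0)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, _ = curve_fit(gaussian_tuning, X, y, p0=start, maxfev=20_000)
            except RuntimeError:
                continue
            sse = float(np.sum((y - gaussian_tuning(X, *popt)) ** 2))
            if np.isfinite(sse) and sse < best_sse:
                best, best_sse = popt, sse

        if best is None:
            self.converged_ = False
            best = p0
        else:
            self.converged_ = True
        A, M, SD = float(best[0]), float(best[1]), abs(float(best[2]))

        ss_res = float(np.sum((y - gaussian_tuning(X, A, M, SD)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.A_, self.M_, self.SD_ = A, M, SD
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.degenerate_ = (
            not self.converged_
            or abs(A - self.chance) <= self.degenerate_margin
            or SD > span
        )
        self.x_range_ = (float(X.min()), float(X.max()))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "A_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return gaussian_tuning(X, self.A_, self.M_, self.SD_)

    def result_(self) -> TuningFit:
        check_is_fitted(self, "A_")
        return TuningFit(A=self.A_, M=self.M_, SD=self.SD_, r2=self.r2_,
                         degenerate=self.degenerate_, converged=self.converged_)


def fit_gaussian_tuning(table: pd.DataFrame, chance: float = 0.5, **kw) -> TuningFit:
    """Fit the tuning curve to a response table for one contour angle.

    ``table`` needs columns ``end_direction_deg``, ``n_trials`` and
    ``n_correct`` (or a precomputed ``proportion`` column).
    """
    if "proportion" in table:
        p = table["proportion"].to_numpy(float)
    else:
        n = table["n_trials"].to_numpy(float)
        k = table["n_correct"].to_numpy(float)
        if (n <= 0).any():
            raise ValueError("n_trials must be positive")
        if ((k < 0) | (k > n)).any():
            raise ValueError("n_correct must lie in [0, n_trials]")
        p = k / n
    est = GaussianTuningFitter(chance=chance, **kw)
    est.fit(table["end_direction_deg"].to_numpy(float), p)
    return est.result_()


def fit_tuning_by_angle(table: pd.DataFrame, chance: float = 0.5, **kw) -> pd.DataFrame:
    """Per-contour-angle tuning fits; one row per angle."""
    rows = []
    for angle, sub in table.groupby("contour_angle_deg"):
        fit = fit_gaussian_tuning(sub, chance=chance, **kw)
        rows.append({"contour_angle_deg": angle, **fit.to_dict()})
    return pd.DataFrame(rows)


def simulate_observer(
    surface: dict | pd.DataFrame,
    conditions: pd.DataFrame,
    n_trials: int,
    seed: int,
    chance: float = 0.5,
) -> pd.DataFrame:
    """Binomially sample a response table from a known tuning surface.

    ``surface`` maps contour angle to (A, M, SD), either as a dict of
    tuples/TuningFits or a DataFrame with columns (contour_angle_deg, A, M,
    SD). Per condition the success probability is
    ``max(chance, Y(end_direction))``; baseline rows (no end elements) use
    an explicit ``p_correct`` column when present, else chance.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if isinstance(surface, pd.DataFrame):
        surface = {
            float(r.contour_angle_deg): (float(r.A), float(r.M), float(r.SD))
            for r in surface.itertuples()
        }
    rng = np.random.default_rng(seed)
    out = conditions.copy().reset_index(drop=True)
    probs = np.empty(len(out))
    for i, row in out.iterrows():
        if bool(row.get("is_baseline", False)) or not np.isfinite(row["end_direction_deg"]):
            probs[i] = float(row["p_correct"]) if "p_correct" in row and np.isfinite(
                row.get("p_correct", np.nan)) else chance
            continue
        params = surface[float(row["contour_angle_deg"])]
        A, M, SD = (params.A, params.M, params.SD) if isinstance(params, TuningFit) else params
        probs[i] = max(chance, gaussian_tuning(float(row["end_direction_deg"]), A, M, SD))
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("tuning surface produced probabilities outside [0, 1]")
    out["n_trials"] = n_trials
    out["n_correct"] = rng.binomial(n_trials, probs)
    out["p_true"] = probs
    out["proportion"] = out["n_correct"] / out["n_trials"]
    return out
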