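"""Weight-versus-distance law fitting and residual extraction.

The central empirical regularity of mesoscale connectomes exploited here is
that connection strength decays with interregional Euclidean distance
approximately as a power law,

    W_ij = alpha * d_ij**(-beta) + eps_ij,

with an exponential law as the standard alternative.  Fits are done by
ordinary least squares on the log10 scale over strictly positive weights
(the convention under which the power law wins the model comparison on the
mouse data), or by Levenberg–Marquardt nonlinear least squares on the
linear scale.  The per-edge residuals eps_ij — in particular their sparse,
strong positive tail — are the object every null-model construction in
:mod:`connsync.builders` manipulates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import skew

from .connectome import Connectome

__all__ = ["DistanceModelFit", "ResidualField", "fit_distance_model",
           "predict_baseline", "compute_residuals", "fit_bilateral",
           "predict_baseline_bilateral"]


@dataclass(frozen=True)
class DistanceModelFit:
    """A fitted distance rule.

    ``model`` is 'power_law' (w = alpha * d**-beta) or 'exponential'
    (w = alpha * exp(-beta * d)); ``fit_scale`` is 'log10' (OLS of log10 w)
    or 'linear' (nonlinear least squares).  ``r_square`` and ``rmse`` are
    computed on the fit scale; ``n_edges_used`` counts the strictly positive
    off-diagonal weights that entered the fit.
    """

    model: str
    alpha: float
    beta: float
    fit_scale: str
    r_square: float
    rmse: float
    n_edges_used: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class ResidualField:
    """Per-edge residuals of a connectome around a fitted distance rule.

    ``residuals[i, j] = W_ij - baseline_ij`` on the linear weight scale;
    ``positive_mask`` flags edges above the rule.  Adding ``residuals`` back
    to the baseline reproduces the weight matrix exactly.
    """

    residuals: np.ndarray
    positive_mask: np.ndarray
    stats: dict

    def positive_values(self) -> np.ndarray:
        return self.residuals[self.positive_mask]

    def positive_mass(self) -> float:
        """Total strength carried by the positive residual tail."""
        return float(self.residuals[self.positive_mask].sum())


def _fit_arrays(conn_or_weights, distances=None, mask=None):
    if isinstance(conn_or_weights, Connectome):
        w, d = conn_or_weights.weights, conn_or_weights.distances
    else:
        w = np.asarray(conn_or_weights, dtype=float)
        d = np.asarray(distances, dtype=float)
    off = ~np.eye(w.shape[0], dtype=bool)
    if mask is not None:
        off = off & np.asarray(mask, dtype=bool)
    return w, d, off


def fit_distance_model(conn_or_weights, distances=None, *,
                       model: str = "power_law", fit_scale: str = "log10",
                       mask: np.ndarray | None = None) -> DistanceModelFit:
    """Fit a decaying weight–distance law.

    Parameters
    ----------
    conn_or_weights : a :class:`Connectome`, or a weight matrix (then
        ``distances`` is required).
    model : 'power_law' or 'exponential'.
    fit_scale : 'log10' — OLS of log10(w) on log10(d) (power law) or on d
        (exponential), over strictly positive off-diagonal weights;
        'linear' — Levenberg–Marquardt nonlinear least squares on the raw
        weights (zero weights included).
    mask : optional boolean matrix restricting the fitted edges (used for
        per-hemisphere block fits).

    Zero-weight edges are excluded on the log scale (their log is
    undefined); ``n_edges_used`` reports how many edges entered the fit.
    """
    if model not in ("power_law", "exponential"):
        raise ValueError(f"unknown model {model!r}")
    if fit_scale not in ("log10", "linear"):
        raise ValueError(f"unknown fit_scale {fit_scale!r}")
    w, d, off = _fit_arrays(conn_or_weights, distances, mask)
    if np.any(d[off] <= 0):
        raise ValueError("off-diagonal distances must be strictly positive")

    if fit_scale == "log10":
        use = off & (w > 0)
        n_used = int(use.sum())
        if n_used < 2:
            raise ValueError(f"need >= 2 positive-weight edges, have {n_used}")
        y = np.log10(w[use])
        x = np.log10(d[use]) if model == "power_law" else d[use]
        X = np.column_stack([np.ones_like(x), x])
        (b0, b1), res, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ np.array([b0, b1])
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        rmse = float(np.sqrt(ss_res / n_used))
        alpha = float(10.0 ** b0)
        beta = float(-b1) if model == "power_law" else float(-b1 * np.log(10.0))
        return DistanceModelFit(model, alpha, beta, "log10", r2, rmse, n_used)

    # linear scale: LM nonlinear least squares, zero weights kept
    use = off
    n_used = int(use.sum())
    if n_used < 2:
        raise ValueError(f"need >= 2 edges, have {n_used}")
    x, y = d[use], w[use]
    if model == "power_law":
        f = lambda x, a, b: a * x ** (-b)
    else:
        f = lambda x, a, b: a * np.exp(-b * x)
    # seed LM from the log-scale fit of the positive weights
    try:
        init = fit_distance_model(w, d, model=model, fit_scale="log10", mask=mask)
        p0 = (init.alpha, init.beta)
    except ValueError:
        p0 = (y.max(), 1.0 / np.median(x))
    popt, _ = curve_fit(f, x, y, p0=p0, method="lm", maxfev=20000)
    yhat = f(x, *popt)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / n_used))
    return DistanceModelFit(model, float(popt[0]), float(popt[1]), "linear",
                            r2, rmse, n_used)


def predict_baseline(fit: DistanceModelFit, distances: np.ndarray) -> np.ndarray:
    """Evaluate the fitted rule on a distance matrix; zero diagonal."""
    d = np.asarray(distances, dtype=float)
    off = ~np.eye(d.shape[0], dtype=bool)
    k = np.zeros_like(d)
    if fit.model == "power_law":
        k[off] = fit.alpha * d[off] ** (-fit.beta)
    else:
        k[off] = fit.alpha * np.exp(-fit.beta * d[off])
    return k


def compute_residuals(conn: Connectome, fit_or_baseline) -> ResidualField:
    """Residuals of the weights around a fitted rule, on the linear scale.

    ``fit_or_baseline`` is a :class:`DistanceModelFit` or a precomputed
    baseline matrix (e.g. a blockwise bilateral baseline).  Diagonal
    residuals are zero by construction.
    """
    if isinstance(fit_or_baseline, DistanceModelFit):
        baseline = predict_baseline(fit_or_baseline, conn.distances)
    else:
        baseline = np.asarray(fit_or_baseline, dtype=float)
    eps = conn.weights - baseline
    np.fill_diagonal(eps, 0.0)
    pos = eps > 0
    vals = eps[~np.eye(eps.shape[0], dtype=bool)]
    stats = {
        "mean": float(vals.mean()),
        "skew": float(skew(vals)),
        "positive_tail_mass": float(eps[pos].sum()),
        "n_positive": int(pos.sum()),
    }
    return ResidualField(eps, pos, stats)


def _hemisphere_masks(n: int, n_ipsi: int):
    h = n_ipsi
    same = np.zeros((n, n), dtype=bool)
    same[:h, :h] = True
    same[h:, h:] = True
    return same, ~same


def fit_bilateral(conn: Connectome, n_ipsi: int | None = None, **kwargs):
    """Fit the ipsilateral and contralateral blocks separately.

    Returns ``(fit_ipsi, fit_contra)``; ``n_ipsi`` defaults to half the
    nodes (mirror-symmetric assembly).
    """
    n = conn.n_regions
    if n_ipsi is None:
        n_ipsi = n // 2
    same, cross = _hemisphere_masks(n, n_ipsi)
    return (fit_distance_model(conn, mask=same, **kwargs),
            fit_distance_model(conn, mask=cross, **kwargs))


def predict_baseline_bilateral(fit_ipsi: DistanceModelFit,
                               fit_contra: DistanceModelFit,
                               distances: np.ndarray,
                               n_ipsi: int | None = None) -> np.ndarray:
    """Blockwise baseline: ipsilateral rule on same-hemisphere edges,
    contralateral rule on cross-hemisphere edges."""
    n = distances.shape[0]
    if n_ipsi is None:
        n_ipsi = n // 2
    same, cross = _hemisphere_masks(n, n_ipsi)
    k = predict_baseline(fit_ipsi, distances)
    kc = predict_baseline(fit_contra, distances)
    k[cross] = kc[cross]
    return k
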