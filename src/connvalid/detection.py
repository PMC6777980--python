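"""Binary detection performance of tractography against tracing.

The tract-tracing matrix is thresholded to a given connectome density
(proportion of strongest edges kept) and binarized; tractography is then
scored as a detector of those ground-truth edges.  Two evaluation modes
are reported:

* matched-density -- the prediction is binarized at the same density as
  the ground truth, giving one confusion tuple per density;
* sweep -- the prediction is thresholded at every distinct predicted
  weight (an ROC/PR point series), and sensitivity, specificity and
  precision are averaged over the sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "threshold_binarize",
    "confusion",
    "detection_sweep",
    "DetectionResult",
    "DEFAULT_DENSITIES",
]

DEFAULT_DENSITIES: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.91, 0.1), 1))


def _upper_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def threshold_binarize(
    conn: WeightedConnectome | np.ndarray, density: float
) -> np.ndarray:
    """Keep the given proportion of strongest unordered edges, binarized.

    Exactly ``ceil(density * E)`` off-diagonal unordered edges are set to
    1 (``E = n(n-1)/2``).  Ties at the cut are broken by stable (row,
    column) index order and logged.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must be in (0, 1], got {density}")
    W = conn.W if isinstance(conn, WeightedConnectome) else np.asarray(conn, dtype=float)
    if not np.array_equal(W, W.T):
        raise ValueError("threshold_binarize expects a symmetric matrix")
    n = W.shape[0]
    ii, jj = _upper_pairs(n)
    w = W[ii, jj]
    E = len(w)
    k = int(np.ceil(density * E))
    order = np.lexsort((jj, ii, -w))  # strongest first, stable index tie-break
    kept = order[:k]
    if k < E and w[order[k - 1]] == w[order[k]]:
        logger.info(
            "threshold_binarize: ties straddle the density=%.2f cut (weight %g)",
            density, w[order[k - 1]],
        )
    out = np.zeros_like(W)
    out[ii[kept], jj[kept]] = 1.0
    out[jj[kept], ii[kept]] = 1.0
    return out


def confusion(gt_bin: np.ndarray, pred_bin: np.ndarray) -> tuple[int, int, int, int]:
    """TP, FP, TN, FN over off-diagonal unordered pairs."""
    gt = np.asarray(gt_bin, dtype=float)
    pred = np.asarray(pred_bin, dtype=float)
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction have different shapes")
    for name, m in (("ground truth", gt), ("prediction", pred)):
        if not np.array_equal(m, m.T):
            raise ValueError(f"{name} matrix must be symmetric")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if not np.all(np.isin(off, (0.0, 1.0))):
            raise ValueError(f"{name} matrix must be binary")
    ii, jj = _upper_pairs(gt.shape[0])
    g, p = gt[ii, jj].astype(bool), pred[ii, jj].astype(bool)
    tp = int(np.sum(g & p))
    fp = int(np.sum(~g & p))
    tn = int(np.sum(~g & ~p))
    fn = int(np.sum(g & ~p))
    return tp, fp, tn, fn


def _measures(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    return sens, spec, prec


@dataclass
class DetectionResult:
    """Detection performance per ground-truth density.

    ``table`` holds one row per (density, mode) with confusion counts and
    derived measures; ``sweep_points`` holds the underlying ROC/PR point
    series (one row per prediction threshold per density).
    """

    densities: np.ndarray
    table: pd.DataFrame
    sweep_points: pd.DataFrame = field(default_factory=pd.DataFrame)

    def measures(self, mode: str) -> pd.DataFrame:
        return self.table[self.table["mode"] == mode].set_index("density_requested")


def detection_sweep(
    gt_w: WeightedConnectome,
    pred_w: WeightedConnectome,
    densities: tuple[float, ...] | np.ndarray = DEFAULT_DENSITIES,
) -> DetectionResult:
    """Score tractography as a detector of density-thresholded tracing edges.

    For each ground-truth density both evaluation modes are recorded (see
    module docstring).  The realized density (after the ceiling at the
    cut) is reported alongside the requested one.
    """
    if gt_w.regions != pred_w.regions:
        raise ValueError("ground truth and prediction use different region sets")
    densities = np.asarray(densities, dtype=float)
    if np.any(densities <= 0) or np.any(densities > 1):
        raise ValueError("densities must lie in (0, 1]")
    if np.all(pred_w.W == 0):
        raise ValueError("prediction matrix is all zero; nothing to threshold")
    n = gt_w.n
    ii, jj = _upper_pairs(n)
    E = len(ii)
    pred_weights = pred_w.W[ii, jj]
    thresholds = np.unique(pred_weights[pred_weights > 0])[::-1]  # strongest first
    rows = []
    points = []
    for d in densities:
        gt_bin = threshold_binarize(gt_w, d)
        realized = gt_bin[ii, jj].sum() / E
        # matched-density mode
        pb = threshold_binarize(pred_w, d)
        tp, fp, tn, fn = confusion(gt_bin, pb)
        sens, spec, prec = _measures(tp, fp, tn, fn)
        rows.append(dict(
            density_requested=d, density_realized=realized, mode="matched",
            TP=tp, FP=fp, TN=tn, FN=fn,
            sensitivity=sens, specificity=spec, precision=prec,
        ))
        # sweep mode: threshold the prediction at every distinct weight
        sweep = np.empty((len(thresholds), 3))
        for k, t in enumerate(thresholds):
            pb_t = np.where(pred_w.W >= t, 1.0, 0.0)
            np.fill_diagonal(pb_t, 0.0)
            tp, fp, tn, fn = confusion(gt_bin, pb_t)
            sens, spec, prec = _measures(tp, fp, tn, fn)
            sweep[k] = (sens, spec, prec)
            points.append(dict(
                density_requested=d, threshold=t,
                TP=tp, FP=fp, TN=tn, FN=fn,
                sensitivity=sens, specificity=spec, precision=prec,
            ))
        mean_sens, mean_spec, mean_prec = sweep.mean(axis=0)
        rows.append(dict(
            density_requested=d, density_realized=realized, mode="sweep",
            TP=np.nan, FP=np.nan, TN=np.nan, FN=np.nan,
            sensitivity=mean_sens, specificity=mean_spec, precision=mean_prec,
        ))
    return DetectionResult(
        densities=densities,
        table=pd.DataFrame(rows),
        sweep_points=pd.DataFrame(points),
    )
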