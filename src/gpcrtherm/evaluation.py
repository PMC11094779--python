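"""Regression metrics, classification-by-regression, and benchmarking.

Continuous stability predictions (dTm here; ddG for most other tools) are
made comparable across methods by classifying them into destabilizing /
neutral / stabilizing with a per-method neutral band: values below the
band's lower edge are destabilizing, above the upper edge stabilizing, and
values on or inside the band — boundaries included — neutral.  A symmetric
band scan locates the band that maximizes the Matthews correlation
coefficient.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

from .errors import GpcrthermError

LABELS = ("destabilizing", "neutral", "stabilizing")


@dataclasses.dataclass(frozen=True)
class NeutralBand:
    """Closed interval [lo, hi] treated as 'no effect'."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= 0 <= self.hi):
            raise ValueError(f"band must straddle zero, got [{self.lo}, {self.hi}]")


@dataclasses.dataclass
class EvalReport:
    """Metrics of one evaluation; classification fields are None for
    regression-only reports."""

    n: int
    pearson: float
    mse: float
    kendall_tau: float
    spearman_rho: float
    accuracy: float | None = None
    mcc: float | None = None
    weighted_f1: float | None = None
    band: NeutralBand | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.band is not None:
            d["band"] = [self.band.lo, self.band.hi]
        return d


def regression_metrics(y_true, y_pred) -> EvalReport:
    """Pearson r, MSE, tie-corrected Kendall tau, and Spearman rho."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal length")
    if len(y_true) < 3:
        raise ValueError("need at least 3 points")
    if np.std(y_true) == 0:
        raise GpcrthermError("correlations undefined: y_true is constant")
    return EvalReport(
        n=len(y_true),
        pearson=float(stats.pearsonr(y_true, y_pred)[0]),
        mse=float(np.mean((y_true - y_pred) ** 2)),
        kendall_tau=float(stats.kendalltau(y_true, y_pred)[0]),
        spearman_rho=float(stats.spearmanr(y_true, y_pred)[0]),
    )


def classify_by_regression(values, band: NeutralBand) -> np.ndarray:
    """Three-way labels from continuous values under a neutral band."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, "neutral", dtype=object)
    out[v < band.lo] = "destabilizing"
    out[v > band.hi] = "stabilizing"
    return out


def binary_stabilizing(values) -> np.ndarray:
    """0/1 labels: 1 for positive values, 0 for negative (and exact zero)."""
    v = np.asarray(values, dtype=float)
    return (v > 0).astype(int)


def classification_metrics(true_labels, pred_labels) -> tuple[float, float, float]:
    """(accuracy, multiclass MCC, support-weighted F1) over shared labels."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    acc = float(accuracy_score(t, p))
    if len(set(t.tolist())) < 2 and len(set(p.tolist())) < 2:
        warnings.warn("single-class labels: MCC undefined, reported as 0", stacklevel=2)
        mcc = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mcc = float(matthews_corrcoef(t, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = float(f1_score(t, p, average="weighted"))
    return acc, mcc, f1


def threshold_scan(
    y_true,
    y_pred,
    start: float = 0.1,
    step: float = 0.05,
    max_threshold: float = 3.0,
    pred_band: NeutralBand | None = None,
) -> pd.DataFrame:
    """Classification metrics over symmetric neutral bands (-t, t).

    Both truth and predictions are classified; when ``pred_band`` is given
    the predictions keep that fixed band (each method carries its own
    thresholds) while the truth band scans the grid, otherwise both sides
    use the scanned band.  Returns one row per band with an ``is_best``
    flag on the MCC argmax.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start > max_threshold:
        raise ValueError("start must not exceed max")
    n_bands = int(np.floor((max_threshold - start) / step + 1e-9)) + 1
    thresholds = start + step * np.arange(n_bands)
    rows = []
    for t in thresholds:
        band = NeutralBand(-t, t)
        truth = classify_by_regression(y_true, band)
        pred = classify_by_regression(y_pred, pred_band if pred_band is not None else band)
        acc, mcc, f1 = classification_metrics(truth, pred)
        rows.append(
            {
                "lo": -t,
                "hi": t,
                "accuracy": acc,
                "mcc": mcc,
                "weighted_f1": f1,
            }
        )
    df = pd.DataFrame(rows)
    df["is_best"] = False
    df.loc[df["mcc"].idxmax(), "is_best"] = True
    return df


def evaluate(
    y_true, y_pred, band: NeutralBand | None = None
) -> EvalReport:
    """Full report: regression metrics plus, given a band, classification."""
    report = regression_metrics(y_true, y_pred)
    if band is not None:
        truth = classify_by_regression(np.asarray(y_true, dtype=float), band)
        pred = classify_by_regression(np.asarray(y_pred, dtype=float), band)
        acc, mcc, f1 = classification_metrics(truth, pred)
        report.accuracy, report.mcc, report.weighted_f1 = acc, mcc, f1
        report.band = band
    return report


def benchmark(
    y_true,
    predictions: dict[str, Sequence[float]],
    bands: dict[str, NeutralBand],
    truth_band: NeutralBand,
) -> pd.DataFrame:
    """Compare methods' predictions against a common truth classification.

    Each method's continuous predictions are classified with that method's
    own band; the truth dTm values use ``truth_band``.
    """
    truth = classify_by_regression(np.asarray(y_true, dtype=float), truth_band)
    rows = []
    for method, pred in predictions.items():
        band = bands[method]
        labels = classify_by_regression(np.asarray(pred, dtype=float), band)
        acc, mcc, f1 = classification_metrics(truth, labels)
        rows.append(
            {
                "method": method,
                "lo": band.lo,
                "hi": band.hi,
                "accuracy": acc,
                "mcc": mcc,
                "weighted_f1": f1,
            }
        )
    return pd.DataFrame(rows)
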