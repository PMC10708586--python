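"""Classification and saliency evaluation metrics.

Classification metrics are derived from a confusion matrix via one-vs-rest
binary counts.  Two F1 conventions are carried side by side: the arithmetic
mean of precision and recall (``f1`` — the convention this pipeline
standardises on for parity with its reference results) and the usual
harmonic mean (``f1_harmonic``).  Cohen's kappa is computed from the binary
counts as ``2*(TP*TN - FN*FP) / ((TP+FP)*(FP+TN) + (TP+FN)*(FN+TN))`` and
macro-averaged over classes.

Saliency metrics: SIM (histogram intersection of unit-sum maps), SSIM
(windowed structural similarity with uniform LxL windows) and CC (Pearson
correlation over pixels).  Undefined values (zero denominators) surface as
NaN rather than being coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


# ---------------------------------------------------------------------------
# Confusion matrix and classification metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_counts(self, index: int):
        """One-vs-rest (TP, TN, FP, FN) for the class at ``index``."""
        tp = self.counts[index, index]
        fn = self.counts[index].sum() - tp
        fp = self.counts[:, index].sum() - tp
        tn = self.total - tp - fn - fp
        return int(tp), int(tn), int(fp), int(fn)


def confusion_matrix(y_true, y_pred, class_labels=None) -> ConfusionMatrix:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if class_labels is None:
        class_labels = sorted(set(y_true) | set(y_pred))
    class_labels = tuple(class_labels)
    index = {c: i for i, c in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, class_labels)


def _safe_div(num, den):
    return num / den if den != 0 else float("nan")


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy, precision, recall, both F1 conventions and kappa."""
    total = tp + tn + fp + fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    kappa_den = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    return {
        "accuracy": _safe_div(tp + tn, total),
        "precision": precision,
        "recall": recall,
        "f1": (precision + recall) / 2.0,
        "f1_harmonic": _safe_div(2.0 * precision * recall, precision + recall)
        if not (np.isnan(precision) or np.isnan(recall))
        else float("nan"),
        "kappa": _safe_div(2.0 * (tp * tn - fn * fp), kappa_den),
    }


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Overall accuracy plus macro-averaged one-vs-rest binary metrics.

    Returns ``{"accuracy", "precision", "recall", "f1", "f1_harmonic",
    "kappa", "per_class", "undefined"}`` where ``per_class`` is a DataFrame
    indexed by class label and ``undefined`` lists (class, metric) pairs
    whose denominator was zero (these are excluded from the macro means).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows, undefined = {}, []
    for i, label in enumerate(cm.class_labels):
        m = binary_metrics(*cm.binary_counts(i))
        rows[label] = m
        undefined.extend((label, k) for k, v in m.items() if np.isnan(v))
    per_class = pd.DataFrame(rows).T
    summary = {
        name: float(np.nanmean(per_class[name].to_numpy()))
        for name in ("precision", "recall", "f1", "f1_harmonic", "kappa")
    }
    summary["accuracy"] = float(np.trace(cm.counts) / cm.total)
    summary["per_class"] = per_class
    summary["undefined"] = undefined
    return summary


# ---------------------------------------------------------------------------
# Saliency metrics
# ---------------------------------------------------------------------------

def _as_map(x) -> np.ndarray:
    values = x.values if hasattr(x, "values") else x
    return np.asarray(values, dtype=float)


def sim(sm, fm) -> float:
    """Histogram-intersection similarity of two maps normalised to sum 1."""
    a, b = _as_map(sm), _as_map(fm)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("saliency maps must have positive mass")
    return float(np.minimum(a / a.sum(), b / b.sum()).sum())


@dataclass
class SSIMParams:
    """Window size and stabilising constants for structural similarity.

    ``K`` is the pixel-intensity range (2**bits - 1 for integer images,
    1.0 for unit-range floats); the stabilisers are k1 = (d1*K)^2 and
    k2 = (d2*K)^2 with d1 = 0.01, d2 = 0.03.
    """

    window: int = 11
    K: float | None = None
    d1: float = 0.01
    d2: float = 0.03

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")

    def constants(self, image: np.ndarray):
        K = self.K
        if K is None:
            K = 255.0 if np.issubdtype(image.dtype, np.integer) else 1.0
        return (self.d1 * K) ** 2, (self.d2 * K) ** 2


def ssim(m, n, params: SSIMParams | None = None) -> float:
    """Mean structural similarity over uniform LxL windows (stride 1, valid).

    Per window: (2*mu_m*mu_n + k1)(2*cov + k2) /
    ((mu_m^2 + mu_n^2 + k1)(var_m + var_n + k2)), with unbiased variance
    and covariance estimates, averaged over all fully-interior windows.
    """
    params = params or SSIMParams()
    m_raw = _as_map(m) if not isinstance(m, np.ndarray) else m
    n_raw = _as_map(n) if not isinstance(n, np.ndarray) else n
    if m_raw.shape != n_raw.shape:
        raise ValueError(f"shape mismatch: {m_raw.shape} vs {n_raw.shape}")
    L = params.window
    if min(m_raw.shape) < L:
        raise ValueError(f"image smaller than {L}x{L} window")
    k1, k2 = params.constants(np.asarray(m.values if hasattr(m, "values") else m))
    a = np.asarray(m_raw, dtype=float)
    b = np.asarray(n_raw, dtype=float)
    win = {"size": L, "mode": "constant"}
    mu_a = ndimage.uniform_filter(a, **win)
    mu_b = ndimage.uniform_filter(b, **win)
    e_aa = ndimage.uniform_filter(a * a, **win)
    e_bb = ndimage.uniform_filter(b * b, **win)
    e_ab = ndimage.uniform_filter(a * b, **win)
    npx = L * L
    corr = npx / (npx - 1.0)  # unbiased estimates
    var_a = (e_aa - mu_a * mu_a) * corr
    var_b = (e_bb - mu_b * mu_b) * corr
    cov = (e_ab - mu_a * mu_b) * corr
    num = (2 * mu_a * mu_b + k1) * (2 * cov + k2)
    den = (mu_a**2 + mu_b**2 + k1) * (var_a + var_b + k2)
    ssim_map = num / den
    pad = L // 2
    interior = ssim_map[pad:-pad or None, pad:-pad or None]
    return float(interior.mean())


def cc(fm, sm) -> float:
    """Pearson correlation between two maps over all pixels."""
    a, b = _as_map(fm).ravel(), _as_map(sm).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_saliency_per_class(pred_maps, truth_maps, labels,
                                ssim_params: SSIMParams | None = None) -> pd.DataFrame:
    """Mean SSIM and CC per digit class plus an overall Average row."""
    if not (len(pred_maps) == len(truth_maps) == len(labels)):
        raise ValueError("pred_maps, truth_maps and labels must be aligned")
    scores: dict = {}
    for pred, truth, label in zip(pred_maps, truth_maps, labels):
        s = ssim(_as_map(pred), _as_map(truth), ssim_params)
        c = cc(_as_map(pred), _as_map(truth))
        scores.setdefault(label, []).append((s, c))
    rows = []
    for label in sorted(scores, key=str):
        arr = np.array(scores[label])
        rows.append(
            {
                "category": label,
                "SSIM": float(np.nanmean(arr[:, 0])),
                "CC": float(np.nanmean(arr[:, 1])),
            }
        )
    table = pd.DataFrame(rows)
    avg = {
        "category": "Average",
        "SSIM": float(table["SSIM"].mean()),
        "CC": float(table["CC"].mean()),
    }
    return pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
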