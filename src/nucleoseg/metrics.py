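"""Pixel-based evaluation: confusion counts, accuracy, Jaccard, curves.

Accuracy is the fraction of correctly predicted pixels,
``(TP + TN) / (TP + FN + TN + FP)``; the Jaccard index (intersection over
union) is ``TP / (TP + FP + FN)``.  Jaccard ignores true negatives and is
therefore the more rigorous of the two when the object of interest is
small relative to the image.  Both metrics are computed per slice; the
headline summary is taken over the central band of slices (interquartile
range of slice indices), where the nucleus is actually present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CLASS_NAMES

__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "jaccard",
    "per_slice_curves",
    "iqr_summary",
    "plot_curves",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies for one class on one slice."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts of a predicted boolean mask against the truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FN + TN + FP); requires at least one pixel."""
    if c.total == 0:
        raise ValueError("accuracy is undefined for zero evaluated pixels")
    return (c.tp + c.tn) / c.total


def jaccard(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); defined as 1.0 when both sets are empty.

    The both-empty convention scores perfect agreement on absence, which
    matters on pole slices where the nucleus does not exist and the
    prediction is (correctly) empty.
    """
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def _binarize(stack: np.ndarray, class_of_interest) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.dtype == bool:
        return stack
    if class_of_interest is None:
        raise ValueError("label-map input requires a class_of_interest")
    if isinstance(class_of_interest, str):
        try:
            class_of_interest = CLASS_NAMES[class_of_interest]
        except KeyError:
            raise ValueError(
                f"unknown class {class_of_interest!r}; choose from {sorted(CLASS_NAMES)}"
            ) from None
    return stack == class_of_interest


def per_slice_curves(
    pred: np.ndarray, truth: np.ndarray, class_of_interest=None
) -> pd.DataFrame:
    """Per-slice accuracy and Jaccard of a predicted stack vs the truth.

    Inputs are boolean mask stacks, or integer four-class label stacks
    together with ``class_of_interest`` (name or label value), binarized
    one-vs-rest.  Returns a table with columns ``slice, accuracy, jaccard``.
    """
    p = _binarize(pred, class_of_interest)
    t = _binarize(truth, class_of_interest)
    if p.ndim == 2:
        p, t = p[None], t[None] if t.ndim == 2 else t
    if p.shape != t.shape:
        raise ValueError(f"geometry mismatch: pred {p.shape} vs truth {t.shape}")
    rows = []
    for i in range(p.shape[0]):
        c = confusion(p[i], t[i])
        rows.append({"slice": i, "accuracy": accuracy(c), "jaccard": jaccard(c)})
    return pd.DataFrame(rows, columns=["slice", "accuracy", "jaccard"])


def iqr_summary(
    curves: pd.DataFrame, low_fraction: float = 0.25, high_fraction: float = 0.75
) -> pd.DataFrame:
    """Summary statistics over the central band of slices.

    Restricts to slice indices in ``[low_fraction*n, high_fraction*n]``
    (inclusive; with 300 slices and the defaults that is slices 75–225)
    and reports mean/median/min/max per metric, indexed by metric name.
    """
    if curves.empty:
        raise ValueError("empty curve table")
    if not (0.0 <= low_fraction <= high_fraction <= 1.0):
        raise ValueError("need 0 <= low_fraction <= high_fraction <= 1")
    n = len(curves)
    lo = int(round(low_fraction * n))
    hi = int(round(high_fraction * n))
    sel = curves[(curves["slice"] >= lo) & (curves["slice"] <= hi)]
    if sel.empty:
        raise ValueError(f"no slices selected in band [{lo}, {hi}]")
    out = {}
    for metric in ("accuracy", "jaccard"):
        vals = sel[metric]
        out[metric] = {
            "mean": float(vals.mean()),
            "median": float(vals.median()),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return pd.DataFrame(out).T[["mean", "median", "min", "max"]]


def plot_curves(curves: pd.DataFrame, path, title: str = "Per-slice metrics") -> None:
    """Save a per-slice accuracy/Jaccard plot (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(curves["slice"], curves["accuracy"], label="accuracy")
    ax.plot(curves["slice"], curves["jaccard"], label="Jaccard index")
    ax.set_xlabel("slice")
    ax.set_ylabel("metric")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
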