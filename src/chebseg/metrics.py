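"""Pixel-level segmentation metrics, ROC analysis, and the additive
white-Gaussian-noise SNR robustness sweep.

Conventions: foreground is the positive class; Dice and IoU are 1.0 when
both masks are empty and 0.0 when exactly one is; zero-denominator ratio
metrics return 0 and set a warning flag instead of raising.  Sensitivity
and recall are both TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .preprocess import NORMALIZED, CTSlice

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "NoiseSweepResult",
    "confusion_counts",
    "dsc",
    "iou",
    "pixel_metrics",
    "evaluate_masks",
    "mean_report",
    "roc_curve",
    "add_awgn",
    "noise_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    dsc: float
    iou: float
    sensitivity: float
    recall: float
    precision: float
    zero_denominator: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "dsc": self.dsc, "iou": self.iou,
                "sensitivity": self.sensitivity, "recall": self.recall,
                "precision": self.precision}


@dataclass(frozen=True)
class NoiseSweepResult:
    snr_values: tuple[float, ...]
    accuracy_per_snr: tuple[float, ...]
    dice_per_snr: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.snr_values) != len(self.accuracy_per_snr):
            raise ValueError("one accuracy per SNR is required")


def _as_bool(mask) -> np.ndarray:
    px = getattr(mask, "pixels", mask)
    return np.asarray(px, dtype=bool)


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Per-pixel confusion tallies with foreground as the positive class."""
    s, t = _as_bool(predicted), _as_bool(truth)
    if s.shape != t.shape:
        raise ValueError("mask shapes differ")
    return ConfusionCounts(tp=int(np.sum(s & t)), tn=int(np.sum(~s & ~t)),
                           fp=int(np.sum(s & ~t)), fn=int(np.sum(~s & t)))


def dsc(predicted, truth) -> float:
    """Dice similarity coefficient 2|S∩T| / (|S|+|T|)."""
    s, t = _as_bool(predicted), _as_bool(truth)
    if s.shape != t.shape:
        raise ValueError("mask shapes differ")
    denom = s.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(s & t) / denom)


def iou(predicted, truth) -> float:
    """Jaccard index |S∩T| / |S∪T|."""
    s, t = _as_bool(predicted), _as_bool(truth)
    if s.shape != t.shape:
        raise ValueError("mask shapes differ")
    union = np.sum(s | t)
    if union == 0:
        return 1.0
    return float(np.sum(s & t) / union)


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def pixel_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, recall and precision from confusion counts.

    Sensitivity and recall share the formula TP/(TP+FN); Dice and IoU are
    derived from the same counts (S∩T = TP, |S| = TP+FP, |T| = TP+FN).
    """
    acc, w1 = _safe_ratio(counts.tp + counts.tn, counts.total)
    sens, w2 = _safe_ratio(counts.tp, counts.tp + counts.fn)
    prec, w3 = _safe_ratio(counts.tp, counts.tp + counts.fp)
    s_size = counts.tp + counts.fp
    t_size = counts.tp + counts.fn
    d = 1.0 if s_size + t_size == 0 else 2.0 * counts.tp / (s_size + t_size)
    union = s_size + t_size - counts.tp
    j = 1.0 if union == 0 else counts.tp / union
    return MetricReport(accuracy=acc, dsc=d, iou=j, sensitivity=sens,
                        recall=sens, precision=prec,
                        zero_denominator=w1 or w2 or w3)


def evaluate_masks(predicted, truth) -> MetricReport:
    """Full pixel-level report for one predicted/reference mask pair."""
    return pixel_metrics(confusion_counts(predicted, truth))


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Unweighted mean of metric reports (e.g. across folds)."""
    if not reports:
        raise ValueError("need at least one report")
    fields = ["accuracy", "dsc", "iou", "sensitivity", "recall", "precision"]
    means = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    return MetricReport(**means,
                        zero_denominator=any(r.zero_denominator for r in reports))


def roc_curve(scores: np.ndarray, labels: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr) over swept score thresholds plus trapezoidal area."""
    labels = np.asarray(labels).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC is undefined for single-class labels")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def add_awgn(ct_slice: CTSlice, snr_db: float, seed: int) -> CTSlice:
    """Add white Gaussian noise at a target SNR (dB) to a normalized slice.

    SNR = 10 log10(P_signal / P_noise) with P_signal the mean squared pixel
    intensity of the clean image.  The output is intentionally not clipped
    so the embedding stage sees the true perturbation.
    """
    if ct_slice.intensity_domain != NORMALIZED:
        raise ValueError("add_awgn expects a normalized slice")
    px = ct_slice.pixels
    p_signal = float(np.mean(px ** 2))
    if p_signal == 0:
        raise ValueError("signal power is zero; SNR is undefined")
    sigma = np.sqrt(p_signal / 10 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = px + rng.normal(0.0, sigma, size=px.shape)
    out = CTSlice(pixels=np.clip(noisy, 0.0, 1.0), intensity_domain=NORMALIZED)
    # keep the unclipped values: downstream SLIC should see the raw noise
    object.__setattr__(out, "pixels", noisy)
    return out


def noise_sweep(model, cases, snr_list, seed: int, n_regions: int = 600,
                beta: float = 10.0, compactness: float = 0.1,
                target: str = "liver") -> NoiseSweepResult:
    """Segmentation accuracy under additive noise across an SNR grid.

    Each test slice is corrupted at each SNR, re-embedded from scratch and
    segmented; pixel accuracy (and Dice) are averaged over slices per SNR.
    ``cases`` are phantom cases; ``target`` picks the liver or tumor mask.
    """
    from .network import predict_mask
    from .pipeline import preprocess_phantom

    snr_list = list(snr_list)
    if not snr_list:
        raise ValueError("snr_list must be nonempty")
    accs, dices = [], []
    for j, snr in enumerate(snr_list):
        case_accs, case_dices = [], []
        for i, case in enumerate(cases):
            clean_slice, masks = preprocess_phantom(case)
            noisy = add_awgn(clean_slice, snr, seed=seed + 7919 * j + i)
            pred, _ = predict_mask(model, noisy, n_regions=n_regions,
                                   beta=beta, compactness=compactness)
            truth = masks[target]
            rep = evaluate_masks(pred.pixels, truth.pixels)
            case_accs.append(rep.accuracy)
            case_dices.append(rep.dsc)
        accs.append(float(np.mean(case_accs)))
        dices.append(float(np.mean(case_dices)))
    return NoiseSweepResult(snr_values=tuple(float(s) for s in snr_list),
                            accuracy_per_snr=tuple(accs),
                            dice_per_snr=tuple(dices), seed=seed)
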