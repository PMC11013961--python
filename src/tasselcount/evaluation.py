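"""Count-accuracy metrics, a baseline component counter, and threshold sweeps.

Metrics over per-image (observed Tk, predicted T̂k) count pairs:

* **MAE** — mean |Tk − T̂k|;
* **NMSPE** — normalized mean square prediction error,
  (1/M) Σ (Tk − T̂k)²/T̂k, a Chi-square-like count-fit statistic;
* **PD** — predictive deviance, 2 Σ [Tk log(Tk/T̂k) − (Tk − T̂k)], a
  Poisson-deviance-style statistic with the log term zeroed when Tk = 0;
* Spearman rank correlation and r² (squared Pearson correlation).

NMSPE and PD divide by (or take logs of) the predicted count, which can be
0 after aggressive filtering, so a configurable floor (default 0.5 counts)
guards the denominator.

The threshold sweep re-filters every test image at each step-2 threshold
0…255, runs a pluggable counter, and records r² against ground truth — the
curve used to locate the filter band that counts best. A connected-component
counter over the two-step filter mask serves as a simple built-in detector.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, stats

from .core_io import CountRecord, RgbImage
from .errors import UndefinedCorrelationError, ValidationError
from .indices import rescaled_index, two_step_filter

__all__ = [
    "MetricsReport",
    "SweepResult",
    "mae",
    "nmspe",
    "predictive_deviance",
    "spearman",
    "r_squared",
    "metrics_report",
    "baseline_component_counter",
    "threshold_sweep",
    "make_baseline_sweep_counter",
]


@dataclasses.dataclass
class MetricsReport:
    """All count-accuracy metrics computed from one CountRecord set."""

    mae: float
    nmspe: float
    pd: float
    spearman: float
    r_squared: float
    n: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


@dataclasses.dataclass
class SweepResult:
    """r² vs. step-2 filter threshold, with the best threshold (ties → lowest)."""

    thresholds: np.ndarray
    r_squared: np.ndarray
    best_threshold: int
    best_r_squared: float
    degenerate: np.ndarray  # True where predictions had no variance (r² recorded 0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "thresholds": self.thresholds.tolist(),
                    "r_squared": self.r_squared.tolist(),
                    "best_threshold": int(self.best_threshold),
                    "best_r_squared": float(self.best_r_squared),
                    "degenerate": self.degenerate.astype(bool).tolist(),
                },
                indent=1,
            )
        )


def _obs_pred(records: Sequence[CountRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise ValidationError("empty record set")
    obs = np.array([r.observed for r in records], dtype=float)
    pred = np.array([r.predicted for r in records], dtype=float)
    return obs, pred


def mae(records: Sequence[CountRecord]) -> float:
    """Mean absolute error of predicted counts."""
    obs, pred = _obs_pred(records)
    return float(np.abs(obs - pred).mean())


def nmspe(records: Sequence[CountRecord], floor: float = 0.5) -> float:
    """Normalized mean square prediction error, (1/M) Σ (Tk−T̂k)²/max(T̂k, floor)."""
    obs, pred = _obs_pred(records)
    denom = np.maximum(pred, floor)
    return float(((obs - pred) ** 2 / denom).mean())


def predictive_deviance(records: Sequence[CountRecord], floor: float = 0.5) -> float:
    """Poisson-deviance-style statistic 2 Σ [Tk log(Tk/T̂k) − (Tk − T̂k)].

    The leading Tk·log term is taken to be 0 when Tk = 0; predicted counts
    are floored before the log/difference so the statistic stays finite.
    """
    obs, pred = _obs_pred(records)
    predf = np.maximum(pred, floor)
    lead = np.where(obs > 0, obs * np.log(np.where(obs > 0, obs, 1.0) / predf), 0.0)
    return float(2.0 * (lead - (obs - predf)).sum())


def spearman(records: Sequence[CountRecord]) -> float:
    """Spearman rank correlation of observed vs. predicted (average ranks for ties)."""
    obs, pred = _obs_pred(records)
    if len(obs) < 2:
        raise ValidationError("need >= 2 records for correlation")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedCorrelationError("zero variance in observed or predicted counts")
    return float(stats.spearmanr(obs, pred).statistic)


def r_squared(records: Sequence[CountRecord]) -> float:
    """Squared Pearson correlation between observed and predicted counts."""
    obs, pred = _obs_pred(records)
    if len(obs) < 2:
        raise ValidationError("need >= 2 records for correlation")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedCorrelationError("zero variance in observed or predicted counts")
    return float(stats.pearsonr(obs, pred).statistic ** 2)


def metrics_report(records: Sequence[CountRecord], floor: float = 0.5) -> MetricsReport:
    """Compute every metric on one record set."""
    return MetricsReport(
        mae=mae(records),
        nmspe=nmspe(records, floor),
        pd=predictive_deviance(records, floor),
        spearman=spearman(records),
        r_squared=r_squared(records),
        n=len(records),
    )


def baseline_component_counter(
    img: RgbImage,
    exg_threshold: float = 131.0,
    tassel_threshold: float = 90.0,
    min_area: int = 12,
) -> tuple[int, list[tuple[int, int, int, int]]]:
    """Count tassels as connected components of the two-step filter mask.

    The surviving mask is labeled with 8-connectivity and components with
    area >= ``min_area`` pixels are counted; their bounding boxes
    (row_min, col_min, height, width) are returned. A deliberately simple
    detector that slots into the sweep machinery wherever a trained
    detector would.
    """
    res = two_step_filter(img, exg_threshold, tassel_threshold)
    keep = res.step1_mask.keep & res.step2_mask.keep
    return _count_components(keep, min_area)


def _count_components(
    keep: np.ndarray, min_area: int
) -> tuple[int, list[tuple[int, int, int, int]]]:
    labels, n = ndimage.label(keep, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0, []
    areas = ndimage.sum_labels(keep, labels, index=np.arange(1, n + 1))
    boxes = []
    for i, sl in enumerate(ndimage.find_objects(labels)):
        if sl is not None and areas[i] >= min_area:
            boxes.append(
                (
                    sl[0].start,
                    sl[1].start,
                    sl[0].stop - sl[0].start,
                    sl[1].stop - sl[1].start,
                )
            )
    return len(boxes), boxes


def threshold_sweep(
    counter: Callable[[RgbImage, float], float],
    test_images: Sequence[RgbImage],
    truth: Sequence[int],
    thresholds: Sequence[int] = range(256),
) -> SweepResult:
    """Evaluate count accuracy (r² vs. truth) as test images are filtered at
    each step-2 threshold.

    ``counter`` is any callable ``(image, tassel_threshold) -> count`` —
    typically a partially applied :func:`baseline_component_counter` or a
    wrapper around a trained model applied to filtered images. Thresholds
    where the counter's predictions have no variance (e.g. everything
    filtered away) are recorded as r² = 0 with a degenerate flag so curves
    stay plottable.
    """
    if len(test_images) < 2:
        raise ValidationError("need >= 2 test images")
    truth_arr = np.array(truth, dtype=float)
    if np.ptp(truth_arr) == 0:
        raise ValidationError("ground-truth counts have zero variance")
    thresholds = np.asarray(list(thresholds), dtype=int)
    r2 = np.zeros(len(thresholds))
    degen = np.zeros(len(thresholds), dtype=bool)
    for i, t in enumerate(thresholds):
        preds = np.array([counter(img, float(t)) for img in test_images], dtype=float)
        if np.ptp(preds) == 0:
            degen[i] = True
            r2[i] = 0.0
        else:
            r2[i] = stats.pearsonr(truth_arr, preds).statistic ** 2
    best = int(np.argmax(r2))  # argmax returns the first (lowest) threshold on ties
    return SweepResult(thresholds, r2, int(thresholds[best]), float(r2[best]), degen)


def make_baseline_sweep_counter(
    exg_threshold: float = 131.0, min_area: int = 12
) -> Callable[[RgbImage, float], float]:
    """Baseline counter family for :func:`threshold_sweep`, with per-image
    caching of the two index maps so a 256-point sweep stays fast."""
    cache: dict[int, tuple[np.ndarray, "np.ndarray"]] = {}

    def counter(img: RgbImage, tassel_threshold: float) -> float:
        key = id(img)
        if key not in cache:
            step1 = rescaled_index(img, "exg").values >= exg_threshold
            cache[key] = (step1, rescaled_index(img, "tassel").values)
        step1, tassel_vals = cache[key]
        keep = step1 & (tassel_vals >= tassel_threshold)
        return float(_count_components(keep, min_area)[0])

    return counter
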