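"""Agreement between two segmentations (machine vs manual/ground truth).

Objects are matched greedily in descending intersection-over-union
(Jaccard) order; agreement is summarized as mean ± sd of matched
per-object IoU plus the object-count ratio. A best-case global
threshold segmentation is provided as the baseline the machine-learning
segmentation is compared against on salt-bearing scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import Image, LabelMask, ProbabilityMap, relabel_sequential_mask
from .measure import segment

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MatchTable:
    """Greedy one-to-one object matches between two label masks."""

    pairs: tuple[tuple[int, int, int, int, float], ...]  # (ref, test, inter, union, iou)
    unmatched_ref: tuple[int, ...]
    unmatched_test: tuple[int, ...]
    n_ref: int
    n_test: int

    @property
    def ious(self) -> np.ndarray:
        return np.array([p[4] for p in self.pairs], dtype=float)


@dataclass(frozen=True)
class AgreementSummary:
    """Mean ± sd of matched per-object IoU and the object-count ratio.

    ``count_ratio`` is test N / ref N; ``inf`` when the reference is
    empty but the test is not, and flagged ``degenerate`` whenever a
    side is empty. Pixel-level Jaccard over the whole field is reported
    alongside the per-object headline figure.
    """

    mean_iou: float
    sd_iou: float
    n_scored: int
    count_ratio: float
    n_ref: int
    n_test: int
    n_unmatched_ref: int
    n_unmatched_test: int
    pixel_jaccard: float
    degenerate: bool = False


def match_objects(ref: LabelMask, test: LabelMask, iou_min: float = 0.2) -> MatchTable:
    """Greedy descending-IoU matching of objects between two masks.

    Candidate pairs (every ref/test pair with nonzero overlap) are
    sorted by descending IoU with (ref id, test id) tie-break; each id
    is used at most once; pairs below ``iou_min`` stay unmatched.
    """
    if ref.shape != test.shape:
        raise ValueError(f"mask shapes differ: {ref.shape} vs {test.shape}")
    r = ref.labels
    t = test.labels
    n_ref, n_test = ref.n_objects, test.n_objects

    both = (r > 0) & (t > 0)
    pairs_raw = np.stack([r[both], t[both]], axis=1) if both.any() else np.empty((0, 2), int)
    if len(pairs_raw):
        uniq, inter = np.unique(pairs_raw, axis=0, return_counts=True)
    else:
        uniq, inter = np.empty((0, 2), int), np.empty(0, int)
    area_ref = np.bincount(r.ravel(), minlength=n_ref + 1)
    area_test = np.bincount(t.ravel(), minlength=n_test + 1)

    candidates = []
    for (ri, ti), ov in zip(uniq, inter):
        union = int(area_ref[ri] + area_test[ti] - ov)
        iou = float(ov) / union
        candidates.append((-iou, int(ri), int(ti), int(ov), union))
    candidates.sort()

    used_ref: set[int] = set()
    used_test: set[int] = set()
    matched = []
    for neg_iou, ri, ti, ov, union in candidates:
        iou = -neg_iou
        if iou < iou_min or ri in used_ref or ti in used_test:
            continue
        used_ref.add(ri)
        used_test.add(ti)
        matched.append((ri, ti, ov, union, iou))
    unmatched_ref = tuple(i for i in range(1, n_ref + 1) if i not in used_ref)
    unmatched_test = tuple(i for i in range(1, n_test + 1) if i not in used_test)
    return MatchTable(tuple(matched), unmatched_ref, unmatched_test, n_ref, n_test)


def _pixel_jaccard(ref: LabelMask, test: LabelMask) -> float:
    a = ref.labels > 0
    b = test.labels > 0
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def agreement_summary(matches: MatchTable, ref: LabelMask | None = None,
                      test: LabelMask | None = None) -> AgreementSummary:
    """Summarize a match table; pixel Jaccard if the masks are supplied."""
    ious = matches.ious
    n = len(ious)
    degenerate = matches.n_ref == 0 or matches.n_test == 0
    if matches.n_ref == 0:
        ratio = float("inf") if matches.n_test else float("nan")
    else:
        ratio = matches.n_test / matches.n_ref
    pixel_j = _pixel_jaccard(ref, test) if ref is not None and test is not None else float("nan")
    return AgreementSummary(
        mean_iou=float(np.mean(ious)) if n else float("nan"),
        sd_iou=float(np.std(ious, ddof=1)) if n > 1 else (0.0 if n == 1 else float("nan")),
        n_scored=n,
        count_ratio=ratio,
        n_ref=matches.n_ref,
        n_test=matches.n_test,
        n_unmatched_ref=len(matches.unmatched_ref),
        n_unmatched_test=len(matches.unmatched_test),
        pixel_jaccard=pixel_j,
        degenerate=degenerate,
    )


def threshold_baseline(img: Image, reference: np.ndarray | LabelMask,
                       min_size: int = 4, n_thresholds: int = 256) -> LabelMask:
    """Best-case global-threshold segmentation (oracle baseline).

    Sweeps candidate thresholds over the intensity range and keeps the
    one maximizing pixel F1 against the reference foreground — an upper
    bound on what plain thresholding could achieve. Components below
    ``min_size`` px are removed, matching the ML segmentation path.
    """
    truth = reference.labels > 0 if isinstance(reference, LabelMask) else \
        np.asarray(reference).astype(bool)
    if truth.shape != img.shape:
        raise ValueError("reference shape does not match image")
    pixels = img.pixels
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo or not truth.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), provenance="threshold_baseline")
    n_pos = truth.sum()
    best_f1, best_thr = -1.0, hi
    for thr in np.linspace(lo, hi, n_thresholds, endpoint=False)[1:]:
        pred = pixels >= thr
        tp = np.logical_and(pred, truth).sum()
        denom = pred.sum() + n_pos
        f1 = 2.0 * tp / denom if denom else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, thr
    mask = pixels >= best_thr
    labels, _ = ndimage.label(mask, structure=_STRUCT_8)
    if labels.max() > 0 and min_size > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_size)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    return relabel_sequential_mask(labels, provenance=f"threshold_baseline(t={best_thr:.1f})")


def object_precision(detected: LabelMask, truth: LabelMask, iou_min: float = 0.2) -> float:
    """Fraction of detected objects that match a true object (IoU ≥ iou_min)."""
    if detected.n_objects == 0:
        return float("nan")
    matches = match_objects(truth, detected, iou_min=iou_min)
    return len(matches.pairs) / detected.n_objects


def validation_report(summary: AgreementSummary) -> str:
    """Human-readable validation log."""
    lines = [
        "segmentation agreement report",
        f"  reference objects : {summary.n_ref}",
        f"  test objects      : {summary.n_test}",
        f"  count ratio       : {summary.count_ratio:.3f}",
        f"  objects scored    : {summary.n_scored}",
        f"  mean IoU          : {summary.mean_iou:.3f}",
        f"  sd IoU            : {summary.sd_iou:.3f}",
        f"  pixel Jaccard     : {summary.pixel_jaccard:.3f}",
        f"  unmatched ref/test: {summary.n_unmatched_ref}/{summary.n_unmatched_test}",
    ]
    if summary.degenerate:
        lines.append("  WARNING: degenerate comparison (an empty side)")
    return "\n".join(lines)
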