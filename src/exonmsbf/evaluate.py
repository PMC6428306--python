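"""Nucleotide-level evaluation of exon score tracks.

Implements confusion counts under a threshold sweep, the approximate
correlation (AC) summary, sensitivity/specificity and ROC/AUC, best-AC
stratified by exon length, and the inter-scale analyses: Jensen-Shannon
divergence between coefficient histograms at adjacent scales for exon
versus intron positions, and per-scale histogram means.

Conventions
-----------
* A position is called exonic when its normalized score is >= the
  threshold; the default sweep uses 101 evenly spaced thresholds on
  [0, 1] (tracks are max-normalized).
* AC ratios with a zero denominator are dropped and the mean is taken
  over the remaining ratios (the convention of the metric's original
  nucleotide-accuracy definition); if all four are undefined the metric
  raises.
* JS divergence uses log base 2, so it is bounded in [0, 1], with
  0*log(0) := 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .seqio import ExonInterval
from .transform import ProductStack, ScoreTrack, TransformStack

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "LengthStratification",
    "DEFAULT_LENGTH_RANGES",
    "exon_mask",
    "confusion_at_threshold",
    "approximate_correlation",
    "roc_auc",
    "stratified_best_ac",
    "js_divergence",
    "interscale_js_table",
    "histogram_means_by_scale",
    "exon_recovery",
]

#: The ten exon-length classes (nt), half-open; the last is unbounded.
DEFAULT_LENGTH_RANGES: tuple[tuple[int, float], ...] = (
    (1, 25),
    (25, 50),
    (50, 75),
    (75, 100),
    (100, 125),
    (125, 150),
    (150, 175),
    (175, 200),
    (200, 300),
    (300, float("inf")),
)


def range_label(rng: tuple[int, float]) -> str:
    lo, hi = rng
    return f"[{lo},{'inf' if np.isinf(hi) else int(hi)})"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class LengthStratification:
    ranges: tuple[tuple[int, float], ...]
    best_ac: dict[str, float]
    best_threshold: dict[str, float]
    n_exons: dict[str, int] = field(default_factory=dict)


def exon_mask(length: int, exons: Iterable[ExonInterval]) -> np.ndarray:
    """Boolean per-position exon membership for one record."""
    mask = np.zeros(length, dtype=bool)
    for iv in exons:
        if iv.end > length:
            raise ValueError(
                f"interval {iv.record_id}:{iv.start}-{iv.end} beyond track "
                f"length {length}"
            )
        mask[iv.start : iv.end] = True
    return mask


def _scores_mask(
    track: ScoreTrack, exons: Sequence[ExonInterval]
) -> tuple[np.ndarray, np.ndarray]:
    if not exons:
        raise ValueError("no annotations supplied; evaluation is meaningless")
    return track.Sp, exon_mask(track.length, exons)


def _confusion_arrays(
    scores: np.ndarray, mask: np.ndarray, threshold: float
) -> ConfusionCounts:
    pred = scores >= threshold
    return ConfusionCounts(
        TP=int(np.count_nonzero(pred & mask)),
        TN=int(np.count_nonzero(~pred & ~mask)),
        FP=int(np.count_nonzero(pred & ~mask)),
        FN=int(np.count_nonzero(~pred & mask)),
    )


def confusion_at_threshold(
    track: ScoreTrack, exons: Sequence[ExonInterval], threshold: float
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN calling positions with Sp >= threshold exonic."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    scores, mask = _scores_mask(track, exons)
    return _confusion_arrays(scores, mask, threshold)


def approximate_correlation(c: ConfusionCounts) -> float:
    """Approximate correlation: 2 * (mean of four conditional ratios - 1/2).

    Ratios with zero denominators are dropped; AC ranges over [-1, 1] and
    equals 1 only for a perfect prediction with both classes present.
    """
    pairs = [
        (c.TP, c.TP + c.FN),
        (c.TP, c.TP + c.FP),
        (c.TN, c.TN + c.FP),
        (c.TN, c.TN + c.FN),
    ]
    ratios = [num / den for num, den in pairs if den > 0]
    if not ratios:
        raise ValueError("all four AC ratios are undefined (empty confusion)")
    return (sum(ratios) / len(ratios) - 0.5) * 2.0


def _roc_from_arrays(
    scores: np.ndarray, mask: np.ndarray, n_thresholds: int
) -> RocCurve:
    if n_thresholds < 2:
        raise ValueError("need at least 2 thresholds")
    n_pos = int(mask.sum())
    n_neg = int(mask.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single-class annotation; ROC undefined")
    # descending sweep over [0, 1]; a virtual threshold above max pins (0, 0).
    # Built as the reversed ascending grid so thresholds match the exact
    # floats of np.linspace(0, 1, n) used elsewhere.
    thresholds = np.linspace(0.0, 1.0, n_thresholds)[::-1]
    se = np.empty(n_thresholds)
    sp = np.empty(n_thresholds)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        se[i] = np.count_nonzero(pred & mask) / n_pos
        sp[i] = np.count_nonzero(~pred & ~mask) / n_neg
    fpr = np.concatenate(([0.0], 1.0 - sp))
    tpr = np.concatenate(([0.0], se))
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(thresholds=thresholds, sensitivity=se, specificity=sp, auc=auc)


def roc_auc(
    track: ScoreTrack | tuple[np.ndarray, np.ndarray],
    exons: Sequence[ExonInterval] | None = None,
    n_thresholds: int = 101,
) -> RocCurve:
    """ROC curve and trapezoidal AUC over a descending threshold sweep.

    Accepts either a :class:`ScoreTrack` with its annotations, or a
    pre-built ``(scores, mask)`` pair (e.g. pooled over many records).
    """
    if isinstance(track, ScoreTrack):
        scores, mask = _scores_mask(track, exons or [])
    else:
        scores, mask = track
    return _roc_from_arrays(np.asarray(scores, float), np.asarray(mask, bool), n_thresholds)


def stratified_best_ac(
    tracks: Sequence[ScoreTrack] | ScoreTrack,
    exons: Sequence[ExonInterval],
    ranges: Sequence[tuple[int, float]] = DEFAULT_LENGTH_RANGES,
    n_thresholds: int = 101,
) -> LengthStratification:
    """Best AC over the threshold sweep, per exon-length class.

    For each length range, positive positions are those inside exons of
    that length; negatives are all intron positions.  Positions inside
    exons of *other* lengths are excluded so detecting them is not
    penalized.  Ranges with no exons are reported as absent.
    """
    if isinstance(tracks, ScoreTrack):
        tracks = [tracks]
    if not exons:
        raise ValueError("no annotations supplied; evaluation is meaningless")
    by_record: dict[str, list[ExonInterval]] = {}
    for iv in exons:
        by_record.setdefault(iv.record_id, []).append(iv)

    scores = np.concatenate([t.Sp for t in tracks])
    any_exon = np.concatenate(
        [exon_mask(t.length, by_record.get(t.record_id, [])) for t in tracks]
    )
    offsets = np.cumsum([0] + [t.length for t in tracks])
    rec_offset = {t.record_id: offsets[i] for i, t in enumerate(tracks)}

    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    best_ac: dict[str, float] = {}
    best_thr: dict[str, float] = {}
    n_ex: dict[str, int] = {}
    for rng in ranges:
        lo, hi = rng
        members = [
            iv for iv in exons if lo <= iv.length < hi and iv.record_id in rec_offset
        ]
        if not members:
            continue
        pos_mask = np.zeros_like(any_exon)
        for iv in members:
            off = rec_offset[iv.record_id]
            pos_mask[off + iv.start : off + iv.end] = True
        keep = pos_mask | ~any_exon  # this range's exons + all introns
        s, m = scores[keep], pos_mask[keep]
        acs = []
        for t in thresholds:
            try:
                acs.append(approximate_correlation(_confusion_arrays(s, m, t)))
            except ValueError:
                acs.append(-np.inf)
        i_best = int(np.argmax(acs))
        label = range_label(rng)
        best_ac[label] = float(acs[i_best])
        best_thr[label] = float(thresholds[i_best])
        n_ex[label] = len(members)
    return LengthStratification(
        ranges=tuple(ranges), best_ac=best_ac, best_threshold=best_thr, n_exons=n_ex
    )


def exon_recovery(
    pairs: Sequence[tuple[ScoreTrack, Sequence[ExonInterval]]],
    min_length: int = 75,
    tolerance: int = 20,
    intron_percentile: float = 90.0,
) -> tuple[int, int]:
    """Count planted exons marked by a strong local maximum of Sp.

    An exon of length >= ``min_length`` counts as recovered when a local
    maximum of its track's Sp exceeding the ``intron_percentile``-th
    percentile of that track's intron scores lies inside the exon or
    within ``tolerance`` nt of its boundaries.  Returns
    ``(n_recovered, n_eligible)``.
    """
    recovered = 0
    eligible = 0
    for track, exons in pairs:
        if not exons:
            continue
        mask = exon_mask(track.length, exons)
        cutoff = np.percentile(track.Sp[~mask], intron_percentile)
        peaks, _ = find_peaks(track.Sp)
        peaks = peaks[track.Sp[peaks] > cutoff]
        for iv in exons:
            if iv.length < min_length:
                continue
            eligible += 1
            if peaks.size and np.any(
                (peaks >= iv.start - tolerance) & (peaks < iv.end + tolerance)
            ):
                recovered += 1
    return recovered, eligible


def js_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon divergence (log base 2) between probability vectors.

    Symmetric, bounded in [0, 1]; 1 is attained for disjoint supports.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 1:
        raise ValueError("P and Q must be 1-D vectors of equal length")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("probability vectors must be nonnegative")
    if not (np.isclose(P.sum(), 1.0, atol=1e-9) and np.isclose(Q.sum(), 1.0, atol=1e-9)):
        raise ValueError("probability vectors must each sum to 1")
    M = 0.5 * (P + Q)

    def kl(A: np.ndarray) -> float:
        nz = A > 0
        return float(np.sum(A[nz] * np.log2(A[nz] / M[nz])))

    return 0.5 * kl(P) + 0.5 * kl(Q)


def _stack_magnitudes(
    stack: TransformStack | ProductStack | np.ndarray, component: str = "domain"
) -> np.ndarray:
    if isinstance(stack, TransformStack):
        if component == "domain":
            return np.abs(stack.U_d)
        if component == "range":
            return stack.U_r
        if component == "bilateral":
            return np.abs(stack.U)
        raise ValueError("component must be 'domain', 'range' or 'bilateral'")
    if isinstance(stack, ProductStack):
        return stack.MP
    return np.abs(np.asarray(stack))


def _hist_prob(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(x, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty histogram; no positions in class")
    return counts / total


def interscale_js_table(
    stack: TransformStack | ProductStack | np.ndarray,
    exons: Sequence[ExonInterval] | np.ndarray,
    n_bins: int = 100,
    component: str = "domain",
) -> tuple[np.ndarray, np.ndarray]:
    """JS divergence of coefficient magnitudes between adjacent scales.

    For every adjacent scale pair, magnitude histograms are built on
    shared equal-width bins spanning the pooled exon-and-intron range of
    the two scales, separately for exon positions and intron positions.
    Returns ``(exon_js, intron_js)``, each of length (number of rows - 1).

    For a :class:`TransformStack`, ``component`` selects which
    coefficients are analysed; the default is the domain-branch
    magnitudes ``|U_d|``: the inter-scale comparison probes how stable
    the multiscale decomposition of each class is across scales, and the
    range envelope's own scale-dependent shape would confound that
    comparison (``"bilateral"`` and ``"range"`` remain selectable).

    ``exons`` may be a list of intervals (single record) or a precomputed
    boolean mask matching the stack's positional axis (e.g. pooled over
    records).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 histogram bins")
    mags = _stack_magnitudes(stack, component)
    J, N = mags.shape
    if J < 2:
        raise ValueError("need at least 2 scales for adjacent pairs")
    if isinstance(exons, np.ndarray):
        mask = np.asarray(exons, bool)
    else:
        mask = exon_mask(N, exons)
    if mask.all() or not mask.any():
        raise ValueError("need both exon and intron positions")
    exon_js = np.empty(J - 1)
    intron_js = np.empty(J - 1)
    for j in range(J - 1):
        pooled = np.concatenate([mags[j], mags[j + 1]])
        lo, hi = float(pooled.min()), float(pooled.max())
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
        exon_js[j] = js_divergence(
            _hist_prob(mags[j][mask], edges), _hist_prob(mags[j + 1][mask], edges)
        )
        intron_js[j] = js_divergence(
            _hist_prob(mags[j][~mask], edges), _hist_prob(mags[j + 1][~mask], edges)
        )
    return exon_js, intron_js


def histogram_means_by_scale(
    stack: TransformStack | ProductStack | np.ndarray,
    exons: Sequence[ExonInterval] | np.ndarray,
    n_bins: int = 100,
    component: str = "bilateral",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean coefficient magnitude within exons and within introns, per row.

    The ``n_bins`` argument is accepted for interface symmetry with the
    histogram analyses; the mean of the binned distribution converges to
    the plain mean, which is what is computed.  For a
    :class:`TransformStack` the bilateral coefficients are analysed by
    default (the quantity the exon/intron amplitude-contrast claim is
    about); ``component`` selects another branch.
    """
    mags = _stack_magnitudes(stack, component)
    J, N = mags.shape
    if isinstance(exons, np.ndarray):
        mask = np.asarray(exons, bool)
    else:
        mask = exon_mask(N, exons)
    exon_means = mags[:, mask].mean(axis=1) if mask.any() else np.zeros(J)
    intron_means = mags[:, ~mask].mean(axis=1) if (~mask).any() else np.zeros(J)
    return exon_means, intron_means
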