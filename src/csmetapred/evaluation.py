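"""Ranked-retrieval evaluation of catalytic-residue predictions.

Every statistic treats one protein's descending-score ranking against its
gold-standard catalytic residues (the positive class) and sweeps the rank
cutoff n: the top-n residues are called positive, the rest negative.  The
module provides

* confusion quantities at any cutoff, per-protein ROC and PR points;
* vertically averaged ROC curves (TPR linearly interpolated on a fixed FPR
  grid, averaged over proteins) and their trapezoid AUCROC;
* Average Specificity, AveS = sum_r S(r) * pos(r) / Npos, where S(r) is the
  specificity at cutoff r and pos(r) = 1 iff the residue at rank r is
  catalytic — so a perfect ranking scores 1; MAS is its dataset mean;
* Average Precision (mean of precision at each catalytic residue's
  retrieval rank) and MAP, its dataset mean;
* averaged PR curves with the Davis–Goadrich local-skew interpolation
  between achievable recall levels (linear PR interpolation is knowingly
  wrong and never used), and their trapezoid AUCPR;
* recall–filtration-ratio (RFR) curves, catalytic-residue coverage curves,
  and the paired Wilcoxon signed-rank comparison of two methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ranking import RankedPrediction, _in_subset
from .score_io import GoldAnnotation, ResidueKey

logger = logging.getLogger(__name__)

#: Default FPR / recall grid for curve averaging (step 0.01 over [0, 1]).
DEFAULT_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


class ConfigurationError(ValueError):
    """Evaluation inputs are inconsistent (e.g. a gold residue missing from
    the ranking being evaluated)."""


@dataclass
class ConfusionAtRank:
    rank_cutoff: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 1.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)


@dataclass
class Curve:
    """An evaluation curve; ``kind`` in {roc, pr, rfr, coverage}."""

    kind: str
    points: list[tuple[float, float]]
    area: float | None = None

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class PerProteinSummary:
    protein_id: str
    aves: float
    ap: float
    catalytic_ranks: list[int] = field(default_factory=list)


@dataclass
class DatasetSummary:
    """Dataset-level aggregate of per-protein summaries."""

    n_proteins: int
    mas: float
    map: float
    median_rank: float
    mean_rank: float


def restrict_gold(gold: GoldAnnotation, subset: str) -> GoldAnnotation:
    """Gold annotation restricted to a residue-type subset (for within-subset
    evaluation of polar-only / nonpolar-only rankings)."""
    return GoldAnnotation(
        protein_id=gold.protein_id,
        catalytic=frozenset(k for k in gold.catalytic if _in_subset(k, subset)),
    )


def _check_gold(pred: RankedPrediction, gold: GoldAnnotation) -> set[ResidueKey]:
    ranked = set(pred.keys)
    for key in gold.catalytic:
        if key not in ranked:
            raise ConfigurationError(
                f"protein {pred.protein_id}: gold catalytic residue {key} "
                f"is absent from the ranked list"
            )
    return set(gold.catalytic)


def catalytic_ranks(pred: RankedPrediction, gold: GoldAnnotation) -> list[int]:
    """Sorted ranks at which the gold catalytic residues are retrieved."""
    positives = _check_gold(pred, gold)
    return sorted(r for k, _, r in pred.entries if k in positives)


def confusion(pred: RankedPrediction, gold: GoldAnnotation, n: int) -> ConfusionAtRank:
    """Confusion counts with the top-n ranked residues called positive."""
    total = len(pred)
    if not (1 <= n <= total):
        raise ValueError(f"cutoff {n} outside 1..{total}")
    positives = _check_gold(pred, gold)
    npos = len(positives)
    tp = sum(1 for k, _, r in pred.entries if r <= n and k in positives)
    fp = n - tp
    fn = npos - tp
    tn = total - npos - fp
    return ConfusionAtRank(rank_cutoff=n, tp=tp, fp=fp, tn=tn, fn=fn)


# -- ROC ---------------------------------------------------------------------

def roc_curve(pred: RankedPrediction, gold: GoldAnnotation) -> Curve:
    """Per-protein ROC points (FPR, TPR) over all rank cutoffs 0..N."""
    hits = catalytic_ranks(pred, gold)
    npos = len(hits)
    total = len(pred)
    nneg = total - npos
    if npos == 0 or nneg == 0:
        raise ConfigurationError(
            f"protein {pred.protein_id}: ROC undefined with {npos} positives "
            f"of {total} residues"
        )
    hit_set = set(hits)
    points = [(0.0, 0.0)]
    tp = fp = 0
    for r in range(1, total + 1):
        if r in hit_set:
            tp += 1
        else:
            fp += 1
        points.append((fp / nneg, tp / npos))
    return Curve(kind="roc", points=points)


def vertical_average_roc(curves: list[Curve], grid: Sequence[float] | None = None) -> Curve:
    """Average per-protein ROC curves vertically on a fixed FPR grid.

    Each protein's TPR is linearly interpolated at every grid FPR (taking the
    best achievable TPR where several cutoffs share an FPR), then averaged
    across proteins; the area under the averaged curve (trapezoid) is the
    AUCROC.
    """
    if not curves:
        raise ValueError("need at least one ROC curve")
    g = np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float)
    tprs = np.empty((len(curves), g.size))
    for i, curve in enumerate(curves):
        fpr = curve.x
        tpr = curve.y
        # collapse duplicate FPR values to the maximum TPR achieved there
        uniq: dict[float, float] = {}
        for x, y in zip(fpr, tpr):
            if x not in uniq or y > uniq[x]:
                uniq[x] = y
        xs = np.array(sorted(uniq))
        ys = np.array([uniq[x] for x in xs])
        tprs[i] = np.interp(g, xs, ys)
    mean_tpr = tprs.mean(axis=0)
    area = float(np.trapezoid(mean_tpr, g))
    return Curve(kind="roc", points=list(zip(g.tolist(), mean_tpr.tolist())), area=area)


# -- AveS / AP ---------------------------------------------------------------

def aves(pred: RankedPrediction, gold: GoldAnnotation) -> float:
    """Average Specificity: mean specificity over the catalytic ranks.

    S(r) is evaluated at the cutoff equal to each catalytic residue's own
    rank, so exactly Npos terms contribute; a ranking placing all catalytic
    residues on top scores 1 and one placing a positive at the very bottom
    contributes 0 for that residue.
    """
    hits = catalytic_ranks(pred, gold)
    npos = len(hits)
    if npos == 0:
        raise ConfigurationError(f"protein {pred.protein_id}: no positive examples")
    nneg = len(pred) - npos
    if nneg == 0:
        logger.warning("protein %s: every residue is catalytic; AveS = 1", pred.protein_id)
        return 1.0
    total = 0.0
    for i, r in enumerate(hits, start=1):
        fp = r - i  # non-catalytic residues ranked above cutoff r
        total += (nneg - fp) / nneg
    return total / npos


def average_precision(pred: RankedPrediction, gold: GoldAnnotation) -> float:
    """AP: mean of precision at each catalytic residue's retrieval rank."""
    hits = catalytic_ranks(pred, gold)
    if not hits:
        raise ConfigurationError(f"protein {pred.protein_id}: no positive examples")
    return sum(i / r for i, r in enumerate(hits, start=1)) / len(hits)


# -- PR ----------------------------------------------------------------------

def pr_curve(pred: RankedPrediction, gold: GoldAnnotation, grid: Sequence[float] | None = None) -> Curve:
    """Per-protein PR points at the achievable recall levels.

    Points are (recall, precision) at the cutoff where each successive
    catalytic residue is retrieved; the area is the trapezoid area of the
    Davis–Goadrich-interpolated curve evaluated on the recall grid.
    """
    hits = catalytic_ranks(pred, gold)
    npos = len(hits)
    if npos == 0:
        raise ConfigurationError(f"protein {pred.protein_id}: no positive examples")
    points = [(k / npos, k / r) for k, r in enumerate(hits, start=1)]
    g = np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float)
    prec = _pr_precision_on_grid(hits, npos, g)
    area = float(np.trapezoid(prec, g))
    return Curve(kind="pr", points=points, area=area)


def _pr_precision_on_grid(hits: list[int], npos: int, grid: np.ndarray) -> np.ndarray:
    """Precision at arbitrary recall levels via Davis–Goadrich interpolation.

    Between adjacent achievable points A = (TP_A, FP_A) and B = (TP_B, FP_B)
    intermediate true positives are added one unit at a time while false
    positives grow by the local skew increment (FP_B - FP_A)/(TP_B - TP_A),
    giving precision TP / (TP + FP_A + s * (TP - TP_A)).  Below the first
    achievable recall the precision of the first retrieved positive is
    carried flat to recall 0.
    """
    tp_grid = grid * npos  # continuous true-positive count
    fp_at = [r - k for k, r in enumerate(hits, start=1)]  # FP at each hit
    prec = np.empty_like(tp_grid)
    for idx, t in enumerate(tp_grid):
        if t <= 1.0:
            prec[idx] = 1.0 / hits[0]  # precision of the first positive
            continue
        k = min(int(np.ceil(t)) - 1, npos - 1)  # interval (k, k+1], 1-based hits[k-1]
        t0, fp0 = float(k), float(fp_at[k - 1])
        if t > k:  # strictly inside interval (k, k+1]
            s = fp_at[k] - fp_at[k - 1]  # local skew per unit TP
            fp = fp0 + s * (t - t0)
            prec[idx] = t / (t + fp)
        else:  # exactly at an achievable level
            prec[idx] = t0 / (t0 + fp0)
    return prec


def average_pr_curve(
    per_protein: list[tuple[RankedPrediction, GoldAnnotation]],
    grid: Sequence[float] | None = None,
) -> Curve:
    """Average per-protein PR curves on a fixed recall grid.

    Each protein's precision is evaluated at every grid recall value via the
    Davis–Goadrich local-skew interpolation, then averaged; the trapezoid
    area of the averaged curve is the AUCPR.
    """
    if not per_protein:
        raise ValueError("need at least one protein")
    g = np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float)
    precs = np.empty((len(per_protein), g.size))
    for i, (pred, gold) in enumerate(per_protein):
        hits = catalytic_ranks(pred, gold)
        if not hits:
            raise ConfigurationError(f"protein {pred.protein_id}: no positive examples")
        precs[i] = _pr_precision_on_grid(hits, len(hits), g)
    mean_prec = precs.mean(axis=0)
    area = float(np.trapezoid(mean_prec, g))
    return Curve(kind="pr", points=list(zip(g.tolist(), mean_prec.tolist())), area=area)


# -- dataset summaries -------------------------------------------------------

def per_protein_summary(pred: RankedPrediction, gold: GoldAnnotation) -> PerProteinSummary:
    return PerProteinSummary(
        protein_id=pred.protein_id,
        aves=aves(pred, gold),
        ap=average_precision(pred, gold),
        catalytic_ranks=catalytic_ranks(pred, gold),
    )


def summarize_dataset(per_protein: list[PerProteinSummary]) -> DatasetSummary:
    """MAS, MAP, and pooled median/mean catalytic rank over a dataset."""
    if not per_protein:
        raise ValueError("need at least one protein summary")
    pooled = [r for s in per_protein for r in s.catalytic_ranks]
    return DatasetSummary(
        n_proteins=len(per_protein),
        mas=float(np.mean([s.aves for s in per_protein])),
        map=float(np.mean([s.ap for s in per_protein])),
        median_rank=float(median(pooled)),
        mean_rank=float(np.mean(pooled)),
    )


def evaluate_dataset(
    per_protein: list[tuple[RankedPrediction, GoldAnnotation]],
) -> tuple[list[PerProteinSummary], DatasetSummary]:
    """Summarize a dataset, excluding proteins without annotated positives.

    AveS and AP are undefined at Npos = 0, so such proteins are dropped with
    a logged count.
    """
    kept = [(p, g) for p, g in per_protein if g.catalytic]
    skipped = len(per_protein) - len(kept)
    if skipped:
        logger.warning("excluded %d protein(s) with no annotated catalytic residue", skipped)
    summaries = [per_protein_summary(p, g) for p, g in kept]
    return summaries, summarize_dataset(summaries)


# -- rank / coverage analyses ------------------------------------------------

def rfr_curve(
    per_protein: list[tuple[RankedPrediction, GoldAnnotation]],
    ratios: Sequence[float] | None = None,
) -> Curve:
    """Recall–Filtration-Ratio curve: mean recall when the top k% of each
    protein's ranked residues (ceiling) are called positive, over a grid of
    filtration ratios k."""
    if not per_protein:
        raise ValueError("need at least one protein")
    ks = np.arange(0.0, 100.5, 1.0) if ratios is None else np.asarray(ratios, dtype=float)
    points = []
    for k in ks:
        recalls = []
        for pred, gold in per_protein:
            hits = catalytic_ranks(pred, gold)
            limit = int(np.ceil(k * len(pred) / 100.0))
            recalls.append(sum(1 for r in hits if r <= limit) / len(hits))
        points.append((float(k) / 100.0, float(np.mean(recalls))))
    return Curve(kind="rfr", points=points)


def coverage_curve(
    per_protein: list[tuple[RankedPrediction, GoldAnnotation]],
    thresholds: Sequence[float] = (0.5, 0.8, 1.0),
    max_rank: int = 100,
) -> list[Curve]:
    """Fraction of proteins reaching a catalytic-residue coverage threshold
    at each rank cutoff r = 1..max_rank.

    Coverage of a protein at rank r is the fraction of its gold residues
    retrieved at ranks <= r; each returned curve (one per threshold) is
    non-decreasing in r.  Curve x is the rank scaled by ``max_rank``.
    """
    if not per_protein:
        raise ValueError("need at least one protein")
    all_hits = [catalytic_ranks(p, g) for p, g in per_protein]
    curves = []
    for thr in thresholds:
        points = []
        for r in range(1, max_rank + 1):
            frac = np.mean([
                (sum(1 for h in hits if h <= r) / len(hits)) >= thr
                for hits in all_hits
            ])
            points.append((r / max_rank, float(frac)))
        curves.append(Curve(kind="coverage", points=points))
    return curves


# -- paired comparison -------------------------------------------------------

def paired_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-protein scores.

    Zero differences are dropped first; at least 6 informative pairs are
    required (the test is meaningless below that).  If every difference is
    zero the methods are indistinguishable and p = 1 is returned with a
    warning.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    nz = d[d != 0.0]
    if nz.size == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 1.0
    if nz.size < 6:
        raise ValueError(f"only {nz.size} non-zero difference(s); need >= 6")
    return float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
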