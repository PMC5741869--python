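"""Ranked residue lists, residue-type subsets, and prediction cut-offs.

Residues are ranked by descending score; catalytic residues are expected
near the top.  Because catalytic residues are overwhelmingly polar/charged,
the 12 polar/charged amino acids (R, N, D, C, Q, E, H, K, S, T, Y, W) and
the remaining 8 non-polar ones can also be ranked separately: subset
filtering is applied *before* ranking so that ranks are within-subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .score_io import NONPOLAR_AA, POLAR_AA, ResidueKey

logger = logging.getLogger(__name__)

SUBSETS = ("all", "polar", "nonpolar")

#: Sentinel score for residues appended to a ranking without a score.
UNSCORED = float("-inf")


@dataclass
class RankedPrediction:
    """A descending-score residue ranking for one protein (one subset)."""

    protein_id: str
    entries: list[tuple[ResidueKey, float, int]] = field(default_factory=list)
    subset: str = "all"

    @property
    def keys(self) -> list[ResidueKey]:
        return [k for k, _, _ in self.entries]

    def rank_of(self, key: ResidueKey) -> int:
        for k, _, r in self.entries:
            if k == key:
                return r
        raise KeyError(key)

    def __len__(self) -> int:
        return len(self.entries)


def _in_subset(key: ResidueKey, subset: str) -> bool:
    if subset == "all":
        return True
    if subset == "polar":
        return key.aa in POLAR_AA
    if subset == "nonpolar":
        return key.aa in NONPOLAR_AA
    raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")


def rank_residues(
    scores: Mapping[ResidueKey, float],
    subset: str = "all",
    protein_id: str = "",
    universe: Iterable[ResidueKey] | None = None,
) -> RankedPrediction:
    """Rank residues by descending score.

    Ties break by residue position (chain, resnum, icode) ascending — an
    arbitrary but deterministic rule.  If ``universe`` is given, residues in
    it that carry no score are appended after all scored residues (score
    sentinel ``-inf``), so the ranking covers the whole chain even for
    methods that score only a subset of residues.
    """
    if not scores and universe is None:
        raise ValueError("cannot rank an empty score mapping")
    pool = dict(scores)
    if universe is not None:
        for key in universe:
            pool.setdefault(key, UNSCORED)
    items = [(k, v) for k, v in pool.items() if _in_subset(k, subset)]
    if not items:
        logger.warning("protein %s: no residue left after %s-subset filtering", protein_id, subset)
        return RankedPrediction(protein_id=protein_id, entries=[], subset=subset)
    items.sort(key=lambda kv: (-kv[1], kv[0].position))
    entries = [(k, v, i + 1) for i, (k, v) in enumerate(items)]
    return RankedPrediction(protein_id=protein_id, entries=entries, subset=subset)


def predict_binary(pred: RankedPrediction, mode: str, value: float) -> set[ResidueKey]:
    """Binary catalytic-residue call from a ranking.

    ``rank_cutoff`` keeps residues with rank <= value; ``filtration_ratio``
    keeps the top ``ceil(value * N / 100)`` residues of an N-residue ranking
    (ceiling, so any positive ratio selects at least one residue).
    """
    if value <= 0:
        raise ValueError("cutoff value must be positive")
    n = len(pred)
    if mode == "rank_cutoff":
        limit = int(value)
    elif mode == "filtration_ratio":
        limit = math.ceil(value * n / 100.0)
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    return {k for k, _, r in pred.entries if r <= limit}
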