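"""Z-normalization of constituent scores and the availability-weighted
consensus meta-score (av-csc).

Each constituent method j assigns a raw score S(ij) to a subset of residues.
Scores are z-normalized per protein, per method, over the residues that
method actually scored:

    zSc(ij) = (S(ij) - mu(j)) / sigma(j)

and the meta-score of residue i is the mean of its available z-scores:

    av-csc(i) = sum_j zSc(ij) * p(j) / sum_j p(j)

where p(j) = 1 when method j scored residue i and 0 otherwise.  High av-csc
marks a residue that scores consistently high across independent predictors,
the signature expected of a catalytic residue.  With the canonical five
sources (crpred, discern, exia2_rank, wcn, catsid) the denominator is at
most 5; the rank score contributes two tables (rank score and WCN are taken
as independent scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .score_io import MethodScoreTable, ResidueKey

logger = logging.getLogger(__name__)


@dataclass
class NormalizedScoreTable:
    """Per-method z-scores plus the normalization constants used."""

    method_id: str
    zscores: dict[ResidueKey, float]
    mu: float
    sigma: float

    @property
    def availability(self) -> frozenset[ResidueKey]:
        return frozenset(self.zscores)


@dataclass
class MetaProfile:
    """Per-residue consensus meta-score for one protein chain.

    ``av_csc`` is defined exactly for residues scored by at least one
    method; ``n_methods`` records how many methods contributed to each.
    """

    protein_id: str
    av_csc: dict[ResidueKey, float] = field(default_factory=dict)
    n_methods: dict[ResidueKey, int] = field(default_factory=dict)


def normalize(table: MethodScoreTable) -> NormalizedScoreTable:
    """Z-normalize one method's scores over the residues it scored.

    Mean and standard deviation (population, n-denominator) are computed
    over this protein's scored residues only.  Degenerate cases — a single
    scored residue, or all scores identical (sigma = 0) — map every z-score
    to 0 with a logged warning: the method then contributes "average"
    evidence rather than failing the whole consensus.
    """
    if not table.scores:
        raise ValueError(f"cannot normalize empty score table {table.method_id!r}")
    keys = list(table.scores)
    values = np.array([table.scores[k] for k in keys], dtype=float)
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma == 0.0:
        logger.warning(
            "method %s: all %d score(s) identical; z-scores set to 0",
            table.method_id, len(values),
        )
        z = np.zeros_like(values)
    else:
        z = (values - mu) / sigma
    return NormalizedScoreTable(
        method_id=table.method_id,
        zscores=dict(zip(keys, z.tolist())),
        mu=mu,
        sigma=sigma,
    )


def meta_score(tables: list[NormalizedScoreTable], protein_id: str = "") -> MetaProfile:
    """Average available z-scores per residue into the consensus meta-score.

    Residues scored by no method are absent from the profile (sum p = 0).
    """
    if not tables:
        raise ValueError("meta_score needs at least one normalized table")
    total: dict[ResidueKey, float] = {}
    count: dict[ResidueKey, int] = {}
    for table in tables:
        for key, z in table.zscores.items():
            total[key] = total.get(key, 0.0) + z
            count[key] = count.get(key, 0) + 1
    av = {key: total[key] / count[key] for key in total}
    return MetaProfile(protein_id=protein_id, av_csc=av, n_methods=count)


def consensus_profile(
    raw_tables: list[MethodScoreTable], protein_id: str = ""
) -> MetaProfile:
    """Convenience: normalize each raw table, then combine into a profile."""
    return meta_score([normalize(t) for t in raw_tables], protein_id=protein_id)


PROFILE_HEADER = ["chain", "resnum", "icode", "aa", "av_csc", "n_methods", "rank"]


def write_profile_tsv(meta: MetaProfile, path, universe=None) -> None:
    """Write a meta-profile as a ranked TSV.

    Scored residues come first in descending av-csc order (ties by residue
    position); residues of ``universe`` that no method scored are listed
    last, flagged ``unscored``, with empty score and n_methods 0.
    """
    scored = sorted(meta.av_csc, key=lambda k: (-meta.av_csc[k], k.position))
    unscored = []
    if universe is not None:
        present = set(meta.av_csc)
        unscored = sorted((k for k in universe if k not in present), key=lambda k: k.position)
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_HEADER + ["status"]) + "\n")
        rank = 0
        for k in scored + unscored:
            rank += 1
            if k in meta.av_csc:
                fh.write(f"{k.chain}\t{k.resnum}\t{k.icode}\t{k.aa}\t"
                         f"{meta.av_csc[k]!r}\t{meta.n_methods[k]}\t{rank}\tscored\n")
            else:
                fh.write(f"{k.chain}\t{k.resnum}\t{k.icode}\t{k.aa}\t\t0\t{rank}\tunscored\n")


def read_profile_tsv(path, protein_id: str = "") -> tuple[MetaProfile, list[ResidueKey]]:
    """Read back a profile TSV; returns the profile plus the full residue
    universe (scored and unscored rows)."""
    from .score_io import ScoreIOError, _parse_residue_fields

    av: dict[ResidueKey, float] = {}
    n: dict[ResidueKey, int] = {}
    universe: list[ResidueKey] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t")[:7] != PROFILE_HEADER:
        raise ScoreIOError(f"{path}: not a meta-profile TSV")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        key = _parse_residue_fields(*fields[:4], path=str(path), lineno=lineno)
        universe.append(key)
        if fields[4].strip():
            av[key] = float(fields[4])
            n[key] = int(fields[5])
    return MetaProfile(protein_id=protein_id, av_csc=av, n_methods=n), universe
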