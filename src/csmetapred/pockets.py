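"""Pocket re-ranking, merging, and the pocket-boosted meta-score.

Catalytic residues overwhelmingly sit in or next to substrate-binding
pockets.  This module exploits that: predicted pockets from two geometric
detectors (Fpocket and LIGSITE) are re-scored with the consensus meta-score,

    poc_sc(i) = mean over pocket residues j of av-csc(j),

the top-k pockets of each detector (k = 5 by default) are pooled and any two
pockets sharing at least half their residues are merged (transitively, to
closure), and every residue receives a pocket residue score

    poc_Rsc(r) = max over pockets containing r of poc_sc,   0 outside pockets,

which is added to the meta-score to give the boosted ranking score

    av-csc-poc(i) = av-csc(i) + poc_Rsc(i).

The whole stage is a pure function of (pockets, meta profile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .consensus import MetaProfile
from .score_io import ResidueKey, ScoreIOError, _parse_residue_fields

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 5          # pockets kept per detector after re-ranking
DEFAULT_MIN_OVERLAP = 0.5  # common-residue fraction triggering a merge


@dataclass(frozen=True)
class Pocket:
    """A detector-predicted pocket as a set of lining residues."""

    pocket_id: str
    source: str                      # fpocket | ligsite | merged | generic
    residues: frozenset[ResidueKey]
    native_rank: int                 # rank assigned by the source detector
    poc_sc: float | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"pocket {self.pocket_id!r} has no residues")


@dataclass
class BoostedProfile:
    """Meta-score plus pocket residue score, per residue."""

    protein_id: str
    av_csc_poc: dict[ResidueKey, float] = field(default_factory=dict)
    poc_rsc: dict[ResidueKey, float] = field(default_factory=dict)


def pocket_score(pocket: Pocket, meta: MetaProfile) -> float:
    """Mean meta-score of the pocket's residues.

    Residues without an av-csc value are excluded from both numerator and
    denominator (a zero placeholder would bias the score toward 0).  If no
    pocket residue is scored at all, the pocket scores 0 with a warning.
    """
    scored = [meta.av_csc[r] for r in pocket.residues if r in meta.av_csc]
    if not scored:
        logger.warning("pocket %s: no residue has a meta-score; poc_sc = 0", pocket.pocket_id)
        return 0.0
    return sum(scored) / len(scored)


def score_pockets(pockets: list[Pocket], meta: MetaProfile) -> list[Pocket]:
    """Return copies of the pockets with ``poc_sc`` assigned."""
    return [replace(p, poc_sc=pocket_score(p, meta)) for p in pockets]


def select_top_pockets(pockets: list[Pocket], meta: MetaProfile, k: int = DEFAULT_TOP_K) -> list[Pocket]:
    """Re-rank one detector's pockets by poc_sc and keep the best ``k``.

    Ties break by native detector rank (ascending), then pocket id.
    """
    scored = score_pockets(pockets, meta)
    scored.sort(key=lambda p: (-p.poc_sc, p.native_rank, p.pocket_id))
    return scored[: min(k, len(scored))]


def _overlap_fraction(a: frozenset, b: frozenset, denominator: str) -> float:
    common = len(a & b)
    if denominator == "smaller":
        return common / min(len(a), len(b))
    if denominator == "union":
        return common / len(a | b)
    raise ValueError(f"unknown overlap denominator {denominator!r}")


def merge_pockets(
    set_a: list[Pocket],
    set_b: list[Pocket],
    meta: MetaProfile,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    denominator: str = "smaller",
) -> list[Pocket]:
    """Pool two detectors' top pockets and merge overlapping ones to closure.

    Two pockets merge when their common-residue fraction — relative to the
    smaller pocket by default (``denominator="union"`` gives Jaccard) — is at
    least ``min_overlap``.  Merging replaces the pair by the union of their
    residue sets and is repeated, re-testing against current unions, until no
    pair qualifies; the result is therefore independent of input order.
    Every output pocket's poc_sc is recomputed on its final residue set, and
    merged pockets carry the ids of their constituents as provenance.
    """
    pool = [
        replace(p, provenance=p.provenance or (p.pocket_id,))
        for p in list(set_a) + list(set_b)
    ]
    changed = True
    while changed:
        changed = False
        pool.sort(key=lambda p: p.pocket_id)
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                frac = _overlap_fraction(pool[i].residues, pool[j].residues, denominator)
                if frac >= min_overlap:
                    a, b = pool[i], pool[j]
                    merged = Pocket(
                        pocket_id="+".join(sorted(set(a.provenance) | set(b.provenance))),
                        source="merged",
                        residues=a.residues | b.residues,
                        native_rank=min(a.native_rank, b.native_rank),
                        provenance=tuple(sorted(set(a.provenance) | set(b.provenance))),
                    )
                    pool = [p for idx, p in enumerate(pool) if idx not in (i, j)] + [merged]
                    changed = True
                    break
            if changed:
                break
    return score_pockets(pool, meta)


def pocket_residue_score(pockets: list[Pocket]) -> dict[ResidueKey, float]:
    """poc_Rsc: per residue, the maximum poc_sc over the pockets containing it.

    Residues outside every pocket are simply absent (treated as 0 by
    :func:`boost`).  Negative pocket scores pass through unclamped.
    """
    rsc: dict[ResidueKey, float] = {}
    for pocket in pockets:
        if pocket.poc_sc is None:
            raise ValueError(f"pocket {pocket.pocket_id!r} has no poc_sc; score it first")
        for r in pocket.residues:
            if r not in rsc or pocket.poc_sc > rsc[r]:
                rsc[r] = pocket.poc_sc
    return rsc


def boost(
    meta: MetaProfile,
    poc_rsc: dict[ResidueKey, float],
    clamp_pocket_score: bool = False,
) -> BoostedProfile:
    """av-csc-poc(i) = av-csc(i) + poc_Rsc(i), with poc_Rsc = 0 off-pocket.

    ``clamp_pocket_score`` clamps negative pocket residue scores to 0, so a
    residue inside a poor pocket never ranks below an identical residue
    outside all pockets.
    """
    rsc = {
        r: (max(v, 0.0) if clamp_pocket_score else v)
        for r, v in poc_rsc.items()
    }
    boosted = {r: v + rsc.get(r, 0.0) for r, v in meta.av_csc.items()}
    full_rsc = {r: rsc.get(r, 0.0) for r in meta.av_csc}
    return BoostedProfile(protein_id=meta.protein_id, av_csc_poc=boosted, poc_rsc=full_rsc)


def boosted_profile(
    meta: MetaProfile,
    fpocket_pockets: list[Pocket],
    ligsite_pockets: list[Pocket],
    k: int = DEFAULT_TOP_K,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    clamp_pocket_score: bool = False,
) -> BoostedProfile:
    """Full pocket stage: re-rank, select top-k per detector, merge, boost."""
    top_f = select_top_pockets(fpocket_pockets, meta, k=k)
    top_l = select_top_pockets(ligsite_pockets, meta, k=k)
    merged = merge_pockets(top_f, top_l, meta, min_overlap=min_overlap)
    return boost(meta, pocket_residue_score(merged), clamp_pocket_score=clamp_pocket_score)


# ---------------------------------------------------------------------------
# Pocket file parsers.  The generic record format is the package's own
# interchange dialect; the fpocket/ligsite readers accept the output layouts
# emulated by the synthetic fixture generator (a PDB-style per-pocket atom
# listing for Fpocket, a whitespace residue table for LIGSITE).
# ---------------------------------------------------------------------------

def read_pockets_generic(path: str | Path) -> list[Pocket]:
    """Read the generic pocket dialect.

    Records open with ``>pocket_id source native_rank`` followed by one
    residue per line (``chain\\tresnum\\ticode\\taa``).
    """
    path = Path(path)
    pockets: list[Pocket] = []
    header: tuple[str, str, int] | None = None
    residues: set[ResidueKey] = set()

    def flush():
        if header is not None:
            pockets.append(Pocket(header[0], header[1], frozenset(residues), header[2]))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                if len(parts) != 3:
                    raise ScoreIOError(f"{path}:{lineno}: expected '>pocket_id source native_rank'")
                header = (parts[0], parts[1], int(parts[2]))
                residues = set()
            else:
                if header is None:
                    raise ScoreIOError(f"{path}:{lineno}: residue line before any '>' record")
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ScoreIOError(f"{path}:{lineno}: expected 4 tab-separated fields")
                residues.add(_parse_residue_fields(*fields, path=str(path), lineno=lineno))
    flush()
    return pockets


def write_pockets_generic(pockets: list[Pocket], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(pockets, key=lambda q: q.native_rank):
            fh.write(f">{p.pocket_id} {p.source} {p.native_rank}\n")
            for r in sorted(p.residues, key=lambda k: k.position):
                fh.write(f"{r.chain}\t{r.resnum}\t{r.icode}\t{r.aa}\n")


_AA3 = None


def _three_to_one(resname: str) -> str:
    global _AA3
    if _AA3 is None:
        from Bio.Data.IUPACData import protein_letters_3to1

        _AA3 = {k.upper(): v.upper() for k, v in protein_letters_3to1.items()}
    return _AA3.get(resname.upper(), "X")


def read_pockets_fpocket(path: str | Path) -> list[Pocket]:
    """Read an Fpocket-style pocket atom file.

    Layout: per-pocket sections opened by a ``HEADER`` line containing
    ``Pocket <n>``, followed by fixed-column PDB ``ATOM`` records of the
    pocket-lining atoms; residues are collected from the ATOM records.
    """
    path = Path(path)
    pockets: list[Pocket] = []
    rank: int | None = None
    residues: set[ResidueKey] = set()

    def flush():
        if rank is not None:
            if not residues:
                raise ScoreIOError(f"{path}: pocket {rank} has no ATOM records")
            pockets.append(Pocket(f"fpocket_{rank}", "fpocket", frozenset(residues), rank))

    with open(path) as fh:
        for line in fh:
            if line.startswith("HEADER") and "Pocket" in line:
                flush()
                rank = int(line.split("Pocket")[1].split()[0])
                residues = set()
            elif line.startswith("ATOM") and rank is not None:
                aa = _three_to_one(line[17:20].strip())
                residues.add(ResidueKey(
                    chain=line[21],
                    resnum=int(line[22:26]),
                    icode=line[26].strip(),
                    aa=aa,
                ))
    flush()
    return pockets


def read_pockets_ligsite(path: str | Path) -> list[Pocket]:
    """Read a LIGSITE-style pocket residue table.

    Layout: whitespace-separated columns ``pocket_rank chain resnum resname``,
    one lining residue per line; ``#`` comments ignored.
    """
    path = Path(path)
    by_rank: dict[int, set[ResidueKey]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ScoreIOError(f"{path}:{lineno}: expected 'rank chain resnum resname'")
            rank = int(parts[0])
            aa = _three_to_one(parts[3]) if len(parts[3]) == 3 else parts[3].upper()
            by_rank.setdefault(rank, set()).add(
                ResidueKey(chain=parts[1], resnum=int(parts[2]), icode="", aa=aa)
            )
    return [
        Pocket(f"ligsite_{rank}", "ligsite", frozenset(res), rank)
        for rank, res in sorted(by_rank.items())
    ]
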