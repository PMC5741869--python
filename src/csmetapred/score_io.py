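"""Readers and writers for residue-level score data.

The package exchanges all residue-level inputs in small tab-separated text
dialects so that heterogeneous upstream predictor outputs can be decoupled
from the consensus core:

* **score table** — header ``chain\\tresnum\\ticode\\taa\\tscore``, one scored
  residue per row; ``icode`` may be blank.
* **gold annotation** — ``chain\\tresnum\\taa``, one known catalytic residue
  per row; lines starting with ``#`` are ignored.
* **template hits** — record-oriented: a ``>template_id score`` line opens a
  hit, followed by one aligned query residue per line
  (``chain\\tresnum\\ticode\\taa``).

Residue numbering follows the author numbering of the source PDB entry
(insertion codes are part of the identity), because curated catalytic-site
annotations (CSA/MACiE style) use author numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: The 12 polar/charged amino acids (functional side chains); the complement
#: of 8 is the non-polar set.  Used both for subset ranking and for the
#: rank-score availability restriction.
POLAR_AA = frozenset("RNDCQEHKSTYW")
NONPOLAR_AA = frozenset("PFAVILMG")
STANDARD_AA = POLAR_AA | NONPOLAR_AA

#: Canonical constituent score sources of the consensus.
CANONICAL_METHODS = ("crpred", "discern", "exia2_rank", "wcn", "catsid")


class ScoreIOError(ValueError):
    """Malformed input file (carries a file/line context in the message)."""


class DuplicateResidueError(ScoreIOError):
    """The same residue key appears twice where uniqueness is required."""


@dataclass(frozen=True)
class ResidueKey:
    """Identity of one residue; the join key across all data sources.

    Parameters
    ----------
    chain : str
        Single-character chain identifier.
    resnum : int
        Author sequence number (PDB numbering, not serial position).
    icode : str
        Insertion code; empty string when absent.
    aa : str
        One-letter amino-acid code (uppercase), ``X`` if unknown.
    """

    chain: str
    resnum: int
    icode: str = ""
    aa: str = "X"

    @property
    def position(self) -> tuple[str, int, str]:
        """(chain, resnum, icode) — the sort/tie-break key."""
        return (self.chain, self.resnum, self.icode)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain}{self.resnum}{self.icode}:{self.aa}"


@dataclass
class MethodScoreTable:
    """Raw per-residue scores from one upstream method.

    ``availability`` is the set of residues the method assigned a score to;
    it always equals the key set of ``scores``.
    """

    method_id: str
    scores: dict[ResidueKey, float] = field(default_factory=dict)

    @property
    def availability(self) -> frozenset[ResidueKey]:
        return frozenset(self.scores)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class TemplateHit:
    """One template hit: a likelihood-style score and the query residues it
    aligns to the template's catalytic residues."""

    template_id: str
    template_score: float
    aligned_pairs: list[tuple[ResidueKey, str]]


@dataclass
class GoldAnnotation:
    """Known catalytic residues of one protein chain (the positive class)."""

    protein_id: str
    catalytic: frozenset[ResidueKey] = frozenset()


def _parse_residue_fields(
    chain: str, resnum: str, icode: str, aa: str, *, path: str, lineno: int
) -> ResidueKey:
    chain = chain.strip()
    aa = aa.strip().upper()
    icode = icode.strip()
    if len(chain) != 1:
        raise ScoreIOError(f"{path}:{lineno}: chain must be one character, got {chain!r}")
    if aa not in STANDARD_AA and aa != "X":
        raise ScoreIOError(f"{path}:{lineno}: unknown amino-acid code {aa!r}")
    try:
        num = int(resnum)
    except ValueError:
        raise ScoreIOError(f"{path}:{lineno}: non-integer residue number {resnum!r}") from None
    return ResidueKey(chain=chain, resnum=num, icode=icode, aa=aa)


SCORE_TABLE_HEADER = ["chain", "resnum", "icode", "aa", "score"]


def read_score_table(path: str | Path, method_id: str) -> MethodScoreTable:
    """Read one method's score table (TSV dialect, see module docstring).

    Raises
    ------
    ScoreIOError
        On a malformed header, row, or non-numeric score (message names the
        offending line).
    DuplicateResidueError
        If the same residue appears twice.
    """
    path = Path(path)
    scores: dict[ResidueKey, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return MethodScoreTable(method_id=method_id, scores=scores)
    header = [c.strip() for c in lines[0].split("\t")]
    if header != SCORE_TABLE_HEADER:
        raise ScoreIOError(f"{path}:1: expected header {SCORE_TABLE_HEADER}, got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ScoreIOError(f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}")
        key = _parse_residue_fields(*fields[:4], path=str(path), lineno=lineno)
        try:
            value = float(fields[4])
        except ValueError:
            raise ScoreIOError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from None
        if value != value or value in (float("inf"), float("-inf")):
            raise ScoreIOError(f"{path}:{lineno}: score must be finite, got {fields[4]!r}")
        if key in scores:
            raise DuplicateResidueError(f"{path}:{lineno}: duplicate residue {key}")
        scores[key] = value
    if method_id == "exia2_rank":
        bad = [k for k in scores if k.aa in NONPOLAR_AA]
        if bad:
            logger.warning(
                "%s: rank score present on %d non-polar residue(s) (e.g. %s); "
                "the rank score is defined only for the 12 polar/charged types",
                path, len(bad), bad[0],
            )
    return MethodScoreTable(method_id=method_id, scores=scores)


def write_score_table(table: MethodScoreTable, path: str | Path) -> None:
    """Write a score table in the TSV dialect (rows in residue-position order)."""
    keys = sorted(table.scores, key=lambda k: k.position)
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_TABLE_HEADER) + "\n")
        for k in keys:
            fh.write(f"{k.chain}\t{k.resnum}\t{k.icode}\t{k.aa}\t{table.scores[k]!r}\n")


def read_template_hits(path: str | Path) -> list[TemplateHit]:
    """Read a template-hit file (``>template_id score`` records)."""
    path = Path(path)
    hits: list[TemplateHit] = []
    current: TemplateHit | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                if len(parts) != 2:
                    raise ScoreIOError(f"{path}:{lineno}: expected '>template_id score'")
                try:
                    score = float(parts[1])
                except ValueError:
                    raise ScoreIOError(f"{path}:{lineno}: non-numeric template score {parts[1]!r}") from None
                current = TemplateHit(template_id=parts[0], template_score=score, aligned_pairs=[])
                hits.append(current)
            else:
                if current is None:
                    raise ScoreIOError(f"{path}:{lineno}: residue line before any '>' record")
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ScoreIOError(f"{path}:{lineno}: expected 4 tab-separated fields")
                key = _parse_residue_fields(*fields, path=str(path), lineno=lineno)
                current.aligned_pairs.append((key, key.aa))
    for hit in hits:
        if not hit.aligned_pairs:
            raise ScoreIOError(f"{path}: template {hit.template_id} has no aligned residues")
    return hits


def write_template_hits(hits: Iterable[TemplateHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(f">{hit.template_id} {hit.template_score!r}\n")
            for key, _label in hit.aligned_pairs:
                fh.write(f"{key.chain}\t{key.resnum}\t{key.icode}\t{key.aa}\n")


def catsid_residue_scores(hits: Iterable[TemplateHit]) -> MethodScoreTable:
    """Sum template scores over all hits aligning each query residue.

    Every hit contributes its template score once per query residue it aligns
    (a residue aligned more than once *within* the same hit still counts
    once); no template-score cut-off is applied.  Residues appearing in no
    alignment are absent from the table's availability.
    """
    scores: dict[ResidueKey, float] = {}
    for hit in hits:
        for key in {k for k, _ in hit.aligned_pairs}:
            scores[key] = scores.get(key, 0.0) + hit.template_score
    return MethodScoreTable(method_id="catsid", scores=scores)


def read_gold_annotation(path: str | Path, protein_id: str | None = None) -> GoldAnnotation:
    """Read a gold-standard catalytic-residue list (``chain resnum aa`` TSV).

    Repeated residues are silently de-duplicated with a logged warning.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    catalytic: set[ResidueKey] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ScoreIOError(f"{path}:{lineno}: expected 3 tab-separated fields")
            key = _parse_residue_fields(fields[0], fields[1], "", fields[2], path=str(path), lineno=lineno)
            if key in catalytic:
                logger.warning("%s:%d: residue %s listed more than once; keeping one copy", path, lineno, key)
            catalytic.add(key)
    return GoldAnnotation(protein_id=protein_id, catalytic=frozenset(catalytic))


def write_gold_annotation(gold: GoldAnnotation, path: str | Path) -> None:
    keys = sorted(gold.catalytic, key=lambda k: k.position)
    with open(path, "w") as fh:
        fh.write("# chain\tresnum\taa\n")
        for k in keys:
            fh.write(f"{k.chain}\t{k.resnum}\t{k.aa}\n")
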