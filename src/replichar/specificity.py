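"""Taxon-rank specificity of proteins from homology presence/absence.

For each protein the frequency of qualifying homologues in a focal group A
and a background group B is turned into a specificity score

    score = fA^2 / (fA + fB)

which is 1 for a protein unique to group A (fA=1, fB=0) and 0.5 for a
ubiquitous protein (fA=fB=1).  An alternative reading of the score,
fA / (2 fA + fB), is available behind a flag; reports name the formula used.
The A/B split is taken at strain, genus or family rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import HitTable, TaxonGrouping

logger = logging.getLogger("replichar")

LEVELS = ("strain", "genus", "family")

#: default homologue-qualification thresholds (orthology-search conventions:
#: e-value 0.001, identity 25%, coverage 50%)
DEFAULT_THRESHOLDS = {"evalue_max": 1e-3, "min_identity": 25.0, "min_coverage": 50.0}


@dataclass
class PresenceMatrix:
    """Boolean presence of a qualifying homologue per (protein, genome)."""

    matrix: pd.DataFrame            # index: query proteins, columns: genomes, bool
    query_to_replicon: dict[str, str]
    coverage_checked: bool = True


@dataclass
class SpecificityRecord:
    protein_id: str
    replicon_id: str
    level: str
    fA: float
    fB: float
    score: float


@dataclass
class SpecificitySummary:
    replicon_id: str
    level: str
    median: float
    q1: float
    q3: float
    n: int


def presence_from_hits(hit_table: HitTable, query_to_replicon: dict[str, str],
                       genomes: list[str] | None = None,
                       thresholds: dict | None = None,
                       focal_genome: str | None = None) -> PresenceMatrix:
    """Threshold a hit table into a presence/absence matrix.

    presence(q, g) is true iff any hit of q against a protein of g passes all
    thresholds.  Coverage is alignment_length / query_length (x100) when
    query_length is known; otherwise the coverage test is skipped with a
    warning.  A protein always counts as present in its own genome
    (``focal_genome``), since a gene is trivially encoded by its source.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    rows = hit_table.rows
    all_genomes = genomes or sorted(rows["subject_genome"].unique())
    queries = sorted(query_to_replicon)
    mat = pd.DataFrame(False, index=queries, columns=all_genomes, dtype=bool)
    coverage_checked = True
    if len(rows) == 0:
        logger.warning("presence_from_hits: no hits at all; all-false matrix")
    else:
        passing = (rows["evalue"] <= thr["evalue_max"]) & \
                  (rows["percent_identity"] >= thr["min_identity"])
        qlen = rows["query_length"]
        has_len = qlen.notna()
        if not has_len.all():
            coverage_checked = False
            logger.warning("presence_from_hits: query lengths missing for %d rows; "
                           "coverage test skipped there", int((~has_len).sum()))
        coverage_ok = pd.Series(True, index=rows.index)
        with np.errstate(invalid="ignore"):
            cov = 100.0 * rows["alignment_length"] / qlen.where(has_len)
        coverage_ok[has_len] = cov[has_len] >= thr["min_coverage"]
        passing &= coverage_ok
        hits = rows[passing]
        for q, g in zip(hits["query_id"], hits["subject_genome"]):
            if q in mat.index and g in mat.columns:
                mat.loc[q, g] = True
    if focal_genome is not None and focal_genome in mat.columns:
        mat[focal_genome] = True
    return PresenceMatrix(matrix=mat, query_to_replicon=dict(query_to_replicon),
                          coverage_checked=coverage_checked)


def specificity_score(fA: float, fB: float, formula: str = "sq") -> float:
    """Specificity of a protein from its group frequencies.

    ``formula`` "sq" gives fA^2/(fA+fB) (default), which maps a group-A-unique
    protein (fA=1, fB=0) to 1 and a ubiquitous one (fA=fB=1) to 0.5; "alt"
    gives fA/(2 fA + fB), an alternative reading kept behind this flag and
    named wherever reported.
    """
    if not (0.0 <= fA <= 1.0 and 0.0 <= fB <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    if fA == 0.0 and fB == 0.0:
        raise ValueError("specificity undefined when fA == fB == 0")
    if formula == "sq":
        return fA * fA / (fA + fB)
    if formula == "alt":
        return fA / (2.0 * fA + fB)
    raise ValueError(f"unknown formula {formula!r}")


def score_all(matrix: PresenceMatrix, grouping: TaxonGrouping, level: str,
              formula: str = "sq") -> list[SpecificityRecord]:
    """Score every protein at one taxonomic level.

    fA is the fraction of group-A genomes in which the protein is present,
    fB likewise for group B; the groups come from the grouping's focal labels
    at ``level``.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    group_a, group_b = grouping.groups(level)
    mat = matrix.matrix
    missing = [g for g in group_a + group_b if g not in mat.columns]
    if missing:
        raise ValueError(f"genomes missing from presence matrix: {missing}")
    a_block = mat[group_a].to_numpy()
    b_block = mat[group_b].to_numpy()
    fa = a_block.mean(axis=1)
    fb = b_block.mean(axis=1)
    records = []
    for i, protein in enumerate(mat.index):
        if fa[i] == 0.0 and fb[i] == 0.0:
            logger.warning("score_all: %s absent everywhere; skipped", protein)
            continue
        records.append(SpecificityRecord(
            protein_id=protein,
            replicon_id=matrix.query_to_replicon.get(protein, "?"),
            level=level, fA=float(fa[i]), fB=float(fb[i]),
            score=specificity_score(float(fa[i]), float(fb[i]), formula=formula),
        ))
    return records


def summarize_by_replicon(records: list[SpecificityRecord]) -> list[SpecificitySummary]:
    """Median and quartiles (linear-interpolation, type-7) per (replicon, level)."""
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        groups.setdefault((r.replicon_id, r.level), []).append(r.score)
    out = []
    for (rep, level), scores in sorted(groups.items()):
        if not scores:
            logger.warning("summarize_by_replicon: empty group %s/%s skipped", rep, level)
            continue
        arr = np.asarray(scores)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        out.append(SpecificitySummary(replicon_id=rep, level=level,
                                      median=float(med), q1=float(q1), q3=float(q3),
                                      n=len(scores)))
    return out


def records_table(records: list[SpecificityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.replicon_id, r.level, r.fA, r.fB, r.score) for r in records],
        columns=["protein_id", "replicon_id", "level", "fA", "fB", "score"],
    )


def summary_table(summaries: list[SpecificitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.replicon_id, s.level, s.median, s.q1, s.q3, s.n) for s in summaries],
        columns=["replicon_id", "level", "median", "q1", "q3", "n"],
    )
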