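"""Per-replicon COG-category abundance profiles and their correlation.

Each annotated gene contributes to the one-letter COG categories it carries;
a gene with k letters contributes full weight 1 to each of the k categories
(fractional 1/k weighting available behind a flag).  Percentages are over
annotated category assignments; unannotated genes are reported but excluded
from percentages by default.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_usage import CorrelationMatrix, _pairwise_matrix, spearman_rho
from .io_formats import AnnotationTable, Replicon

logger = logging.getLogger("replichar")

CATEGORY_UNIVERSE = tuple(string.ascii_uppercase)


@dataclass
class CogProfile:
    replicon_id: str
    category_counts: dict[str, float]
    n_genes_annotated: int
    n_genes_unannotated: int
    n_genes_missing: int = 0  # table ids absent from the replicon

    @property
    def total_assignments(self) -> float:
        return sum(self.category_counts.values())

    @property
    def category_percent(self) -> dict[str, float]:
        total = self.total_assignments
        if total == 0:
            return {}
        return {c: 100.0 * v / total for c, v in self.category_counts.items()}

    def percent_vector(self, categories: tuple[str, ...]) -> np.ndarray:
        p = self.category_percent
        return np.array([p.get(c, 0.0) for c in categories])


def cog_profile(replicon: Replicon, annotation_table: AnnotationTable,
                weighting: str = "full") -> CogProfile:
    """Join annotation rows to a replicon's CDS and count category letters.

    ``weighting`` is "full" (each letter of a multi-letter assignment counts
    1) or "fractional" (a k-letter gene contributes 1/k per letter).
    """
    if weighting not in ("full", "fractional"):
        raise ValueError("weighting must be 'full' or 'fractional'")
    mapping = annotation_table.as_mapping()
    replicon_genes = {c.locus_tag for c in replicon.cds_list}
    counts: dict[str, float] = {}
    n_annot = n_unannot = 0
    for gene in sorted(replicon_genes):
        if gene not in mapping:
            continue  # replicon gene missing from the table: unannotated
        letters = mapping[gene]
        if not letters:
            n_unannot += 1
            continue
        n_annot += 1
        w = 1.0 if weighting == "full" else 1.0 / len(letters)
        for ch in letters:
            counts[ch] = counts.get(ch, 0.0) + w
    n_missing = sum(1 for g in mapping if g not in replicon_genes)
    n_unannot += sum(1 for g in replicon_genes if g not in mapping)
    if n_missing:
        logger.info("cog_profile(%s): %d annotated ids not on this replicon",
                    replicon.id, n_missing)
    return CogProfile(replicon_id=replicon.id, category_counts=counts,
                      n_genes_annotated=n_annot, n_genes_unannotated=n_unannot,
                      n_genes_missing=n_missing)


def filter_display_categories(profiles: list[CogProfile],
                              min_percent: float = 1.0) -> list[str]:
    """Categories reaching ``min_percent`` in at least one profile, sorted."""
    if not (0.0 <= min_percent <= 100.0):
        raise ValueError("min_percent must be in [0, 100]")
    keep = set()
    for p in profiles:
        for c, pct in p.category_percent.items():
            if pct >= min_percent:
                keep.add(c)
    return sorted(keep)


def cog_correlation(profiles: list[CogProfile],
                    drop_unknown: bool = False) -> CorrelationMatrix:
    """Pairwise tie-aware Spearman over aligned category-percentage vectors.

    The category universe is the union of letters observed in any profile
    (category S, function unknown, retained unless ``drop_unknown``); absent
    categories fill with 0.  The result is invariant to category ordering and
    to categories absent from every profile.
    """
    universe = sorted({c for p in profiles
                       for c, v in p.category_counts.items() if v > 0})
    if drop_unknown:
        universe = [c for c in universe if c != "S"]
    if len(universe) < 3:
        raise ValueError("fewer than 3 observed categories: correlation unstable")
    vectors = {}
    for p in profiles:
        v = p.percent_vector(tuple(universe))
        if len(np.unique(v)) < 3:
            logger.warning("cog_correlation: %s has <3 distinct values", p.replicon_id)
        vectors[p.replicon_id] = v
    if len(vectors) < 2:
        raise ValueError("need at least two profiles")
    return _pairwise_matrix(vectors)


def profile_table(profiles: list[CogProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        pct = p.category_percent
        for c in sorted(p.category_counts):
            rows.append((p.replicon_id, c, p.category_counts[c], pct.get(c, 0.0)))
    return pd.DataFrame(rows, columns=["replicon_id", "category", "count", "percent"])
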