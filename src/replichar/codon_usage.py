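"""Per-replicon codon-usage tables, percentage vectors and rank correlation.

Codon usage is summarised as the percentage abundance of each of the 64
codons over all eligible CDS of a replicon; replicons are compared by
tie-aware Spearman rank correlation of those percentage vectors, so replicon
size does not dominate the comparison.  RSCU (relative synonymous codon
usage: observed count over the mean of its synonym family) is provided as a
diagnostic for rare-codon usage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Replicon

logger = logging.getLogger("replichar")

BASES = "ACGT"
#: fixed codon ordering used by every vector in this module
CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: standard genetic code, codon -> amino acid ('*' = stop)
GENETIC_CODE: dict[str, str] = dict(zip(CODONS, (
    "KNKNTTTTRSRSIIMI"
    "QHQHPPPPRRRRLLLL"
    "EDEDAAAAGGGGVVVV"
    "*Y*YSSSS*CWCLFLF"
)))

#: synonym families of the standard code (amino acid or '*' -> codons)
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    SYNONYM_FAMILIES.setdefault(_aa, ())
    SYNONYM_FAMILIES[_aa] = SYNONYM_FAMILIES[_aa] + (_codon,)


@dataclass
class CodonUsageTable:
    replicon_id: str
    counts: dict[str, int]
    total_codons: int
    n_cds_used: int
    n_cds_skipped: int
    n_ambiguous_codons: int = 0

    @property
    def empty(self) -> bool:
        return self.total_codons == 0

    @property
    def percentages(self) -> dict[str, float]:
        if self.empty:
            return {c: 0.0 for c in CODONS}
        return {c: 100.0 * self.counts[c] / self.total_codons for c in CODONS}

    def percentage_vector(self) -> np.ndarray:
        p = self.percentages
        return np.array([p[c] for c in CODONS])


@dataclass
class CorrelationMatrix:
    labels: list[str]
    rho: np.ndarray  # symmetric, unit diagonal

    def value(self, a: str, b: str) -> float:
        return float(self.rho[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)


def codon_counts(replicon: Replicon, include_stops: bool = True) -> CodonUsageTable:
    """Count codons in frame over every eligible CDS of a replicon.

    Eligible means strand-corrected, full-length (not partial) and length
    divisible by 3.  Codons containing N are skipped and counted; stop codons
    are included unless ``include_stops`` is False.
    """
    counts = np.zeros(64, dtype=np.int64)
    n_used = n_skipped = n_ambig = 0
    for cds in replicon.cds_list:
        if not cds.codon_eligible:
            n_skipped += 1
            continue
        n_used += 1
        seq = cds.nucleotide_sequence
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            idx = CODON_INDEX.get(codon)
            if idx is None:
                n_ambig += 1
                continue
            counts[idx] += 1
    if n_skipped:
        logger.info("codon_counts(%s): %d CDS skipped (partial or out of frame)",
                    replicon.id, n_skipped)
    if not include_stops:
        for stop in STOP_CODONS:
            counts[CODON_INDEX[stop]] = 0
    table = CodonUsageTable(
        replicon_id=replicon.id,
        counts={c: int(counts[i]) for i, c in enumerate(CODONS)},
        total_codons=int(counts.sum()),
        n_cds_used=n_used, n_cds_skipped=n_skipped, n_ambiguous_codons=n_ambig,
    )
    if table.empty:
        logger.warning("codon_counts(%s): no eligible CDS; table empty", replicon.id)
    return table


def spearman_rho(x_vector, y_vector) -> float:
    """Tie-aware Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x_vector, dtype=float)
    y = np.asarray(y_vector, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: Spearman rho undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _pairwise_matrix(vectors: dict[str, np.ndarray]) -> CorrelationMatrix:
    labels = list(vectors)
    n = len(labels)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = spearman_rho(vectors[labels[i]], vectors[labels[j]])
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(labels=labels, rho=rho)


def codon_correlation(tables: list[CodonUsageTable]) -> CorrelationMatrix:
    """Pairwise Spearman rho over 64-entry codon percentage vectors."""
    usable = {}
    for t in tables:
        if t.empty:
            logger.warning("codon_correlation: %s empty, excluded", t.replicon_id)
            continue
        usable[t.replicon_id] = t.percentage_vector()
    if len(usable) < 2:
        raise ValueError("need at least two non-empty codon tables")
    return _pairwise_matrix(usable)


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    RSCU(c) = count(c) / mean count over c's synonym family; families with
    zero total usage get RSCU 0 for all members.
    """
    out: dict[str, float] = {}
    for _aa, family in SYNONYM_FAMILIES.items():
        total = sum(table.counts[c] for c in family)
        if total == 0:
            for c in family:
                out[c] = 0.0
        else:
            mean = total / len(family)
            for c in family:
                out[c] = table.counts[c] / mean
    return out


def usage_long_table(tables: list[CodonUsageTable]) -> pd.DataFrame:
    """Long-format (replicon, codon, count, percent, rscu) report."""
    rows = []
    for t in tables:
        r = rscu(t)
        p = t.percentages
        for c in CODONS:
            rows.append((t.replicon_id, c, GENETIC_CODE[c], t.counts[c], p[c], r[c]))
    return pd.DataFrame(rows, columns=["replicon_id", "codon", "amino_acid",
                                       "count", "percent", "rscu"])
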