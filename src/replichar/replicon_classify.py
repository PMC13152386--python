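"""Replicon feature measurement and class assignment.

Each replicon of a multipartite genome is scored on the axes that separate
chromosomes, secondary chromosomes, chromids, megaplasmids and plasmids:
size, G+C difference from the chromosome, codon-usage and COG-profile rank
correlation with the chromosome, presence of core genes, the
replication-marker survey around its origin, and the genus-specificity of
its genes.  A small deterministic rubric then assigns exactly one class:

1. the largest replicon is the chromosome;
2. anything below ``megaplasmid_min`` (350 kb) is a plasmid;
3. a large replicon without core genes is a megaplasmid;
4. core genes + chromosome-like composition + a plasmid-type replication
   system -> chromid;
5. core genes + chromosome-like composition + a chromosomal, incomplete
   chromosomal or unidentified replication system -> secondary chromosome;
6. otherwise megaplasmid, with the conflict noted in the rationale.

"Chromosome-like composition" means delta_gc <= ``gc_tol`` and codon rho vs
the chromosome >= ``rho_min``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import Genome, Replicon

logger = logging.getLogger("replichar")

CLASSES = ("chromosome", "secondary chromosome", "chromid", "megaplasmid", "plasmid")
ORIGIN_CALLS = ("chromosomal", "plasmid", "incomplete-chromosomal", "none")

MARKER_NAMES = ("dnaA", "dnaN", "parA", "parB", "gyrA", "gyrB",
                "rep1", "rep2", "tap", "tpg")

#: name/product patterns per marker; matched case-insensitively against
#: "<locus_tag> <product>" text.  Configurable per run.
DEFAULT_MARKER_VOCABULARY: dict[str, str] = {
    "dnaA": r"\bdnaA\b|chromosomal replication initiat",
    "dnaN": r"\bdnaN\b|DNA polymerase III.*beta",
    "parA": r"\bparA\b|partition(ing)?\s+(protein\s+)?ATPase",
    "parB": r"\bparB\b|partition(ing)?\s+protein\s+B",
    "gyrA": r"\bgyrA\b|gyrase.*subunit A",
    "gyrB": r"\bgyrB\b|gyrase.*subunit B",
    "rep1": r"\brep1\b|iteron",
    "rep2": r"\brep2\b|plasmid replicative (DNA )?helicase",
    "tap": r"\btap\b|telomere[- ]associated protein",
    "tpg": r"\btpg\b|terminal protein\b",
}

DEFAULT_THRESHOLDS = {
    "megaplasmid_min": 350_000,  # bp; size bound below which a replicon is a plasmid
    "gc_tol": 1.0,               # mol% difference from the chromosome
    "rho_min": 0.9,              # codon-usage Spearman rho vs the chromosome
    "cluster_span": 5,           # genes; co-occurrence span for origin markers
    "genus_median_min": 0.5,     # genus-level specificity median for "chromosome-like"
}


@dataclass
class MarkerSurvey:
    replicon_id: str
    markers: dict[str, list[tuple[str, int]]]  # name -> [(locus_tag, position)]
    origin_call: str

    def has(self, name: str) -> bool:
        return bool(self.markers.get(name))


@dataclass
class FeatureVector:
    replicon_id: str
    size_bp: int
    size_ratio_to_chromosome: float
    delta_gc: float                    # mol% difference vs chromosome, >= 0
    codon_rho: float | None
    cog_rho: float | None
    has_core_genes: bool
    origin_call: str
    genus_specific_profile: str | None  # "chromosome-like" | "plasmid-like"
    is_chromosome: bool = False


@dataclass
class ClassLabel:
    label: str
    rationale: list[str] = field(default_factory=list)


def survey_markers(replicon: Replicon,
                   vocabulary: dict[str, str] | None = None,
                   cluster_span: int = DEFAULT_THRESHOLDS["cluster_span"]) -> MarkerSurvey:
    """Find replication/partitioning markers by annotation-text matching.

    origin_call is "chromosomal" when dnaA and dnaN co-occur within
    ``cluster_span`` genes, "plasmid" when rep1 and rep2 do, and
    "incomplete-chromosomal" when dnaN or parA is present without dnaA.
    """
    vocab = {k: re.compile(v, re.IGNORECASE)
             for k, v in (vocabulary or DEFAULT_MARKER_VOCABULARY).items()}
    markers: dict[str, list[tuple[str, int]]] = {name: [] for name in vocab}
    gene_index: dict[str, list[int]] = {name: [] for name in vocab}
    if not replicon.cds_list:
        logger.warning("survey_markers(%s): replicon has no CDS", replicon.id)
        return MarkerSurvey(replicon_id=replicon.id, markers=markers, origin_call="none")
    for gi, cds in enumerate(replicon.cds_list):
        text = f"{cds.locus_tag} {cds.product}"
        for name, pat in vocab.items():
            if pat.search(text):
                markers[name].append((cds.locus_tag, cds.start))
                gene_index[name].append(gi)

    def close(x: str, y: str) -> bool:
        return any(abs(i - j) <= cluster_span
                   for i in gene_index.get(x, []) for j in gene_index.get(y, []))

    if markers.get("dnaA") and markers.get("dnaN") and close("dnaA", "dnaN"):
        call = "chromosomal"
    elif markers.get("rep1") and markers.get("rep2") and close("rep1", "rep2"):
        call = "plasmid"
    elif (markers.get("dnaN") or markers.get("parA")) and not markers.get("dnaA"):
        call = "incomplete-chromosomal"
    else:
        call = "none"
    return MarkerSurvey(replicon_id=replicon.id, markers=markers, origin_call=call)


def build_feature_vector(genome: Genome, replicon_id: str,
                         analysis_results: dict,
                         core_gene_table: set[str] | None = None) -> FeatureVector:
    """Assemble the classification axes for one replicon.

    ``analysis_results`` carries the upstream stage outputs keyed by:
    "gc" (replicon_id -> mol%), "codon_rho" / "cog_rho" (replicon_id ->
    Spearman rho vs the chromosome; the chromosome maps to 1.0),
    "origin_call" (replicon_id -> MarkerSurvey origin_call) and optionally
    "genus_median" (replicon_id -> genus-level specificity median).
    has_core_genes is true when the replicon carries at least one core-table
    entry found on no other replicon.
    """
    rep = genome.replicon(replicon_id)
    chrom = genome.chromosome
    for key in ("gc", "origin_call"):
        if key not in analysis_results:
            raise ValueError(f"missing upstream result: {key!r}")
    gc = analysis_results["gc"]
    if replicon_id not in gc or chrom.id not in gc:
        raise ValueError("missing upstream result: gc for replicon or chromosome")
    delta_gc = abs(gc[replicon_id] - gc[chrom.id])
    codon_rho = analysis_results.get("codon_rho", {}).get(replicon_id)
    cog_rho = analysis_results.get("cog_rho", {}).get(replicon_id)
    origin_call = analysis_results["origin_call"].get(replicon_id, "none")
    genus_median = analysis_results.get("genus_median", {}).get(replicon_id)
    if genus_median is None:
        profile = None
    else:
        chromosome_like = genus_median >= DEFAULT_THRESHOLDS["genus_median_min"]
        profile = "chromosome-like" if chromosome_like else "plasmid-like"
    has_core = False
    if core_gene_table:
        other_genes = {c.locus_tag for r in genome.replicons if r.id != replicon_id
                       for c in r.cds_list}
        own = {c.locus_tag for c in rep.cds_list}
        has_core = bool((own & set(core_gene_table)) - other_genes)
    return FeatureVector(
        replicon_id=replicon_id, size_bp=rep.length,
        size_ratio_to_chromosome=rep.length / chrom.length,
        delta_gc=delta_gc, codon_rho=codon_rho, cog_rho=cog_rho,
        has_core_genes=has_core, origin_call=origin_call,
        genus_specific_profile=profile, is_chromosome=rep.id == chrom.id,
    )


def classify(fv: FeatureVector, thresholds: dict | None = None) -> ClassLabel:
    """Assign one replicon class from its feature vector (pure, deterministic)."""
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    rationale: list[str] = []
    if fv.is_chromosome:
        return ClassLabel("chromosome", ["largest replicon of the genome"])
    if fv.size_bp < thr["megaplasmid_min"]:
        return ClassLabel("plasmid", [
            f"size {fv.size_bp:,} bp below megaplasmid bound {thr['megaplasmid_min']:,} bp"])
    rationale.append(
        f"size {fv.size_bp:,} bp at or above megaplasmid bound {thr['megaplasmid_min']:,} bp")
    if not fv.has_core_genes:
        rationale.append("no core genes unique to this replicon")
        return ClassLabel("megaplasmid", rationale)
    rationale.append("carries core genes found on no other replicon")
    composition_like = (
        fv.delta_gc <= thr["gc_tol"]
        and fv.codon_rho is not None and fv.codon_rho >= thr["rho_min"]
    )
    if composition_like:
        rationale.append(
            f"chromosome-like composition (delta_gc {fv.delta_gc:.2f} <= {thr['gc_tol']}, "
            f"codon rho {fv.codon_rho:.3f} >= {thr['rho_min']})")
    else:
        detail = f"delta_gc {fv.delta_gc:.2f} mol%"
        if fv.codon_rho is not None:
            detail += f", codon rho {fv.codon_rho:.3f}"
        else:
            detail += ", codon rho not measured"
        rationale.append(f"composition unlike the chromosome ({detail})")
        rationale.append("conflict: core genes present but composition differs")
        return ClassLabel("megaplasmid", rationale)
    if fv.origin_call == "plasmid":
        rationale.append("plasmid-type replication system (rep1+rep2)")
        return ClassLabel("chromid", rationale)
    rationale.append(f"replication system: {fv.origin_call}")
    return ClassLabel("secondary chromosome", rationale)


def classification_table(features: list[FeatureVector],
                         labels: dict[str, ClassLabel]) -> pd.DataFrame:
    rows = []
    for fv in features:
        lab = labels[fv.replicon_id]
        rows.append((fv.replicon_id, fv.size_bp, f"{fv.size_ratio_to_chromosome:.3f}",
                     f"{fv.delta_gc:.2f}",
                     "" if fv.codon_rho is None else f"{fv.codon_rho:.3f}",
                     "" if fv.cog_rho is None else f"{fv.cog_rho:.3f}",
                     fv.has_core_genes, fv.origin_call,
                     fv.genus_specific_profile or "not measured",
                     lab.label, "; ".join(lab.rationale)))
    return pd.DataFrame(rows, columns=[
        "replicon_id", "size_bp", "size_ratio", "delta_gc", "codon_rho", "cog_rho",
        "core_genes", "origin_call", "genus_profile", "class", "rationale"])
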