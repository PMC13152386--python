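"""Synthetic multipartite bacterial genomes with known truth tables.

The generator emits everything the pipeline consumes — replicon sequences
with CDS features, COG annotation tables, homology hit tables, a taxon
grouping and a core-gene table — together with truth tables recording the
realised G+C, codon counts, COG counts, TIR coordinates and identity, motif
positions, marker loci, per-gene taxonomic tier, the presence/absence matrix
and the intended class label of every replicon.  All randomness flows from a
single seed; two runs with the same specs and seed are byte-identical.

What is emulated: per-replicon base composition, codon-usage bias, COG
mixtures, terminal inverted repeats with a controlled per-base divergence
(an exact count of round(rate x length) substitutions, so the realised
identity matches the nominal rate to within rounding), implanted motifs,
replication-marker cassettes and a tiered pangenome (strain-unique /
genus-core / family-core / universal genes) over a configurable synthetic
taxonomy.  What is not emulated: gene-order evolution, recombination,
sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_usage import CODONS, STOP_CODONS
from .io_formats import (AnnotationTable, CdsFeature, Genome, HitTable, Replicon,
                         TaxonGrouping, reverse_complement, write_cog_annotations,
                         write_fasta, write_genome_genbank, write_taxon_grouping)

PARS_MOTIF = "GTTTCACGTGAAAC"

TIERS = ("strain-unique", "genus-core", "family-core", "universal")

#: probability that a gene of a given tier has a qualifying homologue in a
#: genome of each taxon group (the focal genome itself is always present)
TIER_PRESENCE = {
    "strain-unique": {"genus": 0.0, "family": 0.0, "outgroup": 0.0},
    "genus-core": {"genus": 0.95, "family": 0.05, "outgroup": 0.02},
    "family-core": {"genus": 0.95, "family": 0.95, "outgroup": 0.05},
    "universal": {"genus": 0.95, "family": 0.95, "outgroup": 0.95},
}

#: synthetic taxonomy: 1 focal strain, 3 further genus genomes, 6 further
#: family genomes, 10 outgroup genomes
DEFAULT_TAXONOMY = {"n_genus": 3, "n_family": 6, "n_outgroup": 10}

_MARKER_CASSETTES = {
    "chromosomal": [
        ("dnaA", "chromosomal replication initiator protein DnaA"),
        ("dnaN", "DNA polymerase III subunit beta DnaN"),
        ("parA", "partitioning protein ATPase ParA"),
        ("parB", "partitioning protein ParB"),
        ("gyrA", "DNA gyrase subunit A"),
        ("gyrB", "DNA gyrase subunit B"),
    ],
    "plasmid": [
        ("rep1", "plasmid replication iteron protein Rep1"),
        ("rep2", "plasmid replicative DNA helicase Rep2"),
        ("parA", "partitioning protein ATPase ParA"),
        ("parB", "partitioning protein ParB"),
    ],
    "incomplete-chromosomal": [
        ("dnaN", "DNA polymerase III subunit beta DnaN"),
        ("parA", "partitioning protein ATPase ParA"),
    ],
}


@dataclass
class RepliconSpec:
    """Blueprint for one synthetic replicon."""

    id: str
    length: int
    topology: str = "linear"
    target_gc: float = 0.70
    codon_weights: np.ndarray | None = None   # 64-vector, normalised
    n_cds: int = 100
    cds_length_mean: float = 320.0            # codons
    cds_length_sd: float = 80.0
    cog_mixture: dict[str, float] = field(default_factory=dict)  # "-" = unannotated
    tir: tuple[int, float] | None = None      # (length, per-base mutation rate)
    tir_source: str | None = None             # share the TIR block of this replicon
    motifs: list[tuple[str, list[int]]] = field(default_factory=list)
    marker_cassette: str | None = None
    gene_tier_mixture: dict[str, float] = field(default_factory=dict)
    truth_label: str = "plasmid"

    def __post_init__(self) -> None:
        if self.codon_weights is None:
            self.codon_weights = codon_weights_from_gc(self.target_gc)
        self.codon_weights = np.asarray(self.codon_weights, dtype=float)
        self.codon_weights = self.codon_weights / self.codon_weights.sum()
        if not self.cog_mixture:
            self.cog_mixture = {"S": 1.0}
        if not self.gene_tier_mixture:
            self.gene_tier_mixture = {"strain-unique": 1.0}
        if self.tir is not None and self.tir[0] >= self.length / 2:
            raise ValueError(f"{self.id}: TIR length must be < length/2")


@dataclass
class TruthTables:
    gc: dict[str, float]
    codon_counts: dict[str, np.ndarray]
    cog_counts: dict[str, dict[str, int]]
    tir: dict[str, dict]                      # replicon -> coords/identity
    motifs: dict[str, list[tuple[str, int]]]
    markers: dict[str, list[tuple[str, str, int]]]  # (marker, locus, position)
    gene_tier: dict[str, str]                 # locus -> tier
    presence: pd.DataFrame                    # genes x genomes, bool
    labels: dict[str, str]
    core_genes: set[str]


@dataclass
class SyntheticDataset:
    genome: Genome
    annotation: AnnotationTable
    hit_table: HitTable
    grouping: TaxonGrouping
    query_lengths: dict[str, int]
    core_genes: set[str]
    truth: TruthTables


_N_GC = np.array([sum(b in "GC" for b in c) for c in CODONS])


def _tilt_to_gc(w: np.ndarray, target_gc: float) -> np.ndarray:
    """Exponentially tilt codon weights so their expected G+C equals target."""
    lo, hi = -20.0, 20.0
    ww = w
    for _ in range(80):
        t = (lo + hi) / 2.0
        ww = w * np.exp(t * _N_GC)
        ww = ww / ww.sum()
        if float(ww @ _N_GC) / 3.0 < target_gc:
            lo = t
        else:
            hi = t
    return ww


def codon_weights_from_gc(gc: float, jitter_seed: int | None = 7) -> np.ndarray:
    """Codon weights of an i.i.d. base model at the given G+C, with a fixed
    multiplicative jitter so different G+C values give distinct rank orders;
    the jittered weights are re-tilted so their expected G+C stays on target."""
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in CODONS])
    if jitter_seed is not None:
        jrng = np.random.default_rng(jitter_seed + int(round(gc * 1000)))
        w = w * np.exp(jrng.normal(0.0, 0.35, size=64))
    return _tilt_to_gc(w / w.sum(), gc)


def _stop_and_internal_weights(w: np.ndarray,
                               target_gc: float | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Split codon weights into internal (stop-free) and stop-codon draws.

    Removing the AT-rich stop codons lifts the G+C of the remaining mass, so
    when ``target_gc`` is given the internal weights are re-tilted back onto
    the target composition.
    """
    stop_idx = [CODONS.index(s) for s in STOP_CODONS]
    w_stop = np.zeros(64)
    w_stop[stop_idx] = w[stop_idx]
    if w_stop.sum() == 0:
        w_stop[CODONS.index("TGA")] = 1.0
    w_stop /= w_stop.sum()
    w_int = w.copy()
    w_int[stop_idx] = 0.0
    w_int /= w_int.sum()
    if target_gc is not None:
        w_int = _tilt_to_gc(w_int, target_gc)
    return w_int, w_stop


def predicted_statistics(spec: RepliconSpec,
                         taxonomy: dict | None = None) -> dict:
    """Closed-form expectations implied by a replicon spec, for use as test
    oracles: expected codon percentages (accounting for the forced start and
    stop codons), expected TIR identity, expected COG percentages and
    per-tier expected specificity frequencies/scores at each level."""
    tax = dict(DEFAULT_TAXONOMY)
    tax.update(taxonomy or {})
    w_int, w_stop = _stop_and_internal_weights(spec.codon_weights, spec.target_gc)
    k = spec.cds_length_mean
    expected_counts = (k - 2) * w_int + w_stop
    expected_counts[CODONS.index("ATG")] += 1.0
    codon_percent = 100.0 * expected_counts / expected_counts.sum()
    annotated = {c: p for c, p in spec.cog_mixture.items() if c != "-"}
    total = sum(annotated.values())
    cog_percent = {c: 100.0 * p / total for c, p in annotated.items()} if total else {}
    out = {
        "expected_codon_percent": dict(zip(CODONS, codon_percent)),
        "expected_cog_percent": cog_percent,
        "expected_gc": spec.target_gc,
    }
    if spec.tir is not None:
        out["expected_tir_identity"] = 100.0 * (1.0 - spec.tir[1])
    n_genus, n_family, n_out = tax["n_genus"], tax["n_family"], tax["n_outgroup"]
    n_b_strain = n_genus + n_family + n_out
    tier_exp = {}
    for tier, p in TIER_PRESENCE.items():
        # strain level: A = focal only
        fa_s = 1.0
        fb_s = (n_genus * p["genus"] + n_family * p["family"]
                + n_out * p["outgroup"]) / n_b_strain
        # genus level: A = focal + genus genomes
        fa_g = (1.0 + n_genus * p["genus"]) / (1 + n_genus)
        fb_g = (n_family * p["family"] + n_out * p["outgroup"]) / (n_family + n_out)
        # family level: A = focal + genus + family genomes
        fa_f = (1.0 + n_genus * p["genus"] + n_family * p["family"]) / (1 + n_genus + n_family)
        fb_f = p["outgroup"]
        tier_exp[tier] = {
            "strain": {"fA": fa_s, "fB": fb_s, "score": fa_s ** 2 / (fa_s + fb_s)},
            "genus": {"fA": fa_g, "fB": fb_g, "score": fa_g ** 2 / (fa_g + fb_g)},
            "family": {"fA": fa_f, "fB": fb_f, "score": fa_f ** 2 / (fa_f + fb_f)},
        }
    out["expected_specificity"] = tier_exp
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_CODON_ARR = np.array(CODONS)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return np.frombuffer(b"ACGT", dtype="S1")[rng.choice(4, size=n, p=probs)].copy()


def _mutate_exact(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute exactly round(rate * len) positions (each to a different base)."""
    n = len(seq)
    k = int(round(rate * n))
    if k == 0:
        return seq, 0
    positions = rng.choice(n, size=k, replace=False)
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    for p in positions:
        base = arr[p].decode()
        choices = [b for b in "ACGT" if b != base]
        arr[p] = rng.choice(choices).encode()
    return arr.tobytes().decode(), k


def _draw_genes(rng: np.random.Generator, spec: RepliconSpec,
                locus_prefix: str) -> list[dict]:
    """Sample gene lengths, strands, codon content and marker identities."""
    w_int, w_stop = _stop_and_internal_weights(spec.codon_weights, spec.target_gc)
    lengths = np.maximum(
        50, np.round(rng.normal(spec.cds_length_mean, spec.cds_length_sd,
                                size=spec.n_cds)).astype(int))
    total_internal = int((lengths - 2).sum())
    internal = rng.choice(64, size=total_internal, p=w_int)
    stops = rng.choice(64, size=spec.n_cds, p=w_stop)
    strands = np.where(rng.random(spec.n_cds) < 0.5, "+", "-")
    cassette = _MARKER_CASSETTES.get(spec.marker_cassette, [])
    marker_slots = {}
    if cassette:
        mid = spec.n_cds // 2
        for off, (marker, product) in enumerate(cassette):
            marker_slots[mid + off] = (marker, product)
        if spec.n_cds < len(cassette):
            raise ValueError(f"{spec.id}: too few CDS for marker cassette")
    genes = []
    offset = 0
    for gi in range(spec.n_cds):
        k = int(lengths[gi])
        idx = internal[offset:offset + (k - 2)]
        offset += k - 2
        codons = np.concatenate([[CODONS.index("ATG")], idx, [stops[gi]]])
        nt = "".join(_CODON_ARR[codons])
        marker, product = marker_slots.get(gi, (None, "hypothetical protein"))
        genes.append({
            "locus_tag": f"{locus_prefix}_{gi + 1:05d}",
            "codon_idx": codons, "nt": nt, "strand": str(strands[gi]),
            "marker": marker, "product": product,
        })
    return genes


def _build_replicon(rng: np.random.Generator, spec: RepliconSpec,
                    tir_blocks: dict[str, str]) -> tuple[Replicon, list[dict], dict]:
    """Assemble one replicon sequence; returns (replicon, genes, tir_truth)."""
    tir_len = spec.tir[0] if spec.tir else 0
    motif_reserve = 3000 if (spec.motifs or tir_len) else 0
    genes = _draw_genes(rng, spec, spec.id)
    gaps = rng.integers(100, 251, size=len(genes) + 1)
    gene_nt_total = sum(len(g["nt"]) for g in genes)
    needed = 2 * tir_len + motif_reserve + gene_nt_total + int(gaps.sum())
    if needed > spec.length:
        raise ValueError(f"{spec.id}: infeasible spec, needs {needed:,} bp "
                         f"but length is {spec.length:,} bp")
    seq = _random_dna(rng, spec.length, spec.target_gc)
    pos = tir_len + motif_reserve + int(gaps[0])
    for gi, g in enumerate(genes):
        nt = g["nt"]
        placed = nt if g["strand"] == "+" else reverse_complement(nt)
        seq[pos:pos + len(nt)] = np.frombuffer(placed.encode("ascii"), dtype="S1")
        g["start"] = pos + 1              # 1-based inclusive
        g["end"] = pos + len(nt)
        pos += len(nt) + int(gaps[gi + 1])
    tir_truth: dict = {}
    if spec.tir:
        rate = spec.tir[1]
        if spec.tir_source and spec.tir_source in tir_blocks:
            block = tir_blocks[spec.tir_source][:tir_len]
            left, k_left = _mutate_exact(rng, block, rate)
            seq[:tir_len] = np.frombuffer(left.encode("ascii"), dtype="S1")
        else:
            left = seq[:tir_len].tobytes().decode()
            k_left = 0
            tir_blocks[spec.id] = left
        right, k_right = _mutate_exact(rng, tir_blocks.get(spec.tir_source or spec.id,
                                                           left), rate)
        seq[-tir_len:] = np.frombuffer(reverse_complement(right).encode("ascii"),
                                       dtype="S1")
        tir_truth = {
            "left": (1, tir_len), "right": (spec.length - tir_len + 1, spec.length),
            "length": tir_len,
            "identity": 100.0 * (1.0 - (k_left + k_right) / tir_len)
            if spec.tir_source else 100.0 * (1.0 - k_right / tir_len),
            "rate": rate,
        }
    motif_truth = []
    for motif, positions in spec.motifs:
        for p in positions:
            if not (1 <= p and p + len(motif) - 1 <= spec.length):
                raise ValueError(f"{spec.id}: motif position {p} out of range")
            for g in genes:
                if not (p + len(motif) - 1 < g["start"] or p > g["end"]):
                    raise ValueError(f"{spec.id}: motif at {p} overlaps CDS "
                                     f"{g['locus_tag']}")
            seq[p - 1:p - 1 + len(motif)] = np.frombuffer(motif.encode("ascii"),
                                                          dtype="S1")
            motif_truth.append((motif, p))
    sequence = seq.tobytes().decode()
    cds_list = [CdsFeature(locus_tag=g["locus_tag"], start=g["start"], end=g["end"],
                           strand=g["strand"], nucleotide_sequence=g["nt"],
                           product=g["product"], has_translation=True)
                for g in genes]
    replicon = Replicon(id=spec.id, sequence=sequence, topology=spec.topology,
                        cds_list=cds_list)
    return replicon, genes, {"tir": tir_truth, "motifs": motif_truth}


def _make_taxonomy(taxonomy: dict) -> TaxonGrouping:
    labels = {"FOCAL": ("strain0", "genusA", "familyA")}
    for i in range(taxonomy["n_genus"]):
        labels[f"G{i + 1}"] = (f"gstrain{i + 1}", "genusA", "familyA")
    for i in range(taxonomy["n_family"]):
        labels[f"F{i + 1}"] = (f"fstrain{i + 1}", f"genusB{i + 1}", "familyA")
    for i in range(taxonomy["n_outgroup"]):
        labels[f"O{i + 1}"] = (f"ostrain{i + 1}", f"genusX{i + 1}", f"familyX{i + 1}")
    return TaxonGrouping(labels=labels, focal_genome="FOCAL")


def _genome_group(grouping: TaxonGrouping, genome_id: str) -> str:
    strain, genus, family = grouping.labels[genome_id]
    if genome_id == grouping.focal_genome:
        return "focal"
    if genus == grouping.labels[grouping.focal_genome][1]:
        return "genus"
    if family == grouping.labels[grouping.focal_genome][2]:
        return "family"
    return "outgroup"


def generate_genome(specs: list[RepliconSpec], seed: int,
                    taxonomy: dict | None = None,
                    genome_id: str = "FOCAL") -> SyntheticDataset:
    """Generate a synthetic multipartite genome with its truth tables.

    Specs are validated for feasibility before any sequence is assembled; an
    infeasible spec raises with no partial output.
    """
    tax = dict(DEFAULT_TAXONOMY)
    tax.update(taxonomy or {})
    rng = np.random.default_rng(seed)
    grouping = _make_taxonomy(tax)
    tir_blocks: dict[str, str] = {}
    replicons: list[Replicon] = []
    all_genes: list[tuple[str, dict]] = []
    truth = TruthTables(gc={}, codon_counts={}, cog_counts={}, tir={}, motifs={},
                        markers={}, gene_tier={}, presence=pd.DataFrame(),
                        labels={}, core_genes=set())
    for spec in specs:
        replicon, genes, extra = _build_replicon(rng, spec, tir_blocks)
        replicons.append(replicon)
        truth.labels[spec.id] = spec.truth_label
        truth.tir[spec.id] = extra["tir"]
        truth.motifs[spec.id] = extra["motifs"]
        counts = np.zeros(64, dtype=np.int64)
        for g in genes:
            np.add.at(counts, g["codon_idx"], 1)
        truth.codon_counts[spec.id] = counts
        seq = replicon.sequence
        g_c = seq.count("G") + seq.count("C")
        truth.gc[spec.id] = g_c / len(seq)
        truth.markers[spec.id] = [(g["marker"], g["locus_tag"], g["start"])
                                  for g in genes if g["marker"]]
        for g in genes:
            all_genes.append((spec.id, g))

    # --- annotations ------------------------------------------------------
    ann_rows = []
    for spec in specs:
        letters = sorted(spec.cog_mixture)
        probs = np.array([spec.cog_mixture[c] for c in letters], dtype=float)
        probs /= probs.sum()
        spec_genes = [g for rid, g in all_genes if rid == spec.id]
        draws = rng.choice(len(letters), size=len(spec_genes), p=probs)
        cog_count: dict[str, int] = {}
        for g, d in zip(spec_genes, draws):
            letter = letters[d]
            ann_rows.append((g["locus_tag"], "" if letter == "-" else letter,
                             g["product"]))
            if letter != "-":
                cog_count[letter] = cog_count.get(letter, 0) + 1
        truth.cog_counts[spec.id] = cog_count
    annotation = AnnotationTable(rows=pd.DataFrame(
        ann_rows, columns=["gene_id", "cog_letters", "description"]))

    # --- tiers, presence matrix, hit table, core genes --------------------
    genome_ids = list(grouping.labels)
    groups = {gid: _genome_group(grouping, gid) for gid in genome_ids}
    presence_rows = {}
    hit_rows = []
    query_lengths = {}
    for spec in specs:
        tiers = sorted(spec.gene_tier_mixture)
        tprobs = np.array([spec.gene_tier_mixture[t] for t in tiers], dtype=float)
        tprobs /= tprobs.sum()
        spec_genes = [g for rid, g in all_genes if rid == spec.id]
        tier_draw = rng.choice(len(tiers), size=len(spec_genes), p=tprobs)
        for g, td in zip(spec_genes, tier_draw):
            tier = tiers[td]
            locus = g["locus_tag"]
            truth.gene_tier[locus] = tier
            qlen = len(g["nt"]) // 3 - 1
            query_lengths[locus] = qlen
            row = {}
            for gid in genome_ids:
                grp = groups[gid]
                if grp == "focal":
                    present = True
                else:
                    present = bool(rng.random() < TIER_PRESENCE[tier][grp])
                row[gid] = present
                if present:
                    ident = 100.0 if grp == "focal" else float(rng.uniform(60, 95))
                    hit_rows.append((locus, f"{gid}|{locus}", ident, qlen,
                                     1e-50, 2.0 * qlen, qlen, gid))
                elif rng.random() < 0.3:  # decoy hit that fails the thresholds
                    ident = float(rng.uniform(5.0, 20.0))
                    hit_rows.append((locus, f"{gid}|{locus}", ident, qlen,
                                     1e-4, 0.5 * qlen, qlen, gid))
            presence_rows[locus] = row
            if tier in ("family-core", "universal"):
                truth.core_genes.add(locus)
    truth.presence = pd.DataFrame.from_dict(presence_rows, orient="index",
                                            columns=genome_ids).sort_index()
    hit_table = HitTable(rows=pd.DataFrame(
        hit_rows, columns=["query_id", "subject_id", "percent_identity",
                           "alignment_length", "evalue", "bitscore",
                           "query_length", "subject_genome"]))
    genome = Genome(genome_id=genome_id, replicons=replicons,
                    strain="strain0", genus="genusA", family="familyA")
    return SyntheticDataset(genome=genome, annotation=annotation,
                            hit_table=hit_table, grouping=grouping,
                            query_lengths=query_lengths,
                            core_genes=truth.core_genes, truth=truth)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a generated dataset as GenBank/FASTA/TSV fixture files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": out / "genome.gbk",
        "fasta": out / "genome.fasta",
        "annotations": out / "annotations.tsv",
        "hits": out / "hits.tsv",
        "grouping": out / "grouping.tsv",
        "core_genes": out / "core_genes.tsv",
        "truth_labels": out / "truth_labels.tsv",
    }
    write_genome_genbank(dataset.genome, paths["genbank"])
    write_fasta([(r.id, r.sequence) for r in dataset.genome.replicons], paths["fasta"])
    write_cog_annotations(dataset.annotation, paths["annotations"])
    hits = dataset.hit_table.rows
    with open(paths["hits"], "w") as fh:
        for _, r in hits.iterrows():
            fh.write("\t".join([
                r["query_id"], r["subject_id"], f"{r['percent_identity']:.1f}",
                str(int(r["alignment_length"])), "0", "0", "1",
                str(int(r["alignment_length"])), "1", str(int(r["alignment_length"])),
                f"{r['evalue']:.3g}", f"{r['bitscore']:.1f}"]) + "\n")
    write_taxon_grouping(dataset.grouping, paths["grouping"])
    with open(paths["core_genes"], "w") as fh:
        fh.write("#core_gene\n")
        for locus in sorted(dataset.core_genes):
            fh.write(locus + "\n")
    with open(paths["truth_labels"], "w") as fh:
        fh.write("#replicon_id\tclass\n")
        for rid, label in dataset.truth.labels.items():
            fh.write(f"{rid}\t{label}\n")
    return paths


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

CHROMOSOME_COG = {"E": 0.11, "G": 0.10, "K": 0.12, "T": 0.08, "P": 0.07,
                  "I": 0.06, "Q": 0.07, "C": 0.06, "H": 0.05, "J": 0.05,
                  "M": 0.05, "O": 0.04, "F": 0.03, "L": 0.04, "S": 0.05,
                  "-": 0.02}
PLASMID_COG = {"L": 0.25, "U": 0.14, "V": 0.12, "S": 0.28, "K": 0.08,
               "D": 0.05, "O": 0.04, "-": 0.04}

CHROMOSOME_TIERS = {"universal": 0.45, "family-core": 0.30,
                    "genus-core": 0.15, "strain-unique": 0.10}
EEC1_TIERS = {"genus-core": 0.50, "family-core": 0.20,
              "universal": 0.10, "strain-unique": 0.20}
PLASMID_TIERS = {"strain-unique": 0.90, "genus-core": 0.10}


def embleya_preset() -> list[RepliconSpec]:
    """A four-replicon genome mirroring a multipartite actinomycete at
    desk scale: a 700 kb chromosome, a 420 kb chromosome-like secondary
    replicon sharing the chromosome's 2.1 kb TIR at 5e-4 per-base
    divergence, and two small plasmids with distinct G+C (delta 2.5 and
    2.1 mol%), one of them circular."""
    chrom_w = codon_weights_from_gc(0.716)
    return [
        RepliconSpec(
            id="CHR", length=700_000, topology="linear", target_gc=0.716,
            codon_weights=chrom_w, n_cds=550, cog_mixture=dict(CHROMOSOME_COG),
            tir=(2_100, 0.0005), motifs=[(PARS_MOTIF, [2_401, 3_001, 3_601])],
            marker_cassette="chromosomal", gene_tier_mixture=dict(CHROMOSOME_TIERS),
            truth_label="chromosome"),
        RepliconSpec(
            id="EEC1", length=420_000, topology="linear", target_gc=0.716,
            codon_weights=chrom_w, n_cds=330, cog_mixture=dict(CHROMOSOME_COG),
            tir=(2_100, 0.0005), tir_source="CHR",
            marker_cassette="incomplete-chromosomal",
            gene_tier_mixture=dict(EEC1_TIERS), truth_label="secondary chromosome"),
        RepliconSpec(
            id="EEC2", length=30_000, topology="linear", target_gc=0.691,
            codon_weights=codon_weights_from_gc(0.691), n_cds=20,
            cog_mixture=dict(PLASMID_COG),
            gene_tier_mixture=dict(PLASMID_TIERS), truth_label="plasmid"),
        RepliconSpec(
            id="EEC3", length=21_000, topology="circular", target_gc=0.695,
            codon_weights=codon_weights_from_gc(0.695), n_cds=13,
            cog_mixture=dict(PLASMID_COG),
            marker_cassette="plasmid", gene_tier_mixture=dict(PLASMID_TIERS),
            truth_label="plasmid"),
    ]


def fiveclass_preset() -> list[RepliconSpec]:
    """The embleya preset extended with a chromid-like replicon (400 kb,
    chromosome-like composition and core genes, plasmid-type replication)
    and a megaplasmid-like replicon (380 kb, divergent composition, no core
    genes), so every replicon class is realised in one genome."""
    chrom_w = codon_weights_from_gc(0.716)
    mega_w = codon_weights_from_gc(0.70, jitter_seed=11)
    return embleya_preset() + [
        RepliconSpec(
            id="CHRD", length=400_000, topology="linear", target_gc=0.716,
            codon_weights=chrom_w, n_cds=310, cog_mixture=dict(CHROMOSOME_COG),
            marker_cassette="plasmid", gene_tier_mixture=dict(EEC1_TIERS),
            truth_label="chromid"),
        RepliconSpec(
            id="MEGA", length=380_000, topology="linear", target_gc=0.70,
            codon_weights=mega_w, n_cds=290, cog_mixture=dict(PLASMID_COG),
            marker_cassette="plasmid", gene_tier_mixture=dict(PLASMID_TIERS),
            truth_label="megaplasmid"),
    ]


PRESETS = {"embleya": embleya_preset, "fiveclass": fiveclass_preset}
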