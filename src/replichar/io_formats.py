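"""Readers and writers for every external format the pipeline touches.

All downstream analyses consume only the domain types defined here
(:class:`Replicon`, :class:`Genome`, :class:`AnnotationTable`,
:class:`HitTable`, :class:`TaxonGrouping`).  Coordinates are 1-based
inclusive throughout, following GenBank convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import BeforePosition, AfterPosition, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("replichar")

VALID_BASES = frozenset("ACGTN")
TOPOLOGIES = ("linear", "circular", "unknown")


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CdsFeature:
    """A protein-coding feature on a replicon.

    ``nucleotide_sequence`` is strand-corrected (read 5'->3' on the coding
    strand): for a minus-strand feature it equals the reverse complement of
    the forward-strand slice ``sequence[start-1:end]``.
    """

    locus_tag: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    nucleotide_sequence: str
    product: str = ""
    partial: bool = False
    has_translation: bool = False

    @property
    def codon_eligible(self) -> bool:
        """Usable for codon analysis: full-length and in frame."""
        return (not self.partial) and len(self.nucleotide_sequence) % 3 == 0


@dataclass
class Replicon:
    """One DNA molecule with its parsed CDS features."""

    id: str
    sequence: str
    topology: str = "linear"
    cds_list: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps the junction on circular replicons."""
        if start <= end:
            return self.sequence[start - 1:end]
        if self.topology != "circular":
            raise ValueError(f"wrapping slice {start}..{end} on non-circular {self.id}")
        return self.sequence[start - 1:] + self.sequence[:end]


@dataclass
class Genome:
    """A named set of replicons plus taxon labels."""

    genome_id: str
    replicons: list[Replicon]
    strain: str = ""
    genus: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError("replicon ids must be unique within a genome")

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    @property
    def chromosome(self) -> Replicon:
        """The largest replicon."""
        return max(self.replicons, key=lambda r: r.length)


@dataclass
class AnnotationTable:
    """Per-gene functional-category letters (eggNOG-mapper style)."""

    rows: pd.DataFrame  # columns: gene_id, cog_letters, description

    def letters_for(self, gene_id: str) -> str:
        sel = self.rows.loc[self.rows["gene_id"] == gene_id, "cog_letters"]
        return sel.iloc[0] if len(sel) else ""

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.rows["gene_id"], self.rows["cog_letters"]))


@dataclass
class HitTable:
    """Tabular homology hits plus a subject -> genome mapping."""

    rows: pd.DataFrame  # query_id, subject_id, percent_identity, alignment_length,
                        # evalue, bitscore, query_length (may be NaN), subject_genome
    n_dropped_unmapped: int = 0
    n_rejected_malformed: int = 0


@dataclass
class TaxonGrouping:
    """genome_id -> (strain, genus, family) labels with a focal genome.

    Group A/B splits per level are derived from the focal genome's labels:
    at strain level A = {focal}; at genus level A = genomes sharing the focal
    genus; at family level A = genomes sharing the focal family.  B is the
    complement in every case.
    """

    labels: dict[str, tuple[str, str, str]]
    focal_genome: str

    def groups(self, level: str) -> tuple[list[str], list[str]]:
        if self.focal_genome not in self.labels:
            raise ValueError(f"focal genome {self.focal_genome!r} not in grouping")
        idx = {"strain": 0, "genus": 1, "family": 2}[level]
        if level == "strain":
            group_a = [self.focal_genome]
        else:
            focal_label = self.labels[self.focal_genome][idx]
            group_a = [g for g, lab in self.labels.items() if lab[idx] == focal_label]
        group_b = [g for g in self.labels if g not in set(group_a)]
        if not group_b:
            raise ValueError(f"group B empty at level {level!r}: no contrast available")
        return group_a, group_b


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def _feature_to_cds(feat: SeqFeature, replicon_seq: str, replicon_id: str) -> CdsFeature | None:
    loc = feat.location
    if loc is None:
        return None
    start = int(loc.start) + 1
    end = int(loc.end)
    length = len(replicon_seq)
    if start < 1 or end > length or start > end:
        logger.warning("CDS outside sequence bounds on %s (%s..%s); feature rejected",
                       replicon_id, start, end)
        return None
    partial = isinstance(loc.start, BeforePosition) or isinstance(loc.end, AfterPosition)
    strand = "-" if loc.strand == -1 else "+"
    raw = replicon_seq[start - 1:end]
    nt = reverse_complement(raw) if strand == "-" else raw
    quals = feat.qualifiers
    locus_tag = quals.get("locus_tag", quals.get("gene", ["?"]))[0]
    product = quals.get("product", [""])[0]
    return CdsFeature(
        locus_tag=locus_tag, start=start, end=end, strand=strand,
        nucleotide_sequence=nt, product=product, partial=partial,
        has_translation="translation" in quals,
    )


def read_genome_genbank(path: str | Path,
                        topology_overrides: Mapping[str, str] | None = None,
                        genome_id: str | None = None) -> Genome:
    """Read a multi-record GenBank flat file into a :class:`Genome`.

    Topology comes from the LOCUS line when present; otherwise it defaults to
    linear (overridable per record id via ``topology_overrides``).
    """
    path = Path(path)
    overrides = dict(topology_overrides or {})
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"malformed GenBank record in {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no records in {path}")
    replicons = []
    for rec in records:
        seq = str(rec.seq).upper()
        topology = rec.annotations.get("topology", "")
        if rec.id in overrides:
            topology = overrides[rec.id]
        if topology not in ("linear", "circular"):
            topology = "linear"
        cds_list = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            cds = _feature_to_cds(feat, seq, rec.id)
            if cds is not None:
                cds_list.append(cds)
        cds_list.sort(key=lambda c: (c.start, c.end))
        replicons.append(Replicon(id=rec.id, sequence=seq, topology=topology,
                                  cds_list=cds_list))
    return Genome(genome_id=genome_id or path.stem, replicons=replicons)


def write_genome_genbank(genome: Genome, path: str | Path) -> None:
    """Write a :class:`Genome` as a multi-record GenBank flat file."""
    records = []
    for rep in genome.replicons:
        rec = SeqRecord(Seq(rep.sequence), id=rep.id, name=rep.id[:16],
                        description=f"{genome.genome_id} {rep.id}")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology if rep.topology != "unknown" else "linear"
        for cds in rep.cds_list:
            start = cds.start - 1 if not cds.partial else BeforePosition(cds.start - 1)
            loc = SimpleLocation(start, cds.end, strand=-1 if cds.strand == "-" else 1)
            quals = {"locus_tag": [cds.locus_tag]}
            if cds.product:
                quals["product"] = [cds.product]
            if cds.has_translation and cds.codon_eligible:
                quals["translation"] = [str(Seq(cds.nucleotide_sequence[:-3]).translate())]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> tuple[list[tuple[str, str]], int]:
    """Read FASTA; returns (records, n_substituted).

    Sequences are upper-cased and characters outside {A,C,G,T,N} replaced by
    N, counted in ``n_substituted``.
    """
    records: list[tuple[str, str]] = []
    n_sub = 0
    current_id: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append((current_id, "".join(chunks)))
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if current_id is None:
                    raise ParseError(f"sequence line before any header in {path}")
                cleaned = []
                for ch in line.upper():
                    if ch in VALID_BASES:
                        cleaned.append(ch)
                    else:
                        cleaned.append("N")
                        n_sub += 1
                chunks.append("".join(cleaned))
    if current_id is not None:
        records.append((current_id, "".join(chunks)))
    if n_sub:
        logger.warning("read_fasta: %d non-ACGTN characters replaced by N", n_sub)
    return records, n_sub


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation (eggNOG-mapper style) tables
# ---------------------------------------------------------------------------

#: header names under which different eggNOG-mapper versions store the
#: COG-category column
_COG_COLUMN_ALIASES = ("cog_category", "cog_cat", "cog categories", "cog")


def read_cog_annotations(path: str | Path,
                         category_column: int | None = None) -> AnnotationTable:
    """Read a tab-separated annotation table of gene id -> COG letters.

    Comment lines start with '#'.  The last such line before data is taken as
    the header and the category column located by name; ``category_column``
    (0-based) overrides this for headerless files.  A '-' category is kept as
    an empty letter set.  Duplicate gene ids are rejected.
    """
    header: list[str] | None = None
    data_rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            data_rows.append(line.split("\t"))
    if category_column is None:
        if header is None:
            raise ParseError(f"{path}: no header line and no category column given")
        lowered = [h.strip().lower() for h in header]
        category_column = next(
            (i for i, h in enumerate(lowered) if h in _COG_COLUMN_ALIASES), None)
        if category_column is None:
            raise ParseError(
                f"{path}: no COG category column in header {header!r}")
    out = []
    seen: set[str] = set()
    for row in data_rows:
        if len(row) <= category_column:
            raise ParseError(f"{path}: row with too few columns: {row!r}")
        gene_id = row[0].strip()
        if gene_id in seen:
            raise ParseError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        letters = row[category_column].strip()
        if letters == "-":
            letters = ""
        if not all(ch.isalpha() and ch.isupper() for ch in letters):
            raise ParseError(f"{path}: bad category letters {letters!r} for {gene_id}")
        desc = row[-1] if len(row) > max(1, category_column) + 1 else ""
        out.append((gene_id, letters, desc))
    df = pd.DataFrame(out, columns=["gene_id", "cog_letters", "description"])
    return AnnotationTable(rows=df)


def write_cog_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#query\tcog_category\tdescription\n")
        for _, r in table.rows.iterrows():
            letters = r["cog_letters"] or "-"
            fh.write(f"{r['gene_id']}\t{letters}\t{r['description']}\n")


# ---------------------------------------------------------------------------
# 12-column tabular homology hits
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ["query_id", "subject_id", "percent_identity", "alignment_length",
                "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
                "evalue", "bitscore"]


def read_hit_table(path: str | Path, subject_to_genome: Mapping[str, str],
                   query_lengths: Mapping[str, int] | None = None) -> HitTable:
    """Read 12-column tabular search output (blast/diamond ``-outfmt 6``).

    Rows whose subject is absent from ``subject_to_genome`` are dropped with a
    counted warning; rows with non-numeric identity/e-value are rejected and
    counted.  ``query_lengths`` optionally supplies query protein lengths for
    coverage computation downstream.
    """
    kept = []
    n_dropped = 0
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                n_rejected += 1
                continue
            try:
                ident = float(parts[2])
                alen = int(float(parts[3]))
                evalue = float(parts[10])
                bits = float(parts[11])
            except ValueError:
                n_rejected += 1
                continue
            if not (0.0 <= ident <= 100.0) or evalue < 0:
                n_rejected += 1
                continue
            subj = parts[1]
            if subj not in subject_to_genome:
                n_dropped += 1
                continue
            qlen = query_lengths.get(parts[0]) if query_lengths else None
            kept.append((parts[0], subj, ident, alen, evalue, bits, qlen,
                         subject_to_genome[subj]))
    if n_dropped:
        logger.warning("read_hit_table: %d rows with unmapped subjects dropped", n_dropped)
    if n_rejected:
        logger.warning("read_hit_table: %d malformed rows rejected", n_rejected)
    df = pd.DataFrame(kept, columns=["query_id", "subject_id", "percent_identity",
                                     "alignment_length", "evalue", "bitscore",
                                     "query_length", "subject_genome"])
    return HitTable(rows=df, n_dropped_unmapped=n_dropped, n_rejected_malformed=n_rejected)


def read_taxon_grouping(path: str | Path, focal_genome: str) -> TaxonGrouping:
    """Read a TSV of genome_id, strain, genus, family."""
    labels: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: grouping row needs 4 columns: {line!r}")
            labels[parts[0]] = (parts[1], parts[2], parts[3])
    return TaxonGrouping(labels=labels, focal_genome=focal_genome)


def write_taxon_grouping(grouping: TaxonGrouping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#genome_id\tstrain\tgenus\tfamily\n")
        for gid, (s, g, f) in grouping.labels.items():
            fh.write(f"{gid}\t{s}\t{g}\t{f}\n")


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def count_cds(replicon: Replicon, require_translation: bool = False) -> int:
    """Number of CDS features, optionally only those carrying a translation."""
    if require_translation:
        return sum(1 for c in replicon.cds_list if c.has_translation)
    return len(replicon.cds_list)


def io_stats(genome: Genome) -> pd.DataFrame:
    """Per-replicon id, length, topology, CDS count."""
    return pd.DataFrame(
        [(r.id, r.length, r.topology, count_cds(r)) for r in genome.replicons],
        columns=["replicon_id", "length", "topology", "n_cds"],
    )
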