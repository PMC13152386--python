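# Methods

This note documents the models, procedures and numerical choices behind
`replichar`: what each stage computes, the tunable parameters and their
defaults, what the synthetic-genome generator does and does not emulate, and
the known limitations.

## Domain model and coordinates

A *genome* is a set of *replicons* (DNA molecules with declared linear or
circular topology), each carrying parsed CDS features.  Coordinates in every
report are 1-based inclusive on the forward strand (GenBank convention).
CDS nucleotide sequences are strand-corrected (read 5'→3' on the coding
strand).  Topology is read from the GenBank LOCUS line; when the record is
silent it defaults to *linear*, the prevailing topology of replicons in the
Streptomycetaceae, and can be overridden per record.  CDS whose length is
not a multiple of 3 and are not flagged partial are kept for counting but
excluded from codon analysis, preventing frameshifted annotations from
polluting codon tables; exclusions are reported.

## Composition and GC skew

Whole-replicon G+C is (G+C)/(A+C+G+T), with N and other ambiguity codes
excluded from numerator and denominator, reported as mol% (×100).

Sliding-window profiles report per-window G+C and GC skew
(G−C)/(G+C), with skew defined as 0 for windows without G or C so the
cumulative series stays total.  Defaults: window 10,000 bp, step 5,000 bp —
fine enough to localise features at ~0.1 Mb resolution, coarse enough for
desk-scale plots.  Windows wrap the junction on circular replicons; the
trailing short window of a linear replicon is kept and flagged.  Under this
sign convention the cumulative-skew minimum falls near the replication
origin of genomes with leading/lagging-strand bias and the maximum near the
terminus; ties break to the smallest window centre.  No DnaA-box scoring or
other formal oriC prediction is attempted.

Plateau segmentation labels maximal runs of windows by skew sign; runs of at
least `min_run` windows (default 10) with |skew| below `slope_threshold`
(default 0.02) are labelled plateaus, shorter near-zero runs are absorbed
into their neighbours by mean sign.  Note the sampling noise of per-window
skew is ≈ 1/√(G+C count per window); plateau calls on small windows need a
proportionally larger threshold.

## Codon usage

Codon tables count codons in frame over every eligible CDS (full-length, in
frame, strand-corrected); codons containing N are skipped and counted.
Stop codons are counted by default (a toggle excludes them), since summary
percentage plots conventionally include them.  Replicons are compared by
tie-aware Spearman rank correlation (scipy's implementation: Pearson on
average ranks) over the 64-entry *percentage* vectors, not raw counts, so
replicon size does not dominate.  RSCU — a codon's count over the mean count
of its synonym family under the standard genetic code, 0 for unused
families — is an added diagnostic for rare-codon usage and is labelled as
such in reports.

## COG profiles

Annotation tables are eggNOG-mapper-style TSV (gene id, category letters;
'-' = unannotated; the category column is located by header name, with an
override for headerless files; duplicate gene ids are rejected).  A gene
with k category letters contributes weight 1 to each (a fractional 1/k mode
exists behind a flag).  Percentages are over annotated category assignments;
unannotated genes are reported but excluded from the denominator.  Category
S (function unknown) is retained in correlation by default, with a flag to
drop it.  Inter-replicon correlation is the same tie-aware Spearman over
category-percentage vectors aligned on the union of categories observed
(count > 0) in any profile, absent categories filled with 0 — making the
result invariant to category order and to globally absent categories.

## Terminal inverted repeats and end homology

TIRs are conventionally established by manual inspection and alignment of
contig ends; `replichar` instead uses a deterministic seed-and-extend
procedure on the two inward reads of a linear molecule (the sequence itself, and the reverse complement
of the full sequence, so both start at a terminus):

1. **Seed** — an exact match of `seed_len` (default 100) bases between the
   two reads, within the first `max_scan` (default 10,000) bases of each,
   choosing the smallest combined offset.  At divergences above ~2% a
   shorter seed (e.g. 24) is appropriate, since 100-base exact runs become
   rare.
2. **Extend** — banded global unit-cost alignment (match 0, mismatch/indel
   1; band width default 50) grown inward in chunks; extension stops when
   identity over the trailing `window` (default 1,000) aligned columns
   falls below `min_identity` (default 95%).
3. **Trim** — the kept alignment ends at the column of maximal cumulative
   score, where a match scores +1 and a mismatch −q/(1−q) with
   q = min_identity/100 (indels one point worse).  A stretch at exactly the
   identity threshold is score-neutral, genuine repeat columns score
   positive, and optimally banded-aligned *random* sequence — which on
   skewed base composition reaches ~60% identity by chasing matches with
   indels — scores strongly negative, so the boundary sits at the end of
   the true repeat rather than drifting into background.  A final greedy
   pass re-claims literal matching bases just beyond the trim, since
   chunk-boundary indels can displace the last repeat column.

Identity is column-wise — matches/(matches+mismatches+indels)×100 — i.e.
indels count as differences; every report carries the full column
bookkeeping.  Shared end homology between two replicons uses the same
machinery on any pair of ends (right ends are reverse-complemented so both
reads run inward).  Detection is reflection-symmetric up to one or two
columns when substitutions sit exactly on the repeat edge (the two
orientations may trim a terminal mismatch column differently).

The boundary of a repeat whose tail locally degrades to background-level
identity is intrinsically ambiguous; on repeats at the length scale the
biology shows (tens of kb) this edge effect perturbs reported identity by
well under 0.1 points.

Motif scanning is a Hamming-distance scan of both strands; palindromic
motifs (equal to their reverse complement, like the parS site
GTTTCACGTGAAAC) are scanned once on the forward strand and flagged.  Dot
plots list exact shared k-mers (k ≥ 8) on forward and reverse-complement
channels, downsampled deterministically (every n-th point) above
`max_points`, with the full count reported.

## Replication-marker survey

Markers (dnaA, dnaN, parA, parB, gyrA, gyrB, rep1, rep2, tap, tpg) are
found by case-insensitive regular-expression matching against locus tag and
product text — annotation matching, not profile-HMM search — with a
configurable vocabulary.  The origin call is *chromosomal* when dnaA and
dnaN co-occur within `cluster_span` genes (default 5), *plasmid* when rep1
(iteron) and rep2 (replicative helicase) do, *incomplete-chromosomal* when
dnaN or parA is present without any dnaA, else *none*.  Precedence follows
that order.

## Taxon-rank specificity

A 12-column tabular homology search against labelled target proteomes is
thresholded into a presence/absence matrix: presence requires e-value
≤ 0.001, identity ≥ 25% and query coverage ≥ 50% (standard orthology-search
settings; all three exposed as flags).  Coverage is alignment_length /
query_length when query lengths are known, otherwise that test is skipped
with a warning.  A protein always counts as present in its own genome, so
strain-level f(A) ≡ 1 for the focal strain's proteins.

The specificity score is f(A)²/(f(A)+f(B)), where f(A) and f(B) are the
fractions of group-A and group-B genomes containing a qualifying homologue.
It lies in [0,1], is 1 for a group-A-unique protein, 0.5 for a ubiquitous
one, strictly increasing in f(A) and strictly decreasing in f(B).  The
source rendering of this equation is typographically ambiguous; the squared
numerator reading is the default because it yields a [0,1] score with the
natural boundary values, and the alternative reading f(A)/(2·f(A)+f(B)) is
available behind a flag, with every report naming the formula used.
Groups: strain level A = the focal genome; genus level A = all genomes
sharing the focal genus; family level A = all genomes sharing the focal
family; B is always the complement and must be non-empty.  Per-replicon
summaries report median and quartiles using linear-interpolation (type-7)
quantiles, stated in output metadata.

Running the homology search itself, and reciprocal-best-hit orthology
clustering, are out of scope: the module's contract is thresholding and
scoring of an existing hit table.

## Classification rubric

Feature axes per replicon: size (bp and ratio to the chromosome = largest
replicon), ΔG+C versus the chromosome (mol%), codon-usage ρ and COG ρ
versus the chromosome, presence of core genes (≥ 1 entry of a user-supplied
core-gene table carried by this replicon and no other — core-gene inference
such as BUSCO is out of scope), the marker-survey origin call, and a
genus-specificity profile ("chromosome-like" when the genus-level median
score is ≥ 0.5, else "plasmid-like"; recorded in the report, not used by
the decision rules).

Decision ladder (pure and deterministic given the thresholds):

1. largest replicon → **chromosome**;
2. size < `megaplasmid_min` (350,000 bp, the conventional bound) →
   **plasmid**;
3. no core genes → **megaplasmid**;
4. core genes + chromosome-like composition (ΔG+C ≤ `gc_tol`, default
   1.0 mol%, *and* codon ρ ≥ `rho_min`, default 0.9) + plasmid-type origin →
   **chromid**;
5. core genes + chromosome-like composition + chromosomal, incomplete-
   chromosomal or unidentified origin → **secondary chromosome**;
6. otherwise **megaplasmid**, with the conflict stated in the rationale.

The literature argues these distinctions qualitatively; the numeric
thresholds here (`gc_tol`, `rho_min`, `cluster_span`) are this package's
own operationalisation, are exposed in the run config, and are echoed into
every report.  Codon ρ versus the chromosome serves as the proxy for
"codon usage bias" since no standard scalar metric is established for the
rubric.  Raising `rho_min` can only move labels away from the chromid /
secondary-chromosome classes, never toward them.

## Synthetic data generator

The generator emulates, per replicon: intergenic DNA i.i.d. at a target
G+C; CDS drawn codon-by-codon from a 64-entry weight vector (start codon
forced to ATG, one stop drawn from the stop-codon weights at the end);
COG letters drawn per gene from a category mixture ('-' = unannotated);
TIRs built by copying the left terminus onto the reverse-complemented right
terminus with **exactly** round(rate × length) substitutions, so realised
divergence matches the nominal rate to within rounding; motifs implanted at
stated positions (validated against CDS overlap); marker cassettes written
as named CDS at the replicon midpoint; and a tiered pangenome
(strain-unique / genus-core / family-core / universal) realised as a
presence matrix over a synthetic taxonomy (defaults: 1 focal strain, 3
further genus genomes, 6 further family genomes, 10 outgroup genomes) with
per-tier presence probabilities, from which a hit table is emitted whose
rows pass the specificity thresholds exactly where the truth matrix says
present (plus decoy rows that fail them).  The hit table is generated from
the presence truth rather than by real alignment: the specificity module's
contract is thresholding and scoring, not searching.  Core genes are the
locus tags of family-core and universal-tier genes.  All randomness flows
from one seed; identical seeds give byte-identical outputs.

Codon weight vectors derive from an i.i.d. base model at a chosen G+C with
a fixed multiplicative log-normal jitter (so different G+C values give
distinct rank orders, as pure i.i.d. models would not), exponentially
re-tilted so the expected G+C of the weights — and again of the stop-free
internal weights, since removing the AT-rich stop codons would otherwise
lift coding G+C — sits on the target.  Whole-replicon realised G+C lands
within ~0.1 mol% of target (the forced ATG and terminal stop contribute a
small AT excess).

`predicted_statistics` returns the closed-form expectations these
constructions imply — expected codon percentages (accounting for the forced
start/stop), COG percentages, TIR identity 100·(1−rate), and per-tier
expected f(A), f(B) and specificity scores at each level — for use as test
oracles.

The **embleya preset** is a desk-scale (≈1:10) model of a four-replicon
actinomycete genome: 700 kb linear chromosome and 420 kb linear secondary
replicon at G+C 0.716 sharing a 2.1 kb TIR at 5×10⁻⁴ per-base divergence
(the secondary replicon carrying dnaN/parA without dnaA, i.e. an incomplete
chromosomal origin, and genus-core-dominated gene tiers), plus a 30 kb
linear and a 21 kb circular plasmid at G+C 0.691/0.695 with plasmid-like
COG mixtures and strain-unique genes; three parS sites are implanted on the
chromosome only.  The sizes keep the secondary replicon above and the
plasmids below the absolute 350 kb megaplasmid bound, which an evenly
scaled-down genome would not.  The **fiveclass preset** adds a 400 kb
chromid-like replicon (chromosome-like composition, core genes, rep1/rep2
origin) and a 380 kb megaplasmid-like replicon (divergent composition, no
core genes), so all five classes are realised in one genome.

What the generator does *not* emulate: gene-order evolution, recombination,
horizontal transfer, sequencing error, annotation error beyond the decoy
hit rows.  Passing tests therefore demonstrate that the measurements and
the rubric recover the constructs' known structure at realistic effect
sizes and scales — not that the thresholds are optimal for any particular
real genome.

## Problem sizes used in tests

The default suite runs entirely on generated data: the shared fixture is
one embleya-preset genome (≈1.17 Mb, ~900 CDS); the class-recovery check
runs 20 seeded five-class replicates (≈1.9 Mb each) through the full
pipeline; statistical recoveries use 200 replicates of 10 kb sequences
(G+C), 1,000 random 64-vectors (Spearman oracle), and a four-rate
divergence sweep on 21 kb repeats.  The acceptance script uses the same
scales with 10 five-class replicates.

## Known limitations

* Marker detection trusts annotation text; unannotated or renamed
  replication genes produce origin call *none* (treated as "unidentified",
  which the ladder maps with core genes and chromosome-like composition to
  secondary chromosome).
* TIR boundaries on heavily diverged repeats are ambiguous where the repeat
  tail locally matches background identity; reported identity is over the
  detected columns.
* The classifier's thresholds operationalise qualitative literature
  distinctions; borderline replicons (ΔG+C near 1 mol%, ρ near 0.9) should
  be read with the printed rationale, not the label alone.
* Spearman over 64 codons or ~20 COG categories has substantial sampling
  noise below ~10⁴ codons or ~10³ annotated genes per replicon; empty or
  tiny replicons are excluded with warnings rather than scored.
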