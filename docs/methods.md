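# Methods

## Pseudogene screening

A COI amplicon from a functional mitochondrial gene translates without
internal stop codons in its coding frame. The screen translates the three
forward frames (optionally also the three reverse-complement frames) under
the vertebrate mitochondrial genetic code (NCBI table 2: TGA = Trp,
ATA = Met, AGA/AGG = stop) and passes a query iff at least one examined
frame has zero internal stops. A stop in the final translated residue is
not internal; codons containing N translate to X and never count as stops;
trailing Ns are stripped before screening, so the verdict is invariant
under uninformative padding. Reverse frames are off by default, matching
amplicons oriented by directional primers. Failing queries are excluded
from matching but written to a `pseudogene_flagged.fasta` side channel —
nothing is silently dropped.

**Known blind spot.** A frameshift within roughly 50 codons of either
amplicon end leaves too few scrambled codons to hit a stop by chance
(≈ 0.06 per shifted codon under uniform sense-codon usage), so one forward
frame stays clean and the screen passes the sequence. This is inherent to
translation-based screening, not an implementation artefact; the synthetic
generator therefore places its pseudogene deletions at least 150 nt from
each end so that injected contamination is of the detectable kind.

## Matching and thresholds

Queries are aligned semi-globally (global alignment with free end gaps on
both sequences) with match +1, mismatch −1, gap open −2, gap extension
−0.5; a length-L gap costs `open + (L−1)·ext`, and an end gap is free only
while one sequence has not yet started or is already exhausted. Identity is
matches over all columns between the first and last aligned pair (internal
gap columns included — stated explicitly because conventions differ);
coverage is the percentage of the query inside that span. Cutoffs are
strict: a hit needs identity > 97 and coverage > 80 at species level. Hits
tied for the best identity after rounding to 2 decimals form the top tie
set, which avoids float noise splitting genuinely identical references.

When nothing clears the species cutoffs a configurable rank ladder retries
at genus (90/80), family (85/80) and order (80/80). These sub-species
thresholds are this package's own stand-in for how shallower
single-database assignments arise in practice; they are not published
values and are fully configurable per database.

Because the exact affine aligner costs ~8 ms per 630-nt pair, an
edit-distance prefilter (edlib, infix mode) discards references whose
approximate identity is more than 5 points below the laxest threshold in
use; the exact aligner runs on the survivors. On hierarchically generated
references the prefilter is conservative by a wide margin;
`prefilter=False` forces exact alignment of every pair, and a test asserts
both modes agree on the clean fixture.

## Consensus and the hierarchical final assignment

Per query, the two database verdicts reconcile as:

1. both silent → **unassigned**;
2. a best-hit tie spanning ≥2 species on either side → **ambiguity**,
   recorded at the child of the tie's lowest-common-ancestor rank (a
   congeneric tie is an ambiguity *at species level*), resolved to the tie
   LCA; both sides ambiguous → tie sets are unioned first (the most
   conservative reading);
3. only one database speaks, or one reaches strictly deeper along the same
   lineage → that database's **single-db** category at its rank (a
   species-level identification is not demoted because the other database
   stopped at the genus);
4. same rank, same taxon → **concordance**;
5. otherwise → **discrepancy**, recorded at the deeper of the two ranks,
   resolved to the LCA of the two taxa.

The final rank keeps the category rank for concordant and single-database
cases and promotes discrepancy/ambiguity one rank up (order-level conflicts
stay at order, flagged). For a discrepancy whose two taxa share no genus
the LCA can sit more than one rank above the category rank; the final taxon
is then the LCA and the final rank its actual rank. The tally recomputes
the final-assignment vector independently from the category × rank matrix
and cross-checks it against the per-query finals. Percentages are reported
half-up to one decimal.

## Distances, trees, bootstrap

K2P distance: with transition proportion P and transversion proportion Q
over unambiguous shared sites, `d = −½·ln((1−2P−Q)·√(1−2Q))`; sites with N
or a gap in either sequence are excluded, and a non-positive logarithm
argument raises a saturation error rather than returning NaN. K2P is the
conventional barcoding distance; the tree is a verification device here, so
no model selection is attempted.

Neighbour joining follows the Saitou–Nei agglomeration with the usual
Q-criterion; ties break on the smallest (i, j) index pair, and negative
branch-length estimates are clamped to zero with the deficit moved to the
sister branch, so trees are deterministic and nonnegative. On additive
matrices the implementation reproduces the generating tree's path-length
matrix to 1e-9 (tested, and cross-checked against scikit-bio's NJ).

Bootstrap support resamples alignment columns with replacement, rebuilds
K2P + NJ per replicate, and reports for each internal edge of the full-data
tree the percentage of completed replicates containing its bipartition
(bipartitions are compared unrooted). Replicates hitting saturation are
skipped and counted. Assignments are verified by conspecific monophyly:
query and reference leaves of one species should form a clade.

Trees serialise to newick via scikit-bio, with integer supports as internal
node labels. The writer encodes spaces as underscores and decodes them on
read, so spaced labels round-trip; labels containing literal underscores
would not, and the synthetic generator avoids them.

## Cost model

Visual identification is strictly per-individual: Σ count(s) ×
minutes(s), with species-specific diagnosis times (10–15 min for the five
reference myctophids). Barcoding is per-individual tissue sampling (2 min)
plus per-batch DNA extraction (15 min) and PCR preparation (30 min),
amortised over ⌈n/96⌉ thermocycler batches. The hourly technician rate is
an input whose default is *derived*, not asserted: the 335-min reference
visual workload is priced at €60.50 of labour, giving ≈ €10.84/h; both
published totals (visual €90.5, barcoding ≈ €169 with consumables at €1
and €5 per individual) follow from that single shared rate, which makes
the pair a consistency check. Totals are rounded to 2 decimals only at the
end. The per-individual labour crossover (barcoding cheaper from n ≈ 5
under the defaults) is exposed as `labour_crossover`.

## Synthetic surveys

The generator's defaults mirror a desk-scale survey: 44 species, 237
queries of 630 nt (a typical edited COI amplicon length), eight stations on
a 37°N → 2°S transect with 200–600 m³ filtered per haul, complete and
concordant databases, query divergence 0.005 substitutions/site with
transition/transversion ratio κ = 4, and no pseudogene contamination.
Stress is opt-in: per-database completeness, congener label conflicts
(discrepancies), verbatim duplicate sequences under a second congeneric
name (ambiguities), and frameshifted pseudogene queries.

Reference sequences evolve hierarchically down the taxonomy: a root drawn
codon-wise from the 60 sense codons of the mitochondrial code, then
stop-free two-parameter substitutions along order/family/genus/species
branches (0.06/0.05/0.04/0.03 expected substitutions/site). This keeps
congeners ≈ 94 % identical (so the 97 % cutoff separates species while the
90 % genus rung still fires), keeps all distances below K2P saturation so
trees are computable, and guarantees every reference passes the pseudogene
screen. Independent uniform draws per species would put inter-species
identity near 25 % — saturated distances, no rank fallback ever, and a
biologically meaningless tree. A rejection step regenerates any species
within 95 % raw identity of an existing one. The public `mutate_sequence`
applies an exact count `round(divergence·L)` of substitutions at distinct
uniform positions (transition probability κ/(κ+2)), which makes its
statistics analytically checkable; the generator's internal variant
additionally avoids creating frame-0 stops, because genuine amplicons come
from functional genes.

What the generator does **not** emulate: codon-position rate heterogeneity,
indel evolution beyond the single pseudogene deletion, amplification or
sequencing error, and real per-station species pools (station assignment is
uniform; a latitudinal gradient in community composition is out of scope).
Passing tests therefore demonstrate the pipeline's logic — thresholds,
reconciliation, conservation of records, determinism — not robustness to
every artefact of real chromatogram data.

## Reproducibility and problem sizes

One global seed fans out to per-stage seeds by fixed offsets; identical
configs give byte-identical outputs, and the run manifest records versions,
seeds, per-stage counts and SHA-256 digests of every file. The test suite
exercises the full pipeline at 500 queries / 100 species / 100 bootstrap
replicates (~1.5 min on one core) and uses 20-seed averages at 24 queries /
8 species for the ambiguity-degradation curve; these sizes were chosen to
keep the whole suite in the minutes range while leaving every statistical
assertion comfortably clear of its threshold.
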