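# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates, strands and the data model

All coordinates are 1-based inclusive (the GenBank and printed-table
convention); conversions are internal. Strands are called *major* (the
strand the genome sequence is written on; "F" in feature tables) and
*minor* ("R") — the heavy/light nomenclature is avoided because its
mapping to sequence orientation varies between papers. A feature that
spans the origin of the circular molecule is represented with
`end > genome_length`, which lets a printed table cell like
"14,999–15,370 on a 15,369 bp genome" be stored verbatim; the wrap is
resolved only when sequence is extracted. Gene names are normalized to a
controlled vocabulary on read (ND1 → nad1, COI → cox1, 16S → rrnL, …);
unknown names are accepted but flagged.

`validate_annotation` never raises: it returns records for
coordinate-vs-declared-size disagreements, out-of-bounds features,
origin-spanning features that collide with the first feature, and
deviations from the canonical 13 PCG / 22 tRNA / 2 rRNA / 1 control
census. Printed tables do contain such internal inconsistencies (the
shipped reference table has a gene whose declared size differs from its
coordinate span by 4 bp, and another by 1 bp); the package's policy is to
represent the table verbatim and report the anomaly rather than silently
repair it.

## Composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C); the value is
undefined (reported as null) when the denominator is zero. Because the
total cancels, counts and percentages of the same sequence give the same
skew. N characters count toward length but are excluded from every
percentage denominator. Partition statistics are computed on the
concatenation of each feature's **gene-strand (sense)** sequence in table
order — the convention under which published per-class skew tables are
internally consistent — with a `partition_strand="major"` switch for the
alternative; the whole-genome row is always the major strand. Overlapping
genes contribute their full spans to their class (so class sizes match
sums of per-gene sizes). Rounding is half-up, 2 decimals for percentages
and 3 for skews, and happens only at presentation; all arithmetic is done
unrounded.

One caveat discovered while validating against the shipped 17-species
table: two printed whole-genome GC-skew cells differ by exactly 0.001
from the skew of the same row's printed percentages (the original authors
evidently computed from unrounded counts). The shipped table keeps the
printed values; the test suite asserts the documented 0.001 discrepancy
for those two cells rather than pretending either number is wrong.

## Codon usage

The invertebrate mitochondrial code (translation table 5) is taken from
Biopython's codon tables: 62 sense codons, stops TAA/TAG. Start codons
are classified canonical iff they match AT[ACGT]; anything else (e.g. a
CGA start on cox1-like genes) is reported verbatim. Stop classification
is purely arithmetic on CDS length mod 3: 0 with terminal TAA/TAG →
complete; 1 with terminal T or 2 with terminal TA → incomplete
(polyadenylation-completed); anything else → unresolved, which is a value
rather than an error. The census counts start codons (they are sense
codons; a switch excludes them), sends complete stops to a separate
tally, drops incomplete remnants, and raises on internal in-frame stops
naming the gene and codon position.

RSCU uses the standard observed-over-family-mean definition with the
Leu1/Leu2 and Ser1/Ser2 split; families with zero total usage yield null
for every member rather than zero (0/0 is not "unused bias"). Amino-acid
ranking sorts descending by family total with alphabetical, flagged
tie-breaks.

## Architecture (junction ledger and gene order)

Gap = `next.start − prev.end − 1`. Ledger summaries exclude junctions
touching the control region and the single wrap junction by default,
matching how published overlap/spacer censuses are tallied (the control
region's intergenic cell is conventionally printed as "—"); both
exclusions are switchable. A verbatim mode substitutes a table's declared
intergenic column for the coordinate-derived gaps, so a printed column
can be reproduced even at a junction where it disagrees with its own
coordinates by 1 bp; the coordinate-derived ledger is the default and the
disagreement surfaces in tests rather than being resolved.

Gene-order comparison builds circular adjacency sets (unsigned by
default; a signed variant treats a strand flip as a change) and counts
adjacencies present in the observed order but not the reference. This
breakpoint count is rotation-invariant and symmetric for equal gene sets.
The ancestral insect arrangement ships as a plain-text signed gene list.

## tRNA cloverleaf folding

The folder is a constrained exhaustive search, not a thermodynamic
model: every admissible boundary vector (acceptor stem 6–7 pairs, D stem
0–4 with ≥3 nt loop — or a 4–14 nt bare loop when the stem is absent —
anticodon stem fixed at 5 with a 7 nt loop, variable region ≤9 nt, T stem
2–5, 3–12 nt loops, ≤3 nt spacers/trailer) is scored with Watson–Crick
pairs +2, G·U wobble +1, tolerated in-stem mismatch −1, and the maximum
is returned. The search space for 60–80 nt is well under 10^5 vectors;
per-stem score memoization keeps a fold around 50–100 ms. Ties break to
the lexicographically smallest boundary vector, so refolding is
bit-identical. Rationale for enumeration over free-energy minimization:
reproducibility, no energy-parameter dependency, and the downstream
outputs (wobble and mismatch censuses, DHU-loop calls, anticodon
location) depend only on the pairing diagram. Mismatches are tolerated
inside stems at a penalty rather than forced into bulges, which is how
in-stem mismatches are counted in descriptive mitogenome work. T is
treated as U for pairing; a structure whose best acceptor stem has fewer
than six non-mismatch pairs is flagged non-cloverleaf but still returned.
The anticodon is read at loop positions 3–5 and decoded as the
translation of its reverse complement under table 5.

## Control-region scanners

Motif search is exact substring scanning (overlaps allowed, optional
reverse-complement). Poly-tracts are maximal single-base runs, default
minimum 10 nt — long enough to exclude ordinary A+T-rich texture while
keeping an undimensioned "poly-A element" detectable. Microsatellites are
maximal perfect repeats with a primitive 1–6 nt unit and ≥5 copies; the
reported phase is the lexicographically smallest unit rotation achievable
without losing a copy (so an AT-repeat is never reported as (TA)n).
Tandem-repeat detection compares the region against itself shifted by
each candidate period p ≥ 10: a p-window with ≥90% matches seeds a
repeat, the best-identity window in each qualifying stretch is extended
outward through exact matches only, and overlapping reports are merged
keeping the highest identity. Identity is ungapped — there is no indel
model, so a repeat interrupted by an insertion is seen as two repeats.
A planted perfect duplication is therefore reported with identity exactly
1.0, which the tests rely on.

## Phylogeny

The 13 PCGs are concatenated in a fixed genome-order gene list, sense
strand, incomplete-stop remnants trimmed to whole codons. Per-gene
sequences must be equal-length across taxa — the synthetic generator
guarantees this; real data must be aligned externally (alignment is
deliberately out of scope). Distances: p (mismatch fraction over mutually
unambiguous columns), JC69 = −(3/4)ln(1 − 4p/3), K2P =
−(1/2)ln((1 − 2P − Q)√(1 − 2Q)). Saturated pairs whose log argument is
nonpositive are flagged and assigned the maximum defined distance + 1 so
tree building can proceed. Neighbor joining is the standard Saitou–Nei
Q-criterion agglomeration with a deterministic tie-break (the
lexicographically smallest pair of cluster labels, a cluster labelled by
its alphabetically first leaf); negative branch lengths are clamped to
zero with a note. NJ is exact on additive matrices, which the tests
verify against independently constructed random additive trees. Bootstrap
support resamples alignment columns with replacement, seeded. A full
maximum-likelihood search is intentionally not reimplemented; NJ with
bootstrap is the desk-scale, testable stand-in, and trees are exchanged
as Newick via dendropy.

## The synthetic-data generator

The generator emulates the *structure* a lepidopteran mitogenome
characterization assumes — it makes no attempt at realistic mutation
spectra or strand-asymmetric replication bias. Defaults: a ~15.4 kb
genome at 80% A+T with the published-like gene order (derived
trnM-trnI-trnQ block first), published-like gene lengths, a planted 7 bp
atp8/atp6 overlap, a CGA start on cox1, incomplete stops (T on cox1 and
cox2, TA on nad4), arm-by-arm-constructed tRNAs with ten planted G·U
wobbles and one U·U acceptor mismatch in trnA, a loop-only DHU arm in
trnS1, and a 372 bp control region carrying an ATAGA motif, an 18 nt
poly-T run, an (AT)8 microsatellite and a 12 nt poly-A element at the
trnM-proximal end, with optional planted exact duplications for
tandem-repeat tests.

Choices worth recording:

* **Codon draws.** PCG bodies are drawn i.i.d. from sense codons with
  weight ∝ (A+T fraction of the codon)^γ, γ = 3. The exponent was chosen
  from the closed-form expectation of the weighting: γ = 3 gives ~80%
  A+T in coding sequence, consistent with the ~78–80% printed partition
  compositions and the 80% genome-wide target (γ = 2 yields only ~74%,
  which cannot reach the genome target given PCGs are ~72% of the
  genome). The AT-rich two-codon families (Asn, Ile, Lys, Phe, Tyr,
  Leu2, Met) dominate the amino-acid ranking as a consequence, not by
  fiat.
* **Published-length adjustments.** Two printed PCG lengths are
  incompatible with their printed complete TAA stops (length ≢ 0 mod 3);
  the generator uses the nearest consistent lengths (1743 and 939) so its
  own annotation validates cleanly. Likewise one printed tRNA size is 1
  bp off its coordinate span; the generator's declared sizes always equal
  the spans.
* **Overlaps.** Only the atp8/atp6 overlap is planted by default: the
  downstream gene's frame takes precedence in the shared window (the
  upstream gene's tail is overwritten and the draw retried until its stop
  remains intact and stop-free in frame). Other published overlaps
  involve tRNA 3′ ends, which the shared-sequence convention would
  corrupt and unfold; those junctions default to 1 bp spacers instead.
* **tRNA construction.** Stems are planted at maximal lengths (acceptor
  7, D 4, anticodon 5, T 5) so no alternative geometry can out-pair the
  planted one; spacer and discriminator positions are fixed to A so
  shifted geometries cannot recruit them into chance pairs; the
  loop-only D region of trnS1 is a poly-A tract, which cannot pair with
  itself. Each tRNA is verified by refolding at generation time and
  redrawn if any alternative decomposition ties or wins — "foldable by
  construction" is checked, not assumed. In the score-degenerate
  loop-D case the planted boundaries are the lexicographically smallest
  admissible split, matching the folder's tie-break.
* **Control region.** Planted features are separated by single G/C guard
  bases so each is maximal exactly as planted; filler is drawn at 94%
  A+T and redrawn (deterministically, from the same seeded stream) if it
  spawns a second motif occurrence, a competing ≥10 nt poly-tract, or a
  competing (AT)≥8 repeat. Shorter homopolymer runs are left in place as
  natural texture.
* **Tree mode.** A root genome is evolved along a user-given Newick tree
  under unconstrained Jukes–Cantor substitution on all sites (per branch
  of length d, each site substitutes with probability (3/4)(1 −
  e^(−4d/3))); annotation coordinates are preserved (no indels). Coding
  constraints are deliberately ignored so that distance-recovery tests
  have a known model.

Everything is drawn from one `numpy` generator seeded by `SimParams.seed`;
identical parameters reproduce the genome, annotation and ground truth
byte-exactly.

**What passing tests do and do not show.** The generator's sequences are
i.i.d. draws with planted structure: they have no codon autocorrelation,
no selection, no strand-asymmetric compositional gradients, no
length variation between homologous genes, and control-region filler is
memoryless. Tests passing on this material demonstrate that the scanners,
folder, ledgers and tree methods compute their definitions correctly and
recover what was planted; they do not demonstrate annotation accuracy on
real genomes, where gene boundaries are uncertain and structures are
shaped by selection.

## Problem sizes in the test suite

The suite runs synthetic genomes at full size (~15.4 kb), folding checks
on 200 single-tRNA fixtures plus naive-enumeration cross-checks on a
handful of 60–70 nt sequences, scanner brute-force comparisons on 200
random regions of 60–500 nt, NJ exactness on 6–10-taxon additive
matrices, and bootstrap at a few dozen replicates on 4-taxon families —
sizes at which every independent oracle (quadratic scanners, full
enumeration, closed forms) is itself fast and trustworthy.

## Known limitations

* Annotation is an input (or synthetic); there is no similarity-search
  gene finder.
* The folder models the cloverleaf geometry only — no free energies, no
  covariance models; structures with genuinely long variable arms
  (serine tRNAs in some lineages exceed the 9 nt bound) need widened
  `FoldParams`.
* The tandem-repeat scanner has no indel model and reports ungapped
  identity only.
* The phylogeny stage assumes pre-aligned, equal-length homologs and
  implements distance methods only.
* GenBank output is a minimal flat-file subset (LOCUS/FEATURES/ORIGIN
  with gene/note qualifiers), not a full submission-grade record.
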