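# Methods

`plastomics` implements a comparative chloroplast-genome analysis of the
kind used to characterize a small plant clade — here modeled on the
Meliaceae (mahogany family) study system: a five-taxon target clade
compared against successively broader outgroup tiers (other Sapindales,
other rosids, other land plants).  Four stages operate on standard
formats (FASTA, GenBank flat files, gapped-FASTA alignments, Newick):
quadripartite structure delineation, an alignment-based variant census,
hierarchical clade-diagnostic SNP discovery in barcode genes, and a
distance-based phylogeny.  A synthetic-plastome generator with planted
ground truth makes every stage testable without downloading data.

## Quadripartite structure

Land-plant plastomes are circles of roughly 120–170 kb carrying two
inverted repeats (IRa, IRb; ~25–27 kb) that separate a large and a small
single-copy region (LSC, SSC).  `detect_inverted_repeats` finds the
maximal pair of disjoint intervals where one equals the reverse
complement of the other:

- **Seeding.** Exact 25-mer matches between the sequence and its reverse
  complement.  For one repeat pair the sum of the two copy start
  coordinates is constant, so all seeds of a pair (from both copies)
  fall on a single anti-diagonal; seeds are binned by that sum and the
  densest bins examined.  k-mers occurring more than ten times are
  skipped to keep low-complexity sequence from inflating the seed set.
- **Extension.** From the anchored seed the pairing is extended outward
  base by base.  Internal mismatch runs of at most `bridge` bp
  (default 10) are absorbed when followed by at least 25 matching bases,
  so the two copies may differ by a few substitutions, as real IR copies
  do.  `bridge` also caps the indel displacement tolerated when
  re-anchoring.
- **Circularity.** The scan is repeated on the sequence rotated by half
  its length and the longer repeat wins; coordinates are mapped back to
  the input frame.  Repeats shorter than `min_len` (default 1000 bp)
  give an explicit no-IR result, since genuine IR loss occurs in some
  lineages and must not be an exception.

`partition_plastome` labels the longer inter-IR arc LSC and the shorter
SSC; IRb is the copy adjacent to the LSC end, giving the canonical
reading LSC → IRb → SSC → IRa with the LSC start rotated to position 1.
All coordinates in the package are 1-based inclusive (the GenBank
convention).  Border-gene classification calls a gene
`duplicated_complete` when at least two copies within 95% of the longest
copy's length exist with one touching an IR; a shorter second copy is
`duplicated_partial` (the rps19 situation at the IR/LSC junction, where
IR expansion decides between a complete and a truncated second copy).
The 95% cut is a numeric stand-in for the complete/incomplete dichotomy
and tolerates annotation fuzz.

## Variant census and diversity profile

The census is defined against a strict-majority consensus of the input
multiple alignment: per column, the consensus is the most frequent base
among non-gap characters (alphabetical tie-break); columns where gaps
outnumber every base carry no consensus coordinate.  A consensus
position is *variable* when at least one sample differs from the
consensus base there; a sample gap at such a position is an indel-type
state, and a multi-column gap counts one variable position per column.
`N` and missing data never trigger a variant; other IUPAC ambiguity
codes count as mismatches but are excluded from allele sets.  Terminal
gap runs are alignment end-trimming artifacts: they are masked as
missing data (`?`) and never counted as indels.  These rules are a
from-scratch, documented semantics — published SNP-pipeline totals
obtained with other tools (and other aligners) are context, not targets.

Window profiles count variable positions in non-overlapping 10 kb tiles
of the consensus (last tile short) and rank the top windows.  Indel
events are maximal per-sample gap runs of ≥ 50 bp, reported at the
consensus coordinate of the first deleted column; runs sharing identical
breakpoints across samples are grouped into one event with a carrier
list, and flanking gene names are attached when a reference annotation
is supplied.

Pairwise global alignment uses match +1 / mismatch −1 and affine gap
costs with open 10 and extension 1 — a gap of length *g* costs
10 + *g*·1, and end gaps cost the same as internal ones.  Progressive
alignment (guide order from 6-mer Jaccard distances, profile–profile
merging under the same scorer) is offered for gene-scale input only; a
hard 5 kb per-sequence guard directs whole-plastome users to supply a
precomputed alignment rather than pretending to reproduce the output of
a genome-scale aligner.

## Clade-diagnostic SNP discovery

The hierarchical barcode scan follows plant two-locus barcoding practice
(matK/rbcL):

1. **Candidates.** In a grouped gene alignment, every consensus column
   where all target-clade samples share one base that differs from the
   base of every first-tier outgroup sample.  A gap, `N` or ambiguity
   code in any target sample disqualifies the column (a documented
   choice); outgroup gaps contribute no allele but do not disqualify.
2. **Validation.** Each candidate is checked in an extended target-clade
   alignment (coordinates transferred through a shared reference
   sample).  Any discordant unambiguous base demotes the candidate to
   `dropped_polymorphic`; partial sequences contribute no allele at
   columns they do not cover, and the observed allele counts are kept as
   the evidence trail (minority alleles with carrier counts).
3. **Tiered specificity.** A candidate is `specific` only when its
   target allele is absent from the union of all outgroup tiers' allele
   sets.  An empty tier is uninformative: it is flagged and the verdict
   withheld rather than silently counting as specific.  The rule is
   monotone — enlarging any tier's allele set can only demote.
4. **Codon effect.** For specific sites inside a CDS, codon index
   ⌈pos/3⌉ and position-in-codon, with amino acids under the
   plastid/bacterial genetic code (translation table 11).

User-supplied gene FASTAs of mixed orientation are auto-corrected by
12-mer similarity against the reference (higher in the reverse frame →
reverse complemented).

`plastomics.examples` carries a compact worked example in exactly this
report shape — a 16-row family-level matK survey with extended-set
minority counts and three tier allele sets — on which the rule yields
four family-specific positions (consensus 346, 1318, 1478, 1494); the
site at consensus 1318 / gene position 1270 falls on the first position
of codon 424.  One instructive row: position 861 shows a single first-
tier allele yet fails, because the rosid tier carries the target allele
— the tiers, not the first contrast alone, decide specificity.

## Phylogeny

Distances are p-distances with pairwise deletion of non-ACGT sites,
corrected under Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p); p ≥ 0.75 is a
saturation error, not a number.  Topologies come from Saitou–Nei
neighbor joining with deterministic tie-breaking (row-major minimum of
the Q matrix) and negative branch lengths clamped to zero.  Support is
the percentage of 100 column-bootstrap replicates containing each
non-trivial bipartition of the full-data tree; supports are attached to
bipartitions rather than nodes to avoid rooting ambiguity, replicates
where some pair has no comparable (or a saturated) site are discarded
and logged, and the Newick renderer hides supports below 70% — the usual
display convention.  An alignment of identical sequences yields a
degenerate star with supports reported as undefined.

A full maximum-likelihood topology search is deliberately not attempted:
the package substitutes NJ for the search and Felsenstein-pruning
log-likelihood under JC (uniform base frequencies, single rate, complete
deletion of gapped columns) for ranking fixed topologies.  Both halves
are exactly specified and independently verifiable — NJ against additive
matrices, the likelihood against brute-force summation over internal
states — which a heuristic search with unpublished internals is not.
Under pure JC a transition/transversion parameter is inert, so none is
exposed.

## Synthetic data generator

`simulate_study` produces the full study system with known truth:

- **Genome.** LSC + IRb + SSC + IRa with IRa the reverse complement of
  IRb; i.i.d. uniform base composition (a neutral default).  Defaults
  LSC 86 kb / IR 27 kb / SSC 18 kb (≈158 kb) match the study scale.  The
  first/last bases of each single-copy segment are adjusted so chance
  complementarity cannot extend the planted repeat, keeping the planted
  partition exactly the maximal repeat pair.  The annotation plants one
  gene straddling the LSC/IRb junction with a truncated IRa copy
  (rps19-like), a gene fully duplicated in both IRs, an intron-bearing
  tRNA whose 2535 bp intron hosts a matK-like CDS, a plain CDS, and a
  pseudogene fragment at the IRa/SSC border.
- **Clade.** A ladderized five-taxon target clade nested in three
  outgroup tiers of five taxa (tier stem depths 0.02/0.04/0.08
  substitutions/site; within-clade edges 0.005) — chosen once to emulate
  family-level plastome divergence, where a few percent of sites vary
  within the target clade and barcode-gene divergence grows with tier
  depth.  Substitution is Jukes–Cantor: per edge of length d each site
  changes with probability (3/4)(1 − e^(−4d/3)) to a uniform alternative
  base.  After evolution IRa is overwritten with revcomp(IRb) in every
  genome (concerted IR evolution, as gene conversion maintains in real
  plastomes).
- **Planting.** 16 clade-diagnostic sites (the scale of a family-level
  barcode survey) at monomorphic positions: all target taxa receive a
  transversion of the background allele, so the target allele is absent
  from every outgroup by construction.  Deletions relative to the
  ancestor: by default a 199 bp deletion shared by four of five targets
  plus 120 bp and 60 bp exclusive deletions, all in the LSC — mirroring
  the observed pattern of shared and exclusive large deletions in
  intergenic regions.  Deletions never overlap planted sites or each
  other.  Insertions are out of scope.  Because only deletions relative
  to the ancestor occur, the true alignment is known exactly (ancestor
  coordinates with gap runs), and is emitted alongside the sequences.
- **Extended set.** 100 additional target-clade individuals at 0.002
  substitutions/site from one target taxon, standing in for the
  ~100-sequence GenBank pulls used for candidate validation.  Real pulls
  are mostly partial and strand-mixed; the generator's are full-length,
  so coverage handling and orientation correction are exercised by
  dedicated fixtures instead.
- **Randomness.** One integer seed expands into independent per-stage
  streams (structure, evolution, site planting, indel planting, extended
  set), so adding a stage never perturbs an earlier one and identical
  configurations are byte-identical.

What passing on synthetic data does *not* show: the generator has no
rate heterogeneity, no base-composition bias, no microsatellite slippage
or small indels, no IR boundary shifts between taxa, and its alignment
is the true one rather than an estimate — so results on real data
additionally depend on aligner quality, and census totals from real
pipelines are not comparable exactly.

## Problem sizes and numerics

The bundled analysis scripts run the generator at the full ~158 kb /
20-taxon scale (about half a minute end to end); the test suite uses
14–17 kb genomes with the same architecture, 100 bootstrap replicates
where support levels are asserted, and oracle comparisons at the sizes
where enumeration is exact (alignments ≤ 8 bp, trees ≤ 5 leaves,
additive matrices ≤ 8 taxa).  Monte-Carlo checks of the JC machinery use
2–3 standard-error bands at fixed seeds.  Floating-point comparisons of
closed forms use 1e−9 absolute tolerance; alignment scores are exact to
rounding.  Known limitations: the IR detector reports boundaries to the
base only when copies end cleanly (a substitution within 25 bp of a
junction can shorten the detected repeat by up to that distance); the
progressive aligner is for genes, not genomes; and `duplicated_complete`
requires an IR-overlapping copy, so tandem duplications outside the IRs
are not distinguished from partial ones.
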