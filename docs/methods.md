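# Methods

This note records the models, conventions and design choices behind
locuskit, in the order a user meets them.

## Coordinates and conventions

All coordinates are 1-based inclusive internally, and gene-internal
positions count from the ATG (position 1 = the A of the start codon),
because that is how breakpoints and codon positions are reported in
amplicon work. BED export converts to 0-based half-open; GFF3 and VCF stay
1-based. SNP-density bins are half-open `[start, start + bin)`, anchored at
the region start; a variant exactly on a boundary belongs to the bin that
opens there.

## Pairwise alignment and discriminating sites

Paralogs are aligned globally with affine gap costs: match +1, mismatch −1,
the first base of a gap −4, each further base −1 (Biopython's
`PairwiseAligner`; the first alignment of its deterministic enumeration is
taken). At ≥97% identity this scoring makes substitution columns strictly
cheaper than gap pairs, so the discriminating-site list is stable; the
independent dynamic-programming oracle in the test suite checks the score
under the identical cost model. Columns containing N in either sequence
are never discriminating. Region labels (e.g. Exon1/Intron/Exon2) are
intervals on sequence A — the "parent A" frame a hybrid is later mapped
against. Identity percent is computed over columns where both sequences
have a base.

## Chimera mapping

A hybrid is aligned to parent A, each discriminating site read through the
alignment, and assigned state A, B, novel (matches neither) or uncallable
(gap/N). Novel sites are point mutations, not template switches: they are
reported but excluded from segmentation. The A/B state sequence is
segmented with the minimal number of switches (for directly observed states
this is the count of adjacent changes); each switch yields a
breakpoint-uncertainty interval between the flanking informative sites, in
hybrid-ATG coordinates, whose `junction_count = first_b_pos − last_a_pos`
counts candidate inter-base junctions. The alternative "strictly interior
bases" convention (`− 1`) is rejected because the candidate junction after
the last A-matching base is attainable while the positions of the sites
themselves are not interior. Patterns A…B…A or B…A…B set a gene-conversion
flag; more than 2 switches is flagged complex. A hybrid covering fewer than
half of the site positions is refused as truncated.

Deletion sizes come from two routes that must agree: `primer_span −
amplicon_length` for a fusion amplicon, and the ATG-to-ATG genomic distance
of the two recombining copies from the annotation. Protein consequences
translate the coding sequences under the standard code; a difference at
coding position p lies in codon `ceil(p / 3)` and is synonymous when the
two codons translate identically.

## Digital PCR

Concentration per chamber is the Poisson occupancy estimate
λ = −ln(1 − k/n). Single-channel 95% bounds apply the same transform to a
Clopper–Pearson (exact beta-quantile) interval for k/n — conservative and
well-defined at k = 0 (one-sided) and k = n (saturated: λ and the upper
bound are reported as not-a-number, only the lower bound is meaningful).
The copy ratio λ_target/λ_ref gets its CI by the delta method on the
log-ratio, var(ln λ̂) ≈ p/(n(1−p)λ²), treating the channels as independent
panels. These are standard constructions for partition-based PCR; the test
suite calibrates them by simulation (bias < 2%, empirical CI coverage
92–98% at ratios 1, 2 and 11 with n = 10,000 chambers, λ_ref = 0.5).
Replicate panels are summarised by the linear-interpolation median and
quartiles, 1.5×IQR whiskers, and outlier flags; the aggregate CI is the
median of per-replicate bounds (a deliberate, simple choice — replicate
scatter, not a pooled likelihood, is the relevant uncertainty here).
Copy numbers are reported per single reference copy with no ploidy
doubling, so a ratio of ~11 reads directly against 12 annotated copies.
The simulator's panel default is 770 chambers (a typical digital array),
overridable everywhere.

## Coverage model and deletion calling

Reads are not simulated as sequences. Coverage is generated directly from a
uniform multimap-allocation model: single-copy positions carry
`mean_depth` where they survive and 0 inside deletions; positions in family
genes carry `mean_depth × S/C`, where C counts the reference copies in the
gene's identity-sharing group (connected components under pairwise identity
≥ `multimap_identity_threshold`, default 0.95) and S the surviving copies,
a chimera counting once. This preserves the two signatures real aligners
produce over such loci — unique genes in a deletion lose all reads, family
genes only dim — without bundling an aligner. Noise is a per-base gamma
multiplier with mean 1 and CV² = `noise_dispersion` (default 0.05, a
realistic depth CV for high-coverage resequencing; 0 gives the exact
expectation). Tracks are on the `count × 10⁶ / total reads` scale.

Deletion calling anchors on unique genes: a gene is "low" when its mean
depth falls below `zero_fraction` (default 0.05) of the track-wide median;
every maximal run of `min_unique` (default 2; 1 for single-gene hunts)
consecutive low unique genes becomes a call spanning first-to-last
supporting gene, extended outward to the midpoints toward the flanking
non-low unique genes or track edges. The family-gene depth inside the call
relative to outside is reported as corroboration; note that under uniform
allocation all reference copies dim equally, so this fraction is ~1 when
the surviving copies still share reads genome-wide, and NaN when every
family copy lies inside the call. Calls with ≥2 supporting genes (or one
gene plus a clearly reduced fraction < 0.75) are "strong", others "weak".

## Variant simulation and classification

Variant tables are planted with Poisson counts per kb — `background_rate`
outside and `block_rate` inside a configured introgression block — at
unique sorted positions with random ref/alt pairs. `simulate_variant_pair`
plants an exact directional overlap: table B keeps `round(f·|A|)` of A's
records verbatim and replaces the rest at fresh positions. Variant sharing
is directional (A's records are the denominator; an empty denominator is
vacuously 100%), matching on (position, alt). SNPs and small indels are one
category. Region classification by variant load uses `low_max = 200` /
`high_min = 800` by default, separating a recurrent-parent background (tens
of variants per 400-kb window) from an introgressed donor block (>1,000)
with wide margins on both sides; both thresholds are explicit parameters.

## The synthetic locus and its preset

`build_locus` draws a random background genome, one random template per
gene family (exon1/intron/exon2 = 180/125/990 bases by default — an
arrangement in which gene position 719 is coding position 594, codon 198),
and each family member as the template with i.i.d. planted substitutions at
rate `per_site_divergence / 2` per member (transition:transversion weight
2:1), so two members differ at about the configured rate. Truth is not the
mutation plan but a direct position-by-position recount of the emitted
member sequences, so downstream site enumeration can be tested for exact
equality. Mirror clusters copy their source block wholesale and
reverse-complement it, making inverted-repeat arms exactly identical in
ATG orientation; nothing else may intrude on a mirrored block's span.

The `i-i-allele` preset lays out a 250,000-bp genome with 12 family copies:
a donor copy at 70,000, four tandem copies, a 27-kb inverted repeat (two
~10.9-kb three-gene arms around a unique central gene), and a
same-orientation acceptor copy whose ATG sits exactly 138,092 bases
downstream of the donor's, with eight unique genes in between and expressed
unique genes (subtilisin/epimerase upstream, galactosidase downstream)
flanking the deletable span close enough that midpoint extension keeps
reciprocal overlap with the planted interval above 0.9.

`apply_nahr` supports same-strand pairs only (opposite-orientation NAHR
forms an inversion and is out of scope, as are duplication-forming events
and read-level FASTQ simulation). The chimera is donor prefix through the
junction plus acceptor suffix; the deleted interval length equals the
ATG-to-ATG distance for every junction, and parent length = mutant length +
deletion length exactly. Features wholly inside the deletion vanish;
non-participant features partially overlapping the breakpoint (none in the
preset) are dropped rather than truncated.

The stand-in paralog pair `synthetic_chs_pair` is a constructed object,
labelled synthetic: it plants the published difference layout of a real
chalcone-synthase paralog pair (4/21/19 sites per region, sites at ATG
positions 578, 719 and 1061 with empty gaps between, the synonymous Phe
codon at coding 594, three amino-acid differences, a stop-codon
difference) into random sequence. Analyses on it exercise the full
alignment/classification pipeline; they do not reproduce the deposited
sequences themselves.

## What the simulator does and does not show

Passing tests demonstrate correctness of the algorithms against exact
planted truth under the stated models: gap-free equal-length paralogs,
uniform multimap allocation, Poisson partition loading, i.i.d. variant
placement. Real data add length polymorphism between paralogs (gapped
alignments), non-uniform aligner behaviour near repeat edges, chamber
volume variation, and variant-calling filters — none of which the
simulator emulates. Results on simulated data therefore validate the
inference machinery, not instrument- or aligner-specific behaviour.

## Problem sizes

The default test suite and the acceptance script run the statistical
checks at: 1,000 simulated chimeras on the 1,295-base template, 50 seeded
250-kb locus simulations for deletion recovery, 500 digital-PCR replicates
per ratio at 10,000 chambers, 100 seeded paralog pairs for site-enumeration
equality, and 1-Mb variant tables — sizes chosen so each check has
negligible Monte-Carlo ambiguity while the whole suite completes in well
under a minute of compute.
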