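# Methods

## Data model and coordinates

A genome is a `GenomeRecord`: an uppercase A/C/G/T/N sequence, a circular
flag, and a flat list of typed features (CDS, rRNA, tRNA, smallRNA,
pseudogene).  Anything flagged `/pseudo` in a source annotation is classed
pseudogene regardless of its original key, with the key preserved in a
qualifier.  Coordinates are 0-based half-open internally; all report
writers emit 1-based inclusive coordinates (BED writers stay 0-based
half-open, as the format requires).  Ambiguity codes other than N are
rejected at parse; N is carried but excluded from GC numerators and
denominators, from substitution calls and from identical-position counts.

Every position of a genome belongs to exactly one partition class.
Overlaps resolve by precedence coding > rna > pseudogene; the remainder is
IGR.  Gene density is (coding + rna)/length.  This makes stratified GC an
exact mixture: Σ class_length × class_GC = genome_length × overall_GC,
which the tests assert to 1e-9.

## Genome profiling

Codon usage tallies complete, in-frame, N-free CDS; the terminal codon goes
to the stop tally when it is a stop, and CDS with internal stops are
excluded and reported by name.  The per-amino-acid bias test asks whether
the observed codon counts within a synonymous family are uniform: Pearson
χ² when all expected counts are ≥ 5, otherwise an exact multinomial test
(sum of outcome probabilities ≤ that of the observation).  The default
significance level is 0.01.  Families with one codon or zero counts are
untestable.  A calibration test plants uniform families and checks the
type-I rate stays within 3σ binomial of α.

Amino-acid profiles are frequencies over the translated proteome
(bacterial code; alternative initiators rendered Met; stops dropped), and
the display ranking orders amino acids by the mean G+C fraction of their
synonymous codons, ties broken alphabetically.

## Strain-pair alignment and variant calling

Two strains of the same endosymbiont differ by ~10⁻⁴ substitutions per
site, so a general-purpose aligner is unnecessary.  The aligner finds all
k-mers unique in both genomes (default k = 31), merges co-diagonal runs
into maximal anchors, and chains anchors greedily longest-first (leftmost
on ties) with overlap trimming — two maximal anchors flanking an indel can
overlap by a few bases on different diagonals, and trimming (rather than
rejecting) the shorter one keeps the chain gap-free.  Inter-anchor
segments are closed by exact affine-gap global alignment (Gotoh; match +1,
mismatch −2, gap open −4, gap extend −1; a gap of length L costs
open + L·extend), jit-compiled for the occasional multi-kilobase segment
that a duplicated region leaves without unique anchors.  If no usable
chain exists the aligner raises a "not collinear" error instead of
returning a partial alignment; genuinely rearranged genomes are out of
scope.  A property test asserts that the anchored alignment's score equals
an independent full-matrix Gotoh optimum on random near-identical pairs.

Runs of gap columns on one side become single indel events; a run mixing
both sides splits at the boundary.  Indels are left-normalized (shifted to
the lowest equivalent position) and stored VCF-style with an anchor base,
so homopolymer-context calls are deterministic.  Classification labels
substitutions as transition/transversion and by direction read A→B —
GC→AT (strain B holds the A/T base), AT→GC (strain A holds it), A↔T, G↔C —
so the symmetric "GC↔AT" share and the per-strain AT-gain split fall out of
the counts.  Partition labels come from strain A's partition.

## Indel sequence context

Homopolymers are maximal single-base runs ≥ 6 nt (the threshold used
throughout), scanned on the deposited strand only; A-runs and T-runs are
tallied separately and summed for "A/T" figures.  Microsatellites are
maximal tandem tracts of 2–8 nt motifs with ≥ 2 copies and ≥ 6 bp total,
reported once with the smallest motif.  An indel is homopolymer-context
iff its allele consists solely of the run base and it lies inside or
immediately abuts a qualifying run; microsatellite-context iff its allele
is an integer stack of motif copies inside or abutting a tract; otherwise
other.  Homopolymer takes precedence.  Because variants are
left-normalized upstream, every equivalent placement classifies
identically (tested by enumerating placements).

## Selection (NG86)

Orthologs are paired by locus name; equal-length pairs are zipped codon
by codon, length-mismatched pairs get a conservative prefix/suffix codon
alignment whose unanchored middle is gapped out, and codon columns with
gaps, N, or stop codons are dropped and counted.  Genes that fall out of
frame (e.g. after a frameshift in one strain) are excluded.  Sites: each
codon position contributes syn/(non-stop changes); mutations to stops
count as no site; site totals average the two sequences, so S + N = 3 ×
codons exactly.  Differences: codon pairs differing at d positions average
the synonymous/non-synonymous step counts over all d! orderings whose
intermediates avoid stops; if every pathway hits a stop the pair is
skipped and reported.  pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected;
p ≥ 3/4 raises an explicit error.  ω = dN/dS, undefined (None) when
dS = 0.  The "±" values are standard errors from a seeded bootstrap over
codon columns (default 1000 replicates).  Concatenation across genes is
the default; per-gene tallies are available.

## Repeats

`find_exact_repeats` reports every maximal exact pair ≥ min_len (default
1000 bp), both orientations, sorted length-descending, with pairs wholly
contained in a longer reported pair (same orientation, both copies)
suppressed.  Inverted pairs are canonicalized left-copy-first and
self-overlapping configurations (e.g. loopless palindromes, whose maximal
extension overlaps itself) are not reported.  The implementation contract
is output equality with a per-diagonal brute force, enforced on ~1000
random sequences; the seed-and-extend indexing is an implementation
detail.  IR-flanked regions are inverted pairs with arms ≥ min_arm whose
interior is positive and at most max_region (default 50 kb); overlapping
candidates resolve longest-arm-first.  The reported region is the
interior between the arms; arm coordinates are reported alongside.

## tRNA inventory vs codon demand

Translational demand is the total count of sense codons over all
functional CDS — the x-axis a comparative panel needs and the quantity the
demand regression uses.  Inventories count functional tRNA genes per
anticodon (pseudo-tRNAs tallied separately, never in totals; unresolvable
anticodons stay in the total but are flagged).  The regression is plain
OLS of tRNA count on demand with R² the squared Pearson correlation; the
overload score is R²(without focal) − R²(with focal), ~0 for a genome on
the panel's line and strongly positive for an over- or under-supplied
genome.  Cognate coverage defaults to exact Watson–Crick anticodon
matching; wobble rules vary by lineage and are therefore supplied as a
data table, not code.

## Functional-ORF rule

Functional iff ORF length ≥ 80% of the closest ortholog's length
(boundary inclusive) OR essential domains intact; the domain flag is an
input, since domain scanning is upstream of this package.  The ratio is
scale-invariant, so nucleotide vs amino-acid lengths are interchangeable;
nucleotide is documented.  Missing both pieces of evidence is an explicit
"unclassifiable" error, not a silent default.

## Synthetic genomes and planted mutations

`generate_genome` lays out non-overlapping features separated by IGRs
drawn from a multinomial split of the residual length: CDS are ATG +
stop-free iid codons + a stop drawn from configurable TAA/TAG/TGA weights;
tRNAs carry real anticodon qualifiers; an optional duplicated block is
written as two identical rRNA-like copies; an optional IR-flanked region
and extra A/T homopolymer runs (Poisson number per kb, length 6 +
geometric) are planted in IGRs.  Realized GC tracks the target within
~0.7% at these scales — stop rejection and planted A/T runs push it up and
down a few tenths of a percent, which the tests bound at 1% for ≥ 100 kb.

`derive_strain` plants substitutions and indels whose class fractions are
realized as exact largest-remainder quotas, not per-event coin flips: the
study conditions are stated as exact counts (transition share, GC↔AT
share and its A↔T/G↔C remainder, per-partition counts, synonymous share
among coding changes, homopolymer-targeting share), and quota realization
reports those conditions back without binomial noise.  The rng still
chooses positions, orientations and orderings, so different seeds give
different genomes and placements.  Constraints that make every planted
label recoverable: a minimum spacing between events (default 10 bp, so
alignment never merges or reinterprets neighbouring events), no events on
feature boundaries or CDS start/stop codons, no substitutions that create
internal stops, at most one kind of event per gene (a gene carries
substitutions or an indel, not both — keeping the ortholog codon alignment
exact for the selection stage), and homopolymer-targeted indels (assigned
to the smallest drawn sizes, since a deletion cannot exceed its run) whose
allele is the run base at the run start.  Non-targeted indels are placed
clear of qualifying runs and verified against the context classifier at
planting time, so the truth label is what the classifier's definition
says, while recovery still exercises the full align → call → normalize →
classify path.  Truth events are stored as left-normalized anchored
variants in ancestor coordinates — the same representation the caller
emits — and applying them to the ancestor reproduces the derived sequence
byte-for-byte (asserted for every seed tested).

The two headline scenarios encode the study conditions: a 138,931 bp / 59%
GC genome (116 CDS, 7 tRNAs, a 4,023 bp duplicated block, a 7,032 bp
region flanked by 71 bp inverted arms) whose sister strain carries 23
substitutions (10 transitions, 20 coding) and five 1–2 nt indels with a
net −4 bp; and a 538,203 bp / 44% GC genome (406 CDS, 41 tRNAs, no
lysine-AAG decoder, IGRs enriched to ~844 A/T runs ≥ 6 nt) whose sister
carries 262 substitutions (236 GC↔AT, 18 A↔T, 8 G↔C; 139 coding of which
77 synonymous; 12 in pseudogenes) and 60 indels (mean ~5 nt, 35 in
homopolymers).  The published per-partition substitution counts are
mutually inconsistent (they sum past the stated total); the scenario keeps
the coding and pseudogene counts absolute and lets IGR absorb the
remainder.  A third, 150 kb scenario carries the same 23 + 5 load for fast
end-to-end recovery, and a fourth plants 10,000 substitutions on an
IGR-heavy 300 kb genome (anchor k = 15 there, since unique 31-mers thin
out at ~3% divergence) for statistical recovery of the class fractions.

## What the synthetic data does and does not show

The generator emulates architecture (sizes, GC, feature mix, duplications,
homopolymer enrichment) and the mutational spectrum, with iid base
composition within each region class.  It does not emulate real codon
usage beyond GC bias, operon structure, annotation noise, assembly or
sequencing error, or selection acting on the planted changes.  Passing
recovery tests therefore demonstrates that the pipeline's calling,
normalization and classification are exact under the stated spacing
conditions — not that a real strain pair is free of alignment ambiguity.
Real-data reproduction of the published per-genome statistics is wired in
`analysis/07_deposited_genomes.py` and the corresponding acceptance test,
and runs when the four deposited GenBank records are supplied locally;
they are not redistributable and this environment cannot fetch them.

## Numerical and design choices

Alignment scoring constants are fixed (+1/−2/−4/−1) — at 99.9% identity
the called variants are insensitive to the scheme, and the DP-optimality
oracle guards the implementation rather than the constants.  dS/dN use
equal pathway weighting and Jukes–Cantor correction; the published dS/dN
for these genomes name no method, so those values are treated as
method-sensitive soft targets and reported alongside the computed ones
(dS ≈ 0.0008, dN ≈ 0.0002, ω ≈ 0.26 under this method on the synthetic
pair).  Problem sizes in the test-suite oracles (200 alignment pairs ≤
2 kb, 200 50-codon NG86 pairs, 1000 sequences ≤ 5 kb for the
homopolymer/repeat oracles, 10,000 planted substitutions, 1000
uniform-null families) keep the whole property suite to a few minutes on
one CPU while leaving each check statistically meaningful.  Bootstrap
reps default to 1000 in the library and are reduced in bulk test runs.
Circular topology is recorded, and the strain pairs are assumed to share
their deposited linearization; origin-crossing features are split at
parse time, and realigning rotated circular genomes is a known limitation.
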