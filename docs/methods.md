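# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind anchorkit. It is written for a user who wants to know
what the package actually computes, what the synthetic data do and do not
emulate, and where genuinely open design choices were resolved.

## Synthetic data model

**Species trees** are random coalescent-style topologies: lineages merge in
random pairs with exponential waiting times plus a small constant (0.01) so
every internal branch has strictly positive length. Tree depth is of order
one coalescent unit. All generators are pure functions of their inputs and
a seed (numpy `default_rng`); the same configuration and seed reproduce the
outputs byte for byte.

**Sequences** evolve under Jukes–Cantor: along a branch of length *t* with
substitution rate *r*, each site changes with probability
¾(1 − e^(−4rt/3)) to a uniformly chosen other base. JC was chosen because
its closed forms give exact oracles for the tests; no indels are simulated,
so synthetic "alignments" are ungapped and real-data alignment error enters
only through explicitly planted shuffled segments. Gene duplications are
specified explicitly as (node, extra divergence) events rather than drawn
from a birth–death family process: the planted copy identity of every
sequence stays exact, which is what the downstream recovery tests need.

**Reads**: fragments are uniform on 175–300 bp (the sonication range of a
typical enrichment protocol); each yields a 150 bp forward read and the
reverse-complemented 150 bp tail (PE150). The pair count is
round(coverage·L/(2·read_length)). Qualities are a deliberate caricature:
Q40 everywhere, Q10 at bases where an error was injected. That is enough to
exercise quality-aware merging without modeling platform error profiles;
conclusions about real error structures cannot be drawn from these tests.

**Morphological characters** evolve under the Mk model: each state leaves
at total rate μ and moves uniformly to one of the k−1 other states, so on a
branch of length t the probability of observing a different state is
(k−1)/k·(1 − e^(−kμt/(k−1))). The two-state closed form anchors the
generator tests.

## Probe design

The reference index stores spaced-k-mer keys of every sequence window, both
strands. The default pattern is contiguous weight-20 in a 20 bp window —
the reproducible baseline; a sampled-position pattern is configurable.
Genome scanning merges matching key positions per locus (runs split at gaps
over 100 bp) and calls a homolog when the region's distinct matched keys
cover at least `min_key_fraction` (default 0.2) of the locus key set; the
hit sequence is extracted with symmetric flanks up to the 3000 bp cap and
reported on the locus-forward strand. Key sets count one strand's worth of
keys, so an exact copy on either strand scores fraction ≈ 1.0. The hit
threshold interacts with divergence sharply — a 20-mer survives 5%
divergence with probability ≈ 0.36 — so candidate alignments should contain
a row reasonably close to each genome being scanned, as they do in practice
when the alignments are built from those genomes.

High-copy screening follows the standard enrichment-design recipe: all 15-mers of
the (per-species) trimmed alignments plus every 15-mer one substitution
away, tallied back onto alignment columns wherever a genome position
matches; columns with counts strictly above the threshold (100,000 for real
genomes; scaled in tests, where genomes are ~10⁴ bp, not 10⁹) are
soft-masked. Scanning is forward-strand; a caller wanting both strands
simply includes the reverse complement rows when building the database.

Probes of length P are tiled at density d with starts round(i·P/d) and the
final probe pinned to the region end; probes overlapping masked or non-ACGT
columns are dropped, so interior unmasked bases are covered ⌊d⌋ or ⌈d⌉
times.

## Read merging and copy-aware assembly

Mates merge at the best ungapped overlap of at least 20 bp with mismatch
rate at most 0.05 (our defaults; the merging literature the protocol cites
does not fix them); disagreements resolve toward the higher-quality base
and merged qualities take the maximum. Reads are recruited and placed on
the locus reference by exact 20-mer seed votes (no indels in v1).

Separating gene copies is the delicate step. Pairwise single-linkage on
read overlaps is unusable here: with copies 10% apart, short (≥20 bp)
read overlaps fall below the 5% mismatch threshold often enough that
chains form across copies, and clusters grown greedily from seeds produce
chimeras at their edges for the same reason. anchorkit instead phases at
variant columns: columns whose second-most-common base has count ≥2 and
frequency ≥0.2 mark divergent copies; reads join a haplotype cluster when
they agree with its variant-column consensus at ≥90% of shared sites, with
the requirement that at least max(5, half the read's variant sites) fall
inside the cluster profile — this anchoring stops a cluster from growing
blindly past its copy's territory. Reads covering too few variant sites
are attached afterwards by overall identity. Finally, phased clusters whose
consensuses differ by at most `split_divergence` (default 0.05) over ≥50
shared columns are merged, which realizes the observable contract directly:
copies more than 5% apart yield separate contigs, closer copies collapse.
Consensus bases are per-column majorities, ties called N; `ref_start`
records the contig's offset on the recruiting reference. Planted copy
numbers 1–4 are recovered exactly across 20 seeds at ≥10% divergence and
2%-diverged copies collapse in 20/20, at 60× coverage.

The 50-read contig filter guards against cross-sample index hopping, which
produces low-coverage ghost contigs; the threshold is configurable.

## Orthology

The similarity of two consensus sequences is the Jaccard fraction of their
distinct 20-mer sets (the natural symmetric, bounded reading of
"percentage of 20-mers found in both"); distance is one minus that.
Distances saturate quickly — sequence divergence δ leaves a 20-mer intact
with probability (1−δ)^20 — so the generator's study conditions keep
orthologs conserved (rate 0.02/site on depth-~1 trees, a few percent
divergence) and paralogs at ≥3× that (extra divergence 0.15), matching the
conserved-anchor regime the capture design targets.

Clustering builds a neighbor-joining tree (dendropy backend; rows sorted
lexicographically for deterministic tie-breaking) and cuts it into the
fewest clades containing at most one sequence per species. Because the NJ
tree is unrooted and saturation tends to place the longest edge at a tip
rather than on the between-copy path, the cut considers every possible
rooting edge and keeps the one yielding the fewest species-unique clades
(ties: longer edge, then a fixed edge order). If the whole input is already
species-unique it is returned as one cluster. The result is always a
partition of the input, and no cluster ever holds two sequences from one
species. The occupancy filter takes an absolute count or a fraction of the
sample-manifest species universe (whether such occupancy cutoffs count species or
samples varies between studies, so both modes exist).

## Alignment masking and trimming

A site (residue i in column c) is *good* when its base matches strictly
more than 50% of the other non-gap residues in its column. This per-residue
reading — rather than a per-column one — is what makes the downstream
20 bp window rule produce per-sequence masks. A residue with no other
non-gap residue to compare against is defined good, consistent with the
convention that a single-sequence alignment is entirely good; gaps are
never good. Sliding 20-column windows (step 1) with fewer than 14 good
sites are masked in full; alignments shorter than the window are judged as
one truncated window with the pro-rated threshold ⌈(14/20)·L⌉. Columns
with fewer than 30 unmasked non-gap bases are then removed (gaps do not
count toward the 30), with masked residues written as the missing symbol —
'?' in PHYLIP/NEXUS, 'N' in FASTA. The 30-base default presumes a
170+-taxon matrix; analyses of smaller taxon sets should scale it (the
synthetic end-to-end run uses 15 for its 20 taxa). Masking never edits
residues, trimming never reorders taxa, and raising either threshold is
monotone in the expected direction.

Concatenation orders loci lexicographically, pads absent taxa with the
missing symbol, and emits a RAxML-style partition table
(`DNA, locus = start-end`, 1-based inclusive) that tiles the matrix
exactly. Parsimony-informative sites are columns with at least two states
each in at least two taxa, gaps and missing excluded; percent missing
counts gap plus missing cells over all cells.

## Tree metrics

Support values are read from internal-node labels. The "fraction at
maximal support" statistic uses internal non-root nodes carrying a numeric
label as its denominator (the root and leaves are excluded; unlabeled nodes
are not counted as zero support). Monophyly tests reroot on the outgroup
(single taxon: its edge; several: their MRCA edge) and require the query
set to be exactly one clade. Robinson–Foulds distances count non-trivial
unrooted splits present in exactly one tree, with splits normalized to the
side excluding a reference leaf; the implementation is checked against
dendropy's symmetric difference on explicitly unrooted trees.

## Morphological parsimony

Tree lengths use the unit-cost Sankoff recursion, which equals Fitch length
on binary trees, stays exact on polytomies, and treats '?' as any state.
The heuristic search runs, per replicate, a random-addition-order stepwise
starting tree, steepest-descent branch swapping (SPR by default, NNI
optional; ties broken on a canonical tree key for determinism), and then a
bounded breadth-first closure over equal-length single-swap moves. Each
closure is by construction a maximal connected set of equally parsimonious
trees — precisely one *tree island* — so islands never need a separate
connectivity pass: two closures at the same length are either identical or
unreachable from one another. Replicate hit counts record how often the
search settled on each island; only islands at the globally best length are
reported. The closure bound (`max_trees`, default 2000) exists for
pathological flat landscapes; if it is hit the island census is a lower
bound. Exhaustive enumeration ((2n−5)!! topologies, refused above 9 taxa)
serves as the internal oracle; on 100 random 6–8-taxon Mk matrices the
heuristic reaches the exhaustive minimum in ≥99 cases with only 10
replicates.

Character changes are mapped exactly with Sankoff down- and up-passes: a
branch carries a change for a character only when forcing its two endpoints
to share a state costs more than the character's tree length — i.e. every
most-parsimonious reconstruction changes there. Because the trees are
unrooted, each branch is reported in both orientations, keyed by the taxon
set on each side, with that side's endpoint state as the derived state when
it is unique across reconstructions (`char:state`); a change whose derived
state differs among reconstructions is counted but carries no token.
Characters whose tree length exceeds (observed states − 1) are flagged
homoplasious. Multistate characters are unordered; ordered characters and
ascertainment-bias corrections are out of scope (Bayesian Mk+Γ reanalysis
belongs to external MCMC software).

## End-to-end synthetic experiment

`pipeline.run_synthetic_pipeline` wires everything together at desk scale:
12 loci × 20 taxa, 800 bp loci, 40× coverage, substitution rate 0.02.
Three loci carry 5 extra copies (3% diverged) planted in the first
reference species' genome, so the ≤4-homologs rule must drop them at the
design stage; two loci are sequenced in only half the samples, so the 72%
occupancy rule must drop them after clustering; the remaining 7 reach the
supermatrix. Assembly output is aligned by reference coordinates (exact,
since the simulator produces no indels) rather than through MAFFT, keeping
the run deterministic and aligner-independent; the MAFFT wrapper is
exercised separately in the unit tests.

## What passing tests do and do not show

The synthetic generators omit indels, real base-quality structure,
capture-efficiency variation, contamination and alignment ambiguity beyond
planted shuffles. Passing recovery tests therefore demonstrates that the
algorithms implement their contracts under the stated models — copy
splitting at the advertised divergence, orthology recovery under
conserved-anchor divergences, masking of grossly misaligned segments — not
that real enrichment datasets will behave as cleanly. Problem sizes in the
tests (kilobase genomes, 6–8-taxon parsimony matrices, 20-taxon pipelines)
are the package's chosen validation scale; all the protocol-level thresholds
(5 homologs, 50 reads, 130 species, 14/20 good
sites, 30 unmasked bases, >100,000 repeat counts, 5% copy divergence,
120 bp / 5.5× probes) are implemented at their stated values and their
boundary behavior is asserted exactly.
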