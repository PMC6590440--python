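# Methods

## Scope and data model

The package analyses circular plastomes carried as `PlastomeRecord`
objects: an uppercase A/C/G/T/N sequence (other IUPAC ambiguity codes
are converted to N with a warning) plus typed features (protein, rRNA,
tRNA, intron, ORF). All coordinates are 0-based half-open on the
forward strand; a record whose annotation wraps the linearization
origin is normalized by rotating the sequence, never by splitting a
feature, so downstream code can ignore the origin. Repeat-duplicated
genes carry a `copy_index` so "unique" counts drop the second copy.
Gene symbols are normalized through a shipped synonym table plus a
mechanical rewrite of tRNA anticodon punctuation (`trnT(ggu)` →
`trnT-GGU`, anticodons in RNA alphabet).

## Repeat detection and the quadripartite partition

The large repeat is found by seed-and-extend: exact 21-mers of the
genome are matched against the genome (direct candidates) and its
reverse complement (inverted candidates), seeds sharing a diagonal are
merged, and merged runs are extended gap-free with an X-drop rule
(+1 match, −3 mismatch, stop 50 below the running maximum, trim to the
best-scoring endpoint). Defaults `min_len = 1000` bp and
`min_identity = 0.98` sit far below the ~7–18 kb repeats of real
plastomes while excluding tRNA-scale duplications; k-mers occurring
more than 25 times are skipped as low-complexity. The two inter-repeat
arcs become LSC (longer) and SSC (shorter); the tiling
`LSC + SSC + 2·repeat = genome length` is enforced as a class
invariant. A genome without a qualifying repeat yields an explicitly
flagged degenerate partition (whole circle = "LSC") instead of an
error. Orientation is `DR` when the copies match on the same strand and
`IR` otherwise; the call is invariant to rotation, reflection and copy
labelling (tested). GC content excludes N from numerator and
denominator. Because detection extends to maximal identity, detected
boundaries can differ from annotation-based boundaries by a few bases;
comparisons against published per-region lengths use a ±20–40 bp
concordance band.

## Gene orders, reversal distance and inversion scenarios

Genomes are projected onto signed gene orders; with a region partition
available, the order is rotated (reflecting if necessary) to the
canonical LSC-first page layout, which makes orders comparable across
species. The large repeat collapses to a single signed block; its sign
convention is the strand of the first gene inside the lower-coordinate
copy, which makes orders extracted from annotated records agree exactly
with the simulator's planted truth.

Pairs of orders are reduced to a common alphabet of maximal synteny
blocks; elements private to one genome are dropped (losses belong to
the content module) and a block occurring twice in the target is
accepted only as a tandem duplication (recorded as an explicit event;
anything else demands manual curation). Distances are computed on the
linearization anchored at the source's first block. The engine is
iterative-deepening A\* over reversals with the admissible,
consistent breakpoint-graph cycle bound *d* ≥ *n* + 1 − *c*; this is
exact without implementing hurdle/fortress bookkeeping, and an
exhaustive breadth-first oracle verifies it for all 384 signed
permutations of n ≤ 4 and for random n = 7 instances. All co-optimal
scenarios are enumerated up to a cap (64) in lexicographic
(leftmost-endpoint, interval-length) order; each is replayed to the
target as an internal assertion. An event whose interval contains the
repeat block is flagged repeat-spanning and toggles the IR/DR
trajectory, so the parity of spanning events always matches the
orientation difference between the two genomes.

Placement on a fixed tree is greedy parsimony over event signatures
(the set of underlying genes an event's interval covers, plus its
repeat flag): at each internal node, a signature that opens some
co-optimal scenario of every descendant tip is assigned to that node's
branch — the deepest branch consistent with all carriers — and the
remainder stay terminal. On planted histories with one shared and one
private inversion per clade this recovers the branch assignment
exactly; it is a placement heuristic, not a median-genome optimization,
and ambiguity is surfaced through the co-optima rather than resolved
silently.

## Content scoring and loss mapping

A protein gene is a pseudogene when its summed exon length is not
divisible by 3 (frameshift), when its translation is shorter than half
the cross-taxon median reference length ("substantial truncation" is
not quantified in the source material; 0.5 is configurable), or — in
taxa flagged as lacking U-to-C RNA editing, where a genomic stop cannot
be repaired at the transcript level — when the frame contains an
internal stop. RNA genes are scored by annotated presence. Intron
presence additionally requires the host gene. The fixed land-plant
catalog shipped with the package has 87 proteins (including the ycf94
ORF), 4 rRNAs, 32 tRNAs and 22 introns; the split of ycf2 into two
reading frames is scored as a separate derived character, not as a
loss.

Losses are mapped with a Sankoff dynamic program over
{intact, pseudogene, absent} under quasi-Dollo costs (intact→pseudogene
1, pseudogene→absent 1, intact→absent 2, any gain 10): plastid gene
regain is implausible, so optima never contain gains in practice.
Polytomies are handled natively by the DP. All minimum-cost
assignments are enumerated up to a cap; branches on which every
optimum implies the same event are marked unambiguous. Replaying the
chosen events from the root reproduces the tip matrix exactly (tested),
and the DP cost equals exhaustive enumeration on all test trees up to
8 tips.

The published functional-content matrix is hand-encoded from the
printed per-genome totals and the named diagnostic losses; per-gene
states not individually printed (notably which tRNAs the reduced
spikemoss plastomes retain) were fixed once as nested, plausible sets
that reproduce every printed total exactly. The 14-taxon topology
places clubmosses sister to (quillworts + spikemosses), with the
spikemoss spine (Skra,(Slep,(Smoe,(Stam,Sunc)))) consistent with the
shared rps4-capturing repeat expansion and the independent DR
retention.

## Divergence estimation

Both likelihood engines share a pruning core: site patterns are
compressed, per-node partials are rescaled to avoid underflow, and
transition matrices come from the eigendecomposition of the
π-symmetrized generator. A binary root is collapsed onto the adjacent
edge so every branch length is identifiable under the reversible
models.

The codon model is MG94-style over the 61 sense codons of the
plastid/bacterial genetic code (translation table 11): only
single-nucleotide codon changes have nonzero rate,
q_ij = θ_class(i,j) · π_nt(target) · ω^[nonsyn], with the six
exchangeabilities optionally tied into classes by a six-digit string
(`012232`, `012312`, `012012` are the selections used for the published
data sets) and a separate ω per branch (a "local" model). Codon
frequencies are the F3x4 construction from empirical per-position
nucleotide frequencies and are never optimized. Each branch's
generator is normalized to unit substitution flux, so t is expected
substitutions per codon; synonymous divergence is
dS = t · ρ_syn(ω)/ρ_syn(1), the standard MG94 synonymous-site scaling.
(The alternative convention — the unrescaled synonymous component —
differs by a constant factor; the scaled form is the default and the
one all internal truth values use.) Internal stop codons are an error,
not silently dropped: in lineages without U-to-C editing a genomic stop
is biological signal that must be handled by the content module first;
a stop in the final column is tolerated as a terminal stop.

The nucleotide model is GTR with 4 discrete mean-one Gamma categories
(median method) and an invariant-site proportion; reported divergence
is d = t · (1 − p_inv), expected substitutions per site. With equal
frequencies, a single exchangeability class and no rate variation, the
two-sequence fit reproduces the Jukes–Cantor closed form to 1e-4
(tested).

Fitting is coordinate ascent: per-branch Brent line searches using
spectral likelihood coefficients (likelihood as a function of one
branch length is a small exponential sum once the flanking conditionals
are projected into the eigenbasis; for the codon model the per-branch ω
is nested outside the t search), alternating with bounded Nelder–Mead
over the global parameters, until the log-likelihood gain falls below
`tol` (default 1e-6) or `max_sweeps` is reached. The optimizer starts
from one deterministic point (t = 0.1, ω = 0.5, θ = 1); on all
closed-form and simulation checks this reaches the optimum, and
keeping the fit a pure function of the data was preferred over random
restarts. Likelihood is invariant to root placement (tested), and the
likelihood ordering of nested exchangeability tyings
(`012345` ≥ `012232` ≥ `000000`) holds on fitted data.

`compare_rates` forms the ratio of a species' terminal branch value
between the duplicated-gene tree and the single-copy tree; a zero
denominator is flagged rather than propagated.

## Synthetic data

The generator's defaults are the study conditions: a 40-gene circular
plastome whose rRNA operon (rrn16, rrn23, rrn4.5, rrn5) forms a ~5 kb
two-copy repeat flanking the SSC; ~1 inversion per branch with a
quarter spanning the repeat; a 2% per-element per-branch loss rate
(removal or pseudogenization with equal odds, single-copy genes only —
the rRNA operon is never lost in the study group); GC 0.36; and, for
sequence evolution, 2000 codons per partition (6667 ≈ 20 kb in the
recovery experiments), ω = 0.2, transition-biased exchangeabilities
(1,4,1,1,4,1), Γ shape 0.5 with p_inv = 0.2 for the rRNA-like
partition, and branch lengths of 0.08–0.25 expected substitutions per
site — the range spanned by the real terminal branches. All outputs
are pure functions of the configuration including its seed (tested
byte-identical).

Structural histories operate on a unit list in which each repeat copy
is atomic: inversions never split a copy, an inversion containing
exactly one copy exchanges single-copy sequence between the arcs and
toggles IR↔DR, and intervals containing both copies are disallowed
(equivalent to inverting the complement). Tip genomes are emitted as
fully annotated records in which the second repeat copy is an exact
sequence copy (same strand for DR, reverse complement for IR), so
detection has a planted truth; pseudogenization plants a 1-bp deletion
(frameshift).

Sequence evolution along the tree uses exact transition matrices. The
repeat partition evolves at rate r·t, and with copy-correction
probability γ each mutation in either copy is immediately homogenized,
the direction chosen uniformly (spread to both copies, or erased).
Under this neutral conversion model the marginal substitution rate of
a copy is unchanged by γ — homogenization only correlates the copies —
so the observable rate reduction is carried entirely by r, and γ = 1
makes the copies identical at every tip while r = 1, γ = 0 is exactly
the single-copy null (both tested). Orientation does not enter the
sequence model at all, mirroring the finding that a direct orientation
does not disrupt copy-dependent repair. Tract-based conversion and
repeat boundary shifts (expansion/contraction) are not simulated;
boundary events are inputs to, not outputs of, the generator, and
intergenic sequence is random rather than realistic.

What passing the synthetic tests does and does not show: the generator
matches the estimators' model families, so recovery tests validate the
inference machinery (likelihood code, optimizer, scenario search), not
robustness to model misspecification, alignment error, annotation
error, or rate variation across genes — all present in real data.

## Recovery experiment design and tolerances

At 20 kb the per-branch dS MLE has a sampling SD of roughly 3–8%
(per-branch ω noise propagates into the synonymous-site scaling), so
recovery is asserted on the across-seed mean per branch (<10% over
seeds 1–20) — i.e. the estimator is unbiased at that size — with
per-seed recovery covered at a looser 25% bound in the unit suite.
The r = 0.3 repeat/single-copy ratio is recovered within ±0.05 with
conversion on or off. The acceptance script runs scaled-down versions
of the same computations (5 nucleotide and 4 codon replicates, 60
orientation genomes) and prints each value with the problem size used.

## Known limitations

Exact reversal distance is exponential in the worst case; the cap
(default 20 blocks) and the scenario bound `max_events = 12` keep it
desk-scale, matching real plastome comparisons after block collapse.
The placement heuristic assumes shared events appear as openings of
some co-optimal ordering. The Gblocks-style trimmer is a plain
gap-fraction column filter. The repeat detector reports the single
best pair, not nested or dispersed repeat families.
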