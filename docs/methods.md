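# Methods

This document records the definitions, statistical models, and numerical
conventions implemented by `synbreak`, with the rationale for each choice.

## Coordinates and formats

All intervals are 0-based half-open internally. GFF3 (1-based inclusive)
is converted at the read/write boundary; BED is native. A gene's single
reference position, where one is needed (FISH probes, quantile probe
placement), is the integer midpoint of its interval.

Repeat family labels are mapped to four coarse groups — retrotransposons
(class I), DNA transposons (class II), unclassified TEs, and
simple/low-complexity repeats — by case-insensitive token matching;
unmatched labels fall back to `unknown_te` with a warning rather than an
error, because repeat libraries routinely contain novel labels.

## Synteny blocks and breakpoint regions

A synteny block is a maximal run of **at least two** genes consecutive in
both species' orders: along the reference order, the genes' target
positions must step uniformly +1 (sign `+1`) or −1 (sign `−1`). Membership
ignores gene strand; the sign records only whether the within-block order
is preserved or reversed. Length-1 runs are reported as singletons and
never form blocks — a single transposed gene must not masquerade as an
inversion breakpoint.

The breakpoint region (BR) between two reference-adjacent blocks is the
interval from the end of the left block's last gene to the start of the
right block's first gene. BRs are numbered with Roman numerals left to
right. Abutting or overlapping flank genes are an error: the breakpoint
interval would be empty, which signals an inconsistent annotation.

Block metrics report gene density per 100 kb both at full precision and
rounded to two decimals (Python's banker's rounding), plus a Total row
whose density comes from the summed quantities, not from averaging the
per-block densities.

## Reversal distance and scenarios

`reversal_distance` is a full re-implementation of the
Hannenhalli–Pevzner theory of sorting signed permutations by reversals:

1. The signed permutation is doubled to an unsigned one (+x → 2x−1, 2x;
   −x → 2|x|, 2|x|−1) and framed by 0 and 2n+1.
2. The breakpoint graph's cycles are found by alternating black edges
   (adjacent positions) and gray edges (consecutive values).
3. A gray edge is *oriented* iff its endpoints occupy positions of equal
   parity; components are formed by interleaving (strictly overlapping)
   gray-edge intervals.
4. Unoriented components that appear exactly once in the circular sequence
   of collapsed component runs are *hurdles*; a hurdle is *super* iff
   deleting it would turn another component into a hurdle (its two
   flanking runs belong to one component occurring exactly twice); a
   *fortress* has an odd number ≥ 3 of hurdles, all super.
5. d = (n+1) − c + h + f.

Correctness is established against an independent oracle: a plain
breadth-first search over the reversal graph, sharing no code with the
breakpoint-graph machinery. The test suite checks every signed permutation
of size ≤ 5 exhaustively and random permutations at n ∈ {6, 7}.

`enumerate_minimal_scenarios` performs a depth-first search over reversals
that decrease the distance by exactly one, emitting every **ordered**
sequence of d reversals in lexicographic step order. Enumeration is capped
(default 10,000) and flagged `truncated` rather than raising, since the
scenario count can grow combinatorially.

## The iterative mapping campaign

Round 1 places `n_initial` (default 17) probes at even quantiles of the
reference chromosome. Localized markers are classified by the longest
non-strict monotone backbone of their target-zone ranks, tried in both
chromosome orientations: backbone markers are collinear, the rest
translocated. Ties (same zone) stay compatible with the backbone because
zone resolution, not gene order, limits what FISH can see.

Candidate intervals open between reference-adjacent mapped markers
wherever the backbone membership changes, and additionally where a
translocated stretch breaks its own monotone trend. Each following round
places up to `k` (default 3) probes per open interval at the interval's
(k+1)-quantile points — a multi-point generalization of bisection — always
choosing the available gene whose midpoint is nearest each quantile point.
The campaign stops when no available gene lies strictly inside any open
interval; the final intervals are then the tightest gene-bounded brackets
around the breakpoints. A stretch whose round-1 markers all stay collinear
is never probed further: the method cannot see an inversion no initial
probe landed in, which is a property of the experimental design, not of
this implementation.

## Poisson breakpoint-region test

To ask whether a BR is repeat-enriched, the chromosome is tiled from
coordinate 0 with bins of width equal to the BR; the trailing partial bin
is excluded. λ is the mean element count per bin, x the BR's own count,
and the reported value is the upper tail P(X ≥ x) under Poisson(λ),
computed as `poisson.sf(x − 1, λ)`; x = 0 gives p = 1 by convention.
Elements are assigned to bins and regions **by start coordinate only**, so
no element is counted twice. With a coding mask, coding base pairs are
removed from both the bins and the BR and elements starting inside coding
sequence are dropped, making λ a non-coding rate — this guards against
mistaking gene-poorness for repeat-richness.

Because the statistic is discrete, the test is conservative
(super-uniform): under uniform element placement the rejection rate at
any α is at most α. The calibration study in the acceptance suite verifies
this over 1,000 simulated regions.

The neighborhood profile reports element counts in BR-width bars across
the BR and 50 kb flanks on each side; bars truncated by a chromosome end
keep their true width so densities remain comparable.

## Gene-density ANOVA

Each block is tiled with 100-kb bins from its start (trailing partial bin
dropped; blocks spanning fewer than two whole bins are an error, as are
comparisons with fewer than two blocks). A one-way ANOVA over the per-bin
gene counts grouped by block tests whether density differs between blocks.
All-equal counts return F = 0, p = 1 directly, since the F statistic is
undefined when every group is constant.

**Null calibration.** ANOVA's null distribution presumes between-group
sampling variation. A simulation that fixes each block's exact gene count
(as the default generator does, to pin block spans to the base pair)
degenerates this null: group means become deterministic and the p-values
collapse to 1. The generator therefore has a `poisson_gene_counts` mode in
which per-block counts are drawn Poisson around the configured mean and
gene starts fall uniformly in the block (a marked homogeneous point
process, overlaps permitted, no end-pinning). Under that equal-density
null the ANOVA p-values are uniform (Kolmogorov–Smirnov check across 100
seeds in the acceptance suite). The exact-count mode remains the default
because reproducing fixed block arithmetic requires it.

## Ancestry calls

Each BR is flanked by a gene pair adjacent in ingroup A and separated in
ingroup B (states drawn from `adjacent_same_order`, `adjacent_other_order`,
`not_adjacent`, `unresolved`). A's arrangement is called ancestral iff at
least `min_support` (default 1) outgroups show A's state and **none** show
B's, and symmetrically for B. Any conflict between usable outgroups leaves
the call undetermined — no majority vote, matching the conservative
reading a curator would apply. `unresolved` observations (scaffold breaks,
missing orthologs) never influence a call. The chromosome-level verdict
follows the determined calls when they agree and is `mixed` otherwise.

## Term enrichment

Per flat term (no ontology-graph propagation), the one-sided
hypergeometric upper tail P(X ≥ k) is computed with parameters N
(universe), K (term genes in the universe), n (list size), k (term genes
in the list). Terms absent from the list (k = 0) are not tested; the
Benjamini–Hochberg and Bonferroni adjustments span exactly the tested
terms. Fold enrichment is (k/n)/(K/N). The 2×2 odds ratio a·d/(b·c) is
reported raw with no continuity correction; a zero cell in the denominator
yields +inf (or 0 when the numerator is also zero), which is honest about
divergence rather than hiding it behind an arbitrary pseudocount.

## Simulator

The generator emulates the experimental substrate without nucleotide
sequence: coordinates, orders, and counts carry all the structure the
pipeline consumes.

- **Blocks and BRs.** Block spans are gene-anchored (first gene starts and
  last gene ends exactly at the block boundary), separated by gene-free BR
  spacers, so the chromosome length is the sum of both. The default BR
  lengths (9, 12, 7, 10 kb) sit in the 7–12 kb range typical of
  gene-free inversion breakpoint intervals.
- **Genes.** Lengths are normal (mean 2,000 bp, sd 1,000, floor 200);
  inter-gene gaps follow a Dirichlet uniform-spacings partition of the
  free space — the integer analogue of dropping gene starts uniformly at
  random conditional on no overlap.
- **Repeats.** A homogeneous Poisson process per group with rates per
  100 kb of 2 (retrotransposons), 15 (DNA transposons), 5 (unclassified),
  30 (simple repeats) — an insect-genome-like mix where simple repeats
  dominate counts; `br_repeat_multiplier` scales the rates inside the true
  BR intervals to plant enrichment.
- **Target species.** The planted block-level reversal scenario (default
  the nested pair ((3,3),(2,4)) producing 1 −4 3 −2 5) is applied to the
  block order; gene positions mirror within sign-flipped blocks.
- **FISH.** Zones are `zone_count` (default 39) equal-width bins of the
  target chromosome. A probe reports its true zone, perturbed by ±1 zone
  with probability `localization_noise`; unmappable probes (probability
  `unmappable_prob` per gene) yield no signal. Probes co-hybridized into
  one zone are dye-resolved: their true relative order is observable,
  mirroring dual-colour FISH of nearby probe pairs.
- **Determinism.** All randomness flows from one seed through named
  child streams (genes, repeats, mappability flags, FISH), so datasets are
  byte-identical across reruns; every emitted file embeds the seed in a
  header comment.
- **`paper_scale` preset.** Five blocks of 1,458,895 / 526,550 /
  10,348,225 / 2,148,753 / 3,273,690 bp carrying 122 / 42 / 722 / 137 /
  199 genes (17,756,113 bp of blocks; ~17.8 Mb with BR spacers), the
  nested two-inversion scenario, and the four BR spacers above.

**Limitations.** No nucleotide sequence, no gene families or duplications,
no translocations between chromosomes, equal-width cytogenetic zones, and
repeat lengths that ignore family-specific size distributions. These are
deliberate: every downstream method consumes only orders, intervals, and
counts.

## Output conventions

JSON floats are serialized with six significant digits; display columns
mirror two-decimal conventions where densities are reported. Each CLI
subcommand writes a `manifest.json` (tool version, seed, inputs, outputs,
config hash) beside its outputs; reruns with the same manifest inputs are
byte-identical. Logs go to stderr; results never do.
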