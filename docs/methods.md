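# Methods

## Similarity and distance model

Percent similarity between two aligned sequences is
`100 x identical compared sites / compared sites`. Under the default
*pairwise deletion* policy a site is compared only when both sequences carry
an unambiguous A/C/G/T; gaps, N and IUPAC ambiguity codes are excluded.
*Complete deletion* (drop every column containing any gap/ambiguity across
the whole record set) is available by flag and applied at matrix level.

The Kimura two-parameter distance separates the transition proportion P
(A<->G, C<->T) from the transversion proportion Q:
`d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`. The estimator is undefined when
either logarithm argument is non-positive (saturation); this raises a
dedicated error carrying P and Q rather than returning a number.

Before between-taxon statistics, conspecific strains are collapsed to a
per-species consensus so within-species SNPs do not depress similarity.
Per column the majority base wins; a column is a gap only when gaps hold a
strict majority; base ties become the covering IUPAC code by default
(policy "iupac") so no information is silently dropped — an ambiguous
consensus site is then simply excluded from comparisons. Policy "first"
(alphabetically first tied base) exists for workflows that need a concrete
A/C/G/T consensus, e.g. primer design.

Summary statistics use the sample SD (n-1 denominator). Reported values are
rounded half-up to one decimal, the precision of printed similarity tables.
The per-taxon specificity signal (`taxon_vs_others_average`) excludes
congeners of the target by default; the published per-taxon values the test
suite reproduces require that convention.

## Marker ranking

A marker is *eligible* for a target genus when its margin
(total average - target-vs-others average, both at one-decimal reporting
precision) is positive **or** the genus is monophyletic on the marker's
tree. The OR is deliberate: a genus can sit slightly above the similarity
baseline yet form a clean clade, and such markers are legitimate design
substrates. When trees are available, monophyly dominates the ranking and
margins break ties; without trees the margin alone orders markers. Ties
resolve by marker name, so rankings are deterministic and input-order
invariant.

Monophyly is evaluated as an unrooted bipartition test — does any edge
(including leaf edges) separate exactly the genus's tips from the rest —
so outgroup or rooting choices cannot flip the answer. The bundled
neighbor-joining builder is desk-scale plumbing for when no externally
inferred tree is supplied: similarities convert to distances as
d = (100 - S)/100; negative NJ branch lengths are clamped to zero with the
deficit shifted onto the sibling edge, preserving path lengths through each
join. It recovers additive matrices exactly; it is not a substitute for
likelihood or Bayesian inference on real data.

## Window discovery

A discriminative window for a target genus is an alignment interval
[s, s+L) (0-based half-open columns, L within the primer length range)
such that

- the target rows match their own consensus in at least
  `min_conservation` percent of cells (default 90),
- for **every** other genus, the *closest* member differs from the target
  consensus in at least `min_diff_per_genus` positions (default 1), and
- the consensus slice is plain A/C/G/T (a primer cannot contain gaps).

Counting differences against the closest off-target sequence (not an
off-target consensus) is a worst-case convention: a specificity claim then
holds against every panel member. Windows are ranked by worst-case
difference count, leftmost first on ties. Consensus ties break
alphabetically, which is deterministic but not complement-symmetric; exact
coordinate mirroring under reverse complement therefore holds on tie-free
(e.g. fully conserved-within-target) alignments.

## Primer screening and pairing

Candidates cut from the window consensus are screened on:

- length 18-25 nt (default),
- melting temperature, Wallace rule `2(A+T) + 4(G+C)` by default (a GC
  formula `64.9 + 41 x (nGC - 16.4)/N` is available); no nearest-neighbor
  thermodynamics in this version,
- GC content 30-70%,
- hairpins: a fold-back stem needs >= min_stem reverse-complementary bases
  around a loop of >= 3; the *detector* defaults to min_stem 4, while the
  *design cap* rejects only stems longer than 5,
- primer dimers: the longest contiguous antiparallel complementary run over
  all offsets, capped at 10 for self-dimers and 8 cross-pair.

The caps are deliberately permissive: validated, wet-lab-proven
genus-specific primer sets contain a 5-bp fold-back stem and a 10-bp
palindromic self-overlap, so stricter binary run-length screens would
reject working primers. All ten packaged published primers pass the
defaults, which the test suite pins as a regression.

Pairs must satisfy a product-size range (measured on the degapped target
consensus from forward start to reverse end) and a maximum Tm difference
(default 6 degC). The recommended annealing temperature is the grid point
of {51, 53, 55, 57, 59} degC nearest to min(Tm) - 5, lower on ties — a
documented convention standing in for wet-lab gradient optimization, which
is out of scope. Rejections are tallied per constraint and returned instead
of raising, so an empty result is diagnosable. All orderings have full
deterministic tie-breaks (difference count, product-size closeness,
coordinates, sequence), making outputs byte-reproducible.

## 3'-terminal mismatch scoring

For genus pairs too similar to yield many-base windows, discrimination is
engineered by placing the few diagnostic SNPs at the primer's 3' terminus,
where a template mismatch impairs polymerase extension. The per-position
extension-failure probabilities default to p1 = 22.5%, p4 = 31.7%,
p5 = 32.9% (distance k from the 3' terminus, k = 1 terminal), empirical
values from allele-specific PCR mismatch studies. Positions without a
tabulated value (k in {2, 3} and k > 5) are **not** invented: they are
reported as "unknown" and excluded from the combined score
`C = 100 x (1 - prod (1 - p_k/100))`, which assumes independent
per-position failure. The table is user-overridable. Scoring requires the
primer to bind the target template perfectly — discrimination is defined
relative to an intact target duplex — and locates the off-target site as
the best no-indel placement on either strand.

## In-silico PCR

Default binding rules: at most 2 total mismatches, any 3'-terminal mismatch
rejects, at most 1 mismatch within the last 5 nt; N in the template counts
as a mismatch. These thresholds operationalize the qualitative 3'-mismatch
rationale and are all configurable; no published mismatch-count tolerance
exists to calibrate them against, and they are chosen to reproduce the
qualitative specificity contrasts (a 3'-placed pair separates near-identical
genera; a pair without 3' placement amplifies both). Binding is binary —
no extension-efficiency, band-intensity or detection-limit model.

Amplicons arise from a forward site on + strand upstream of a reverse site
on -, length measured forward-start to reverse-end; the mirrored
configuration (reverse on +, forward on -) is the same duplex viewed from
the other strand and is enumerated too, making predictions invariant under
reverse complement of the templates. Coordinates are 0-based half-open on
the + strand throughout.

## Synthetic panels

`generate_genus_panel` draws a uniform root, mutates genus ancestors at the
between-genus divergence and members at the within-genus divergence, with
substitutions under a 2:1 transition:transversion bias so P/Q-aware
statistics are exercised. Defaults (5 genera x 3 members, 600 columns, 2%
within / 15% between) put between-genus similarity in the mid-80s — the
regime where marker-based genus discrimination operates. Planted windows
are overwritten *after* background mutation: target rows become identical
to the target ancestor inside the window and every other genus is set to
differ in exactly D positions, so ground-truth difference counts are exact
rather than expected. Realized within/between divergences match a 4-state
Markov-chain expectation (verified in the tests against a closed-form
kernel product). The generator produces no indels, rate heterogeneity or
recombination; passing tests therefore demonstrate algorithmic correctness
on idealized panels, not robustness to alignment error or heterotachy in
real data.

The planted-window recovery check uses a saturated plant (18 differences in
a 20-column window over a 5%-divergence background): a window shifted off
the plant strictly loses differences, so top-rank recovery is the expected
outcome for every seed rather than a sampling accident.

## Problem sizes

Packaged matrices span 6-12 taxa per marker. Synthetic regression panels
use 3-5 genera, 2-3 members each, 400-600 alignment columns, and 20-seed
sweeps for calibration and recovery properties; exhaustive window-search
oracles run on alignments of at most 60 columns. These sizes are the
package's chosen study conditions for deterministic, fast verification.

## Known limitations

- Degenerate-primer expansion, multiplex pooling, TaqMan probe design and
  duplex thermodynamic (delta-G) models are out of scope.
- Trees are consumed, not inferred (beyond the desk-scale NJ surrogate).
- The 3'-mismatch probability table covers three positions; combined scores
  over other positions silently shrink toward the known-position product.
- Sequence alignment itself is an input; the toolkit never aligns.
- Trimming of ragged alignment ends is explicit (column-range slicing), not
  inferred.
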