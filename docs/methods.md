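# Methods

## The inference problem

Comparing genomes across species cannot separate insertions from deletions
without a third lineage, and indels in functional sequence are shaped by
selection. Dead-on-arrival transposable elements sidestep both problems:
each LINE copy is a decaying fossil of its subfamily's master (consensus)
sequence, evolving neutrally from the moment of insertion. Aligning every
copy against its master and reading gap runs as events yields per-region
insertion and deletion rates from a single genome.

The package's central quantities, per genomic window:

- insertion rate = Σ inserted bp / Σ repeat bp,
- deletion rate = Σ deleted bp / Σ repeat bp,
- deletion bias = Σ deleted bp / Σ inserted bp (undefined, not 0 or ∞,
  when no insertion was observed),
- net loss = deletion rate − insertion rate,

where "repeat bp" is the summed ungapped master-sequence span of the
window's elements, so the denominators are comparable across windows
regardless of how much sequence the copies themselves have lost. Sign
convention: positive net loss = contraction. (Some presentations plot the
opposite sign, insertion − deletion; `net_loss` is deletion − insertion
throughout, and plotting code can negate.)

Windows are non-overlapping, 1 Mb by default (5 Mb or arbitrary sizes are a
parameter); an element belongs to the window containing its genomic start;
elements split into fragments by a nested insertion count once, in the
window of their first fragment. Windows with no elements carry missing
rates, never zeros — an empty window is absence of evidence, and coding it
as 0 would manufacture correlation with anything that predicts repeat
density.

## Indel calling

Within one gapped alignment pair, a maximal run of gap characters in the
master string is one insertion (its sequence is the copy bases over the
run); a maximal run in the copy string is one deletion. Two design rules
matter:

- **Terminal gap runs are not events.** LINE copies are very often
  5'-truncated on arrival and the source alignments are local; a gap run
  touching either end of the alignment records truncation or alignment
  scope, not an indel mutation. Counting terminal runs would inflate
  deletion rates by orders of magnitude.
- **No merge window.** Gap runs separated by ≥ 1 aligned column are
  separate events. No realignment or gap-placement optimization is
  attempted.

Event coordinates are expressed on the master (consensus) axis
(`m_start` + master bases preceding the run), which makes the same mutation
observed in several copies — a violation of the star-phylogeny assumption
by undetected daughter activity or gene conversion — detectable: the
*unique-events* mode groups events by (subfamily, kind, master position,
length, and inserted sequence for insertions) and removes every group with
multiplicity > 1. For deletions the deleted sequence is gone from the copy,
so position + length is the grouping key. All headline correlations can be
recomputed in this mode as a robustness check.

Substitution divergence is the mismatch proportion over ungapped,
unambiguous columns, with closed-form corrections (JC69 default,
−¾ ln(1 − 4p/3), undefined at p ≥ 0.75; K2P optional). A likelihood-based
substitution model fit was deliberately not used: divergence serves here as
a covariate and normalizer, not as a dated estimate, and the closed forms
keep the chain dependency-free and exactly reproducible.

## Subfamily chronology from nesting

If elements of subfamily B are found inserted *inside* elements of
subfamily A but not vice versa, A's activity preceded B's. A nesting is
recorded when two fragments of one copy (same element id, same subfamily)
flank, adjacently in genomic order, an element of another subfamily lying
strictly between them. From the count matrix N[host, nested], each
subfamily's relative activity time is the Laplace-smoothed fraction of its
involvements as the younger partner:

    t_i = (n_nested,i + 1) / (n_nested,i + n_host,i + 2),

in (0, 1), low t_i = old, 0.5 for a subfamily never involved in nesting.
This is a deliberately simple rank-preserving estimator — only the rank
order of t_i is consumed downstream — in place of a full probabilistic
activity-period model.

Window divergence is normalized for age composition by the factor
t̄_window / t̄, where t̄_window is the mean t_i over the window's elements
and t̄ the unweighted mean over subfamilies genome-wide. The factor is the
identity when a window's age mix matches the genome and scales divergence
linearly with relative recency. The exact functional form is a package
design choice (the normalization only needs to be monotone and
composition-neutral); every correlation is therefore also reported
un-normalized, and the normalization can be switched off.

## Resampling tests

Window variables are heavily non-normal, so all association tests use
Kendall's tie-corrected τ_b with the asymptotic normal p-value.

**Z vs autosomes.** Because subfamily composition differs between
chromosome classes, naive comparisons of LINE length or deletion bias
between the Z chromosome and autosomes confound chromosome with subfamily
age. The bootstrap therefore shuffles category labels *within subfamily
strata* (10,000 replicates by default), preserving both category sizes and
stratum composition; the statistic is either the difference of mean element
lengths or the difference of the two categories' deletion biases, each bias
computed as Σ deleted bp / Σ inserted bp over the category's elements.
Replicates in which a category has zero inserted bp are redrawn and
counted. p-values are add-one permutation probabilities,
p = (1 + #extreme) / (R + 1), two-sided by default with the one-sided value
reported alongside.

**Per-chromosome randomization.** Genome-wide correlations could be driven
by between-chromosome differences alone. Restricting to chromosomes with at
least 20 complete windows, the statistic is the unweighted mean of
per-chromosome τ; the null permutes the y variable independently within
each chromosome (preserving each chromosome's x distribution, tie structure
and window count), 10⁶ replicates by default, one-sided for the directional
claim. Per-chromosome p-values are Benjamini–Hochberg adjusted when
reported as a table. The permutation loop uses precomputed sign matrices —
under within-chromosome permutation the τ_b tie-correction denominator is
invariant, so only the concordance numerator is recomputed — which is what
makes 10⁶ replicates practical; the fast path is tested for exact equality
against the public τ_b.

**Segregating indels.** If recombination promoted deletions via selection
rather than mutation, insertions should segregate at lower frequencies than
deletions where selection is effective. The test builds the 2×2 table of
kind × (MAF < 0.05 vs ≥ 0.05) per context class (intron / intergenic /
LINE) and applies Pearson's χ² with 1 df and no continuity correction.

All three tests are calibrated in the acceptance suite: type-I error within
[0.03, 0.07] at α = 0.05 over 500 null simulations each (permutation tests
run with R = 199 add-one replicates there, making the nominal rejection
probability exactly 10/200).

## The decay model

Three-species ancestral-repeat alignments (focal, sister, outgroup) allow
branch assignment by parsimony:

- focal-specific gap, sister and outgroup with bases → focal deletion;
- focal-specific bases, sister and outgroup both gapped → focal insertion;
- all three with bases, focal ≠ sister = outgroup → focal substitution;
- all three different → unassignable, excluded from numerator and
  denominator.

Indels are counted as gap *runs*, consistent with the caller; a run with
mixed column support is assigned by strict majority of its columns, ties
excluded. Triples where the sister or outgroup ungapped length is below 80%
of the alignment length are excluded first (spurious flanking sequence);
the boundary (exactly 80%) is kept. Denominators: substitutions per
three-way ungapped site; deletion and insertion bp per ancestral-present
site (sister and outgroup both with bases). Window estimates are combined
with the per-window denominators as weights, which makes the genome-wide
estimate the pooled ratio of summed counts — invariant to how repeats are
grouped into windows.

With branch rates D, I, S, the net loss per substitution is (D − I)/S.
Taking divergence as the time axis (no molecular-clock calibration) and
modeling neutrally evolving sequence length as f(t) = e^(−rt), one branch
of its own divergence S must lose exactly the observed net fraction D − I,
so

    r = −ln(1 − (D − I)) / S,    fraction lost after t = 1 − e^(−rt).

The identity `fraction_lost(decay_rate(D, I, S), S) = D − I` holds to
machine precision and is asserted over random rate triples. As
(D − I) → 0, r → (D − I)/S, the loss-per-substitution, which is the
small-loss sanity check. Confidence intervals are percentile bootstrap over
whole repeats (1,000 replicates by default), recomputing the entire chain
per replicate; per-repeat counts are precomputed so the bootstrap is exact
and fast. Large-scale insertions (new element expansions) are explicitly
outside the model: it quantifies loss from small indels only.

Known parsimony caveat: substitutions on the sister or outgroup branch
remove columns from the focal numerator (the all-differ exclusion), so S is
undercounted by roughly the product of the other branches' substitution
probabilities (≈ 8% at the simulated divergences). This is inherent to
parsimony counting, affects D and I far less, and biases r slightly
*upward*; the bootstrap CIs quantify sampling, not this systematic, error.

## The simulator

The generator produces exactly the data structure the estimators assume,
plus a complete truth table, so every stage can be checked for calibration
rather than alignment artifacts:

- **Star phylogeny.** Each subfamily has a random master sequence and an
  activity epoch on a [0, 1] time axis; every copy draws an insertion time
  uniformly in its epoch and evolves independently for elapsed time
  1 − insertion time. Default rates per site per unit time: substitution
  0.10, deletion 0.05 bp, insertion 0.015 bp (base deletion bias 3.33,
  within the range observed in compact vertebrate genomes).
- **Indel lengths** are a three-class mixture — small 1–2 bp, intermediate
  3–20 bp, long > 20 bp — with truncated-geometric lengths within class and
  default weights (0.45, 0.50, 0.05) chosen so the intermediate class
  dominates bp turnover. Events are placed away from sequence ends and
  without collisions, so the emitted alignment is the true alignment and
  the caller must recover the truth table *exactly* (asserted).
- **Substitutions** are placed without replacement on surviving master
  sites (infinite-sites per copy); recovery checks compare on the
  p-distance scale.
- **Recombination map**: per-window gamma-distributed rates (shape 4)
  around class means (macrochromosome 2.5 cM/Mb, microchromosome 6.0 —
  the obligate-crossover elevation of small chromosomes), Z at half the
  autosomal mean (it recombines only in males), W at 0 (never recombines).
  The recombination→deletion link is linear: per-copy deletion intensity
  multiplier 1 + β·rate/mean rate. β is 0 in the `null` scenario and 2 in
  `contraction`/`sex-chromosome`; the linear form is the simplest monotone
  link — the analyses downstream are rank-based and only assume
  monotonicity.
- **Truncation** clips the 5' end of a copy (probability and minimum kept
  fraction configurable) at an event-free coordinate, so truncation never
  masquerades as a deletion.
- **Nesting**: with configurable probability a copy of a younger subfamily
  inserts at an event-free internal coordinate of an older, previously
  placed element in the same window, splitting it into two fragments that
  share the element id — exactly the signal the nesting detector consumes.
  Only unsplit hosts are eligible (no recursive nesting).
- **Placement** assigns each copy to a recombination-map window (length
  weighted), then lays windows out with multinomially distributed gaps;
  overflowing a window is a configuration error, not a silent truncation.
- **Gene models** are toy multi-exon genes at a configurable density, used
  by the exon filter and the genome-structure features. **Polymorphisms**
  draw a folded neutral site-frequency spectrum (n = 100 chromosomes),
  identical for insertions and deletions — a null by construction for the
  SFS test.
- One `numpy` generator seeded once drives every draw; fixed seed gives
  byte-identical fixtures.

What the simulator does *not* emulate — and what passing tests therefore do
not show about real data: realignment noise and gap-placement ambiguity in
the source alignments (the caller is exact here, not on RepeatMasker
output), base-composition and CpG effects, microsatellite slippage,
recombination hotspot fine structure, gene conversion, selection, and
correlated placement of repeats with genomic features beyond the
recombination link itself.

## Problem sizes and defaults in the test suite

Simulated checks run at desk scale by the package's own choice of
conditions: rate recovery at 2,000 copies × 1 kb (relative error < 10%
asserted; < 3% typical), the sign-pattern reproduction at 200 windows × 100
seeds with β = 2, calibrations at 500 null replicates with R = 199, the
nesting chronology with ten subfamilies spanning epochs [0.1, 0.9]. The
named scenarios (`null`, `contraction`, `sex-chromosome`) use 2–6 Mb
genomes with 1,200 copies in 50 kb map windows so a full
simulate-and-analyze cycle takes seconds; all sizes scale up by
configuration only.

## Known limitations

- Fragmented elements are treated as separate alignment records sharing an
  id; no re-joining before calling. Real multi-fragment RepeatMasker
  elements may split single events across fragments.
- The terminal-gap rule discards genuine indels that touch an alignment
  end; this trades a small undercount for robustness against truncation.
- The divergence normalization is a declared reconstruction (see above),
  not a fitted model; conclusions should not rest on its scale, only on
  ranks, and the un-normalized numbers are always available.
- The decay extrapolation assumes a constant rate parameter and that rates
  inside transposable elements represent the whole genome; DNA gain by
  large insertions is outside the model.
- Mixed-model control for chromosome identity is out of scope; the
  per-chromosome randomization test covers that concern
  non-parametrically.
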