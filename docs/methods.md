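# Methods

This note records the statistical procedures `macromap` implements, the
choices made where the design was genuinely open, and what the synthetic
scenarios do and do not establish about real data.

## Map model

Positions are 0-based cM floats on `[0, length]` per linkage group;
chromosome labels are strings (the default universe in the simulators is
12 groups, the haploid chromosome number of Pinaceae, but the count is
free).  Ties in position are allowed and meaningful: on a mapping
population of a few hundred progeny, loci with no observed recombinant
print identical positions, and those zero-recombinant groups are an
analysis object (`colocalized_groups`, default `epsilon = 0`).  Whether
co-localization should tolerate small nonzero cM differences is not
settled; `epsilon` is exposed and the default is exact ties.

**Composite-map transfer.**  A locus mapped only in a donor taxon is
placed on the reference map at the midpoint of the interval between its
two flanking anchor loci (genes mapped in both taxa), flanking being
determined in donor coordinates.  Donor loci outside the anchor span are
skipped with a warning rather than extrapolated — the midpoint rule only
defines interior placement.  An anchor set whose reference positions are
not monotone along the donor order (a putative inversion) is refused for
that chromosome rather than silently averaged.

## Uniformity testing

Per chromosome, `D_n = sup_x |F_n(x) − x/L|`, evaluated at both one-sided
limits of every jump of the empirical CDF; tied positions contribute
multiple steps.  Significance is read from the modified statistic

    D*_n = D_n (√n − 0.01 + 0.85/√n)

whose critical-value table (0.775 → 0.15 … 0.895 → 0.05, 1.035 → 0.01)
does not depend on n.  The multiplier is not printed in the source
analysis; it was identified from the printed critical values and
verified to reproduce the printed per-chromosome D* values from the
printed (n, D) pairs to ≈2×10⁻⁴ on most rows (three rows only to
≈6×10⁻³, consistent with rounding of the printed D to four decimals).

**Calibration caveat.**  Those critical values are the
D'Agostino–Stephens points for the *estimated-parameters* (Lilliefors
type) case.  Against a fully specified uniform null they are strongly
anti-conservative: in uniform simulation at n = 150, `D* ≥ 0.895` occurs
in ≈38% of samples, not 5%.  One may argue a map's support is partly
estimated (its endpoints are themselves loci), but pinning two endpoints
does not produce the estimated-parameters distribution either (measured
rejection is unchanged).  The package therefore reports, alongside the
band, the exact p-value of `D_n` under the fully specified null
(`ks_exact_p`, the exact one-sample two-sided KS distribution), which
calibrates at α in simulation.  Conclusions of non-uniformity based on
the band column alone should be treated as anti-conservative.

## Gene density and GRR calling

Adaptive Gaussian KDE per chromosome:

1. pilot fixed-bandwidth estimate with Silverman's rule
   `h = 0.9 min(sd, IQR/1.349) n^{−1/5}` (the source analysis does not
   state its bandwidth and reports insensitivity to it);
2. local factors `λ_i = (g / f̃(x_i))^{1/2}`, `g` the geometric mean of
   the pilot density at the data points (adaptive exponent ½);
3. final estimate `f̂(x) = (1/n) Σ K_{hλ_i}(x − x_i)` with reflection at
   0 and L, so `∫f̂ = 1 ± 0.01` and end clusters are not biased low;
4. pointwise variance `V̂(x) = (1/(n(n−1))) Σ (K_i(x) − f̂(x))²` and band
   `f̂ ± z_{1−α/2} √V̂` (lower limit clipped at 0).

A GRR is a maximal interval where the lower band limit exceeds 1/L;
boundaries are linearly interpolated between the 0.1 cM grid points.
Chromosomes are tested independently at fixed α with no genome-wide
multiplicity correction, matching the per-chromosome reporting
convention of the source analysis.

**Calibration caveat.**  The band is pointwise and plug-in, and the
adaptive step feeds back on random clusters (where the pilot is high,
`λ_i < 1` sharpens the peak further).  Under uniform simulation (1,000
loci, L = 100, α = 0.01) at least one false GRR is called in ≈12–14% of
replicates; the identical band without the adaptive step fires in ≈5%,
and the adaptive calls are a superset of the fixed-bandwidth calls.
Power is not the issue — a 4× enrichment cluster of 40 genes in a 5 cM
window is recovered in ≈100% of replicates at α = 0.05.  Users wanting
a replicate-level false-call rate below 10% should either use
`adaptive=False` for calling (keeping the adaptive curve for display)
or tighten α; the default follows the adaptive prescription.

## Tandem arrays and family dispersion

Arrays are maximal single-linkage chains of same-family loci on one
chromosome with consecutive gaps ≤ 5 cM (chains of ≥ 2 loci); an array
is class "1cM" iff all its gaps are ≤ 1 cM.  Single-linkage with a gap
cap was chosen over a span cap so membership does not depend on
processing order.

The dispersion test redistributes the members of multi-gene families
over the fixed set of mapped positions (sampling positions without
replacement each replicate, default R = 1,000) and tabulates families by
the number of chromosomes occupied (1..C).  The χ² compares observed to
mean simulated category counts; categories with simulated expectation
< 1 are pooled toward lower k before summing (standard practice; the
source's pooling is unstated) and df is reported as C − 1.  Per family,
an empirical p is the fraction of replicates in which a random family of
its size occupies as few or fewer chromosomes; families at p ≤ 0.05 are
flagged as clustered.  Note a structural limit: with 12 chromosomes a
two-member family's best attainable empirical p is ≈1/12, so only
families of ≥ 3 members can ever be flagged at 0.05 — power statements
about planted tandem families are made with 3–4-member plants.

Two-category χ² tests on printed duplicate-pair counts use equal
expected frequencies (50:50); this reconstruction reproduces all three
printed values (482.2, 1.9, 18.9) exactly at printed precision.  The
Welch t compares recent vs ancient same-chromosome distance sets with
Welch–Satterthwaite df.

## Dating duplications against the GA split

Input trees are unrooted bootstrap consensus gene trees (one NJ, one MP
per family), supports on internal edges; leaves classify by label
prefix (focal gymnosperm `Pg`, other gymnosperm `Pt`, angiosperms `AT`,
`Os`).  Edges below 50% support are collapsed first (threshold
configurable).  The tree is rooted on the lexicographically smallest
angiosperm leaf — a deterministic convention; labels driven by resolved
clades are invariant to which angiosperm roots the tree, which is
asserted by a re-rooting property test.  For a pair (a, b) of focal
genes:

* **recent** — the MRCA clade contains no angiosperm leaf;
* **ancient** — otherwise, if the MRCA is binary or an angiosperm lies
  inside one of the two MRCA children containing a and b;
* **undetermined** — the MRCA is a multifurcation whose angiosperms all
  sit in children holding neither gene (the polytomy leaves the event
  order unresolved).

Pairs are labelled on both trees; disagreement (including a gene absent
from one tree) makes the pair **incongruent**, excluded from age
tallies.  Percentages are reported over the congruent pairs.  Strict
consensus of the two trees is also emitted per family as an artifact.
Other-gymnosperm leaves never influence a label — they anchor nothing
about the GA split.  A known bias is accepted, not corrected: an ancient
duplicate lost independently in both sampled angiosperm lineages would
masquerade as recent; with two divergent angiosperm genomes sampled the
effect is small, and it can only *understate* the ancient:recent ratio.

Consensus machinery: splits are stored normalised to the side not
containing the smallest leaf; majority rule keeps splits in strictly
more than half of the inputs (these are always mutually compatible) with
percentage supports; strict consensus is split-set intersection.  Both
are verified against exhaustive subset enumeration on trees of ≤ 8
leaves and against an independent consensus implementation.

## Synteny between two maps

Reciprocal best hits from BLAST-style tabular hits, ordering key
(bit score, identity, subject id) — fully deterministic — with a default
identity floor of 80%.  For each chromosome of map A, the homoeologous
chromosome of B is the plurality receiver of its links; a link is
syntenic iff it joins a homoeologous pair.  "Collinear" has no standard
operational definition on genetic maps; here it is membership in a
longest nondecreasing subsequence of map-B positions (links sorted by
map-A position, coordinate ties compatible), computed per homoeologous
pair, with an option (default on) to take the better of forward and
reversed map-B orientation, since a whole-arm inversion conserves local
order.  Conserved segments are maximal runs of collinear links with
inter-link gaps ≤ 20 cM on both maps (the cap is a config property, and
coverage percentages are properties of that cap, not comparable across
caps).

## Synthetic scenarios

The generators are pure functions of a `ScenarioConfig` (seed included)
and emit ground truth sufficient to score every stage.  Defaults
describe the emulated study conditions: 12 linkage groups with lengths
120–205 cM (total ≈2,085 cM), ~150 genes per group, 157 multi-gene
families with sizes 2 + Poisson(1.4), a fraction 8/9 of duplication
events predating the GA split, translocation probabilities 0.919
(ancient) / 0.425 (recent), same-chromosome offsets Exp(mean 4.3 cM)
for recent and Normal(47, 15) cM for ancient pairs.  The ancient sd of
15 cM is chosen so truncation at chromosome ends leaves the realized
mean at the nominal 47; these values are generator parameters, not
claims about any real dataset.  Family trees place a sibling
angiosperm cherry under every pre-GA lineage (angiosperm-loss
probability defaults to 0 so ancient labels are identifiable; raising
it exercises the masquerade bias above).  Tree noise is independent
per-edge NNI and collapse on the two tree copies; retained edges carry
support 100.

Map pairs are related by chromosome renaming, optional position jitter,
single-gene translocations and segment inversions; the identity
(zero-rearrangement) scenario keeps jitter at 0 because any jitter can
swap the order of close genes, which is itself a micro-rearrangement.
Hit identities are Normal(92, 3) truncated to [70, 100] and rounded to
3 decimals, with uniform low-identity decoys.

For translocation/distance recovery the scenario uses two-member
families so that each gene pair corresponds to exactly one duplication
event — with larger families, pair-level translocation statuses are
correlated through shared placements and the per-pair probability is
no longer the generator's Bernoulli parameter.

**What passing tests show, and what they do not.**  The scenarios have
uniform backgrounds, exact exponential/normal offset laws, noise-free or
simply-noised trees, and an orthology that is 1:1 by construction.  Real
maps have recombination-driven marker clustering (e.g. centromeric
compression), gene families without clean 1:1 orthology, alignment and
paralogy artefacts in hit tables, and tree error that is not independent
NNI/collapse noise.  Recovery of planted truth therefore validates the
algorithms and their wiring, not the biological error rates to expect on
real data.

## Problem sizes

Default test and acceptance runs use 100–1,000 Monte-Carlo replicates
per calibration, 157–700 families per dating scenario and 150 shared
genes per map pair; these sizes put Monte-Carlo standard errors well
inside the asserted 3σ tolerances while keeping the full suite in the
tens of seconds.

## Known limitations

* The modified-statistic significance bands are anti-conservative for a
  fully specified uniform null (see above); the exact p column is the
  calibrated test.
* The adaptive-KDE band's replicate false-call rate at α = 0.01 is
  ≈12–14% under uniform simulation, inherent to plug-in pointwise bands
  with adaptive bandwidths.
* GRR boundaries depend on the pilot bandwidth and grid; counts of GRRs
  are not a stable quantity across bandwidth choices, only the calling
  rule is.
* Per-family dispersion flags are not multiplicity-corrected across
  families.
* Collinearity by LIS measures order conservation only; it does not
  model inversion breakpoints or segmental micro-rearrangements.
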