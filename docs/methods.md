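# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic generators do and do not emulate.

## Ortholog prediction

**Reciprocal best hits.** For every ordered (feature, partner-genome)
slot the best hit is selected by bitscore, then percent identity, then
lexicographic subject id (full determinism under ties). A pair is called
when the choice is mutual and the alignment reaches ≥ `id_min` (default
80%) identity over ≥ `cov_min` (default 0.80) of the length of **both**
sequences. Coverage is enforced bidirectionally because that is the
stricter, symmetric reading of an "80% of the length" rule; a
query-only rule would make orthology depend on search direction. Recorded
identity/coverage come from the better-ranked of the two hit directions,
so output is invariant to hit-file row order.

**Synteny confirmation and rescue.** A pair is confirmed when at least
`min_support` (default 2) of the `window` (default 5) genes flanking one
member are themselves paired with genes inside the other member's window.
A feature unpaired toward some genome is rescued through its best
sub-cutoff hit when that hit has ≥ `relaxed_id` (default 50%) identity,
the partner is also unpaired, and the same neighborhood test passes.
These thresholds are exposed parameters, not claims about any particular
published pipeline: windowed-support synteny scripts are typically
unpublished, so the defaults are conservative choices that our synthetic
fixtures validate (a 70%-identity family inside a conserved 10-gene block
is rescued; the same family in a scrambled context is not).

**Markov clustering.** Edges are hits at E ≤ 1e−5 weighted by
−log₁₀E capped at 300. Species-pair weight rescaling used by some
orthology pipelines is deliberately not reproduced; plain E-value weights
keep the graph construction transparent. The MCL iteration is column
normalization, expansion (matrix power, default 2), inflation (entrywise
power, default 1.5, then renormalization) and pruning of entries < 1e−8,
until the matrix moves by < 1e−6 or 100 iterations (non-convergence
returns the current clustering with a warning). Per-node self-loops equal
to the node's maximum incident weight are added before iterating; without
loops the power iteration can oscillate with period two on bipartite-ish
components. Clusters are the attractor sets of the limit matrix;
features with no qualifying edges are reported separately as orphans and
become singleton rows in the pan-matrix.

**Built-in aligner.** For fixtures and toy inputs an internal local
aligner (BLOSUM62, gap open −11 / extend −1) replaces an external search.
Its scores are converted to bits with gapped Karlin–Altschul parameters
(λ = 0.267, K = 0.041) and to pseudo-E-values E = mn·2^(−bits) so the MCL
edge weighting is uniform across both hit sources. These E-values are
calibrated for ranking, not significance testing.

Pseudogenes are excluded from clustering by default (`--include-pseudo`
overrides); cluster membership is binarized per genome for the pan-matrix
while copy counts are retained alongside.

## Pan-matrix accounting

For strain s: *total* = clusters present in s; *core* = clusters present
in all G strains; *distributed* = total − core (unique included, so
total = core + distributed holds row by row); *unique* = clusters present
only in s. Percentages are rounded half-away-from-zero to integers —
the convention that reproduces every printed percentage in the published
17-strain table this accounting is checked against (31.7 → 32,
44.8 → 45, 10.49 → 10). Summary standard deviations use the n−1
denominator.

## Rarefaction

Pan(g)/core(g) are counted along prefixes of random genome orderings;
means and sample standard deviations are taken over `n_perm` (default
500) orderings, with exact enumeration replacing sampling when
G! ≤ n_perm. Monotonicity (pan non-decreasing, core non-increasing) holds
within every single ordering, not only on averages; the g = G endpoints
are ordering-free and equal the observed pan and core sizes. Orderings
are drawn from a seeded PRNG for reproducibility.

## Zero-truncated binomial mixture

A pan-genome of N families falls into K classes with weights πₖ; a
class-k family is detected in each of G genomes independently with
probability ρₖ. Families observed in zero genomes are invisible, so the
observed spectrum y₁…y_G follows the truncated mixture

    P(j) = Σₖ πₖ C(G,j) ρₖʲ (1−ρₖ)^{G−j} / (1−U),   U = Σₖ πₖ(1−ρₖ)^G.

Truncation is applied to the mixture as a whole: πₖ are weights among
*all* families, observed or not. (The alternative — truncating each
component before mixing — spans the same distribution family but changes
the meaning of π and breaks the direct extrapolation formulas below.)
The pmf is verified in tests against exhaustive enumeration of all 2^G
presence patterns.

**Fitting.** EM with an explicit latent never-observed class: the E-step
computes component responsibilities for the observed counts plus the
expected number of unobserved families n₀ = n_obs·U/(1−U), apportioned to
components by πₖ(1−ρₖ)^G; the M-step sets πₖ from expected family counts
and ρₖ = expected detections / (G · expected families). This keeps the
monotone-likelihood guarantee (asserted on every iteration, tolerance
1e−6 for floating-point wobble). Default 20 random restarts with ρ starts
jittered around quantiles of the observed j/G mass; components whose
weight collapses below 1e−10 are dropped with a warning. Convergence at
|Δloglik| < 1e−9 or 2000 iterations.

**Extrapolation.** pan = round(n_obs/(1−U)); core = round(pan·Σₖπₖρₖ^G).
The core is estimated from the fitted mixture rather than by pinning a
ρ = 1 component; a pinned-core variant is available for comparison via
`fit` on a model whose K includes a fixed component. U ≥ 1−1e−12 raises:
the pan size is then unbounded and the fit non-identifiable.

**Model selection.** BIC = −2·loglik + (2K−1)·ln(n_obs) (K detection
probabilities plus K−1 free weights), minimized over K = 1…8 by default,
ties toward smaller K.

## Gene-content dendrograms

Strain distance is Euclidean on presence/absence vectors — the square
root of the number of discordant clusters, the natural geometry for Ward
linkage (which minimizes the within-cluster variance increase per merge).
Jaccard is available for sensitivity analysis. Linkage is computed with
scipy's Ward implementation (Lance–Williams update; merge heights are
monotone) and verified against an independent naive O(n³) implementation.
Partitions at a cut are invariant to strain relabeling; group labels are
assigned in leaf order.

## MLST distances, trees and dating

**Masking.** Loci are concatenated in a fixed order and every codon
column containing a gap or ambiguous base in any strain is removed for
all strains (complete deletion at whole-codon granularity — deleting
single nucleotides would break reading frames).

**Nei–Gojobori dS.** Each codon position contributes a weighted fraction
of one synonymous site: possible single-base changes are weighted R for
transitions and 1 for transversions (R = 1 recovers the unweighted
original; R is an exposed, logged parameter because the appropriate
transition bias is data-dependent). Changes that create stop codons are
excluded from both site counting and pathway averaging; codons differing
at several positions average their synonymous/nonsynonymous step counts
over all minimal substitution pathways avoiding stops (falling back to
unrestricted averaging in the rare all-blocked case). The raw proportion
p_S = synonymous differences / mean synonymous sites is Jukes–Cantor
corrected, dS = −¾·ln(1−4p_S/3); p_S ≥ 3/4 raises a saturation error.
The implementation is frozen against a hand-computed example (six TTT
codons vs TTC+5×TTT: S = 2, one synonymous difference, dS = 0.8239).

**Trees.** Neighbor joining provides the starting topology; branch
lengths are re-estimated by ordinary least squares on the leaf-pair path
matrix, and nearest-neighbor interchanges are accepted whenever the total
tree length (negative branch lengths clamped to zero) decreases — the
minimum-evolution criterion. On additive matrices this inverts the
generating tree exactly. Bootstrap resamples codon columns of the
concatenated alignment, rebuilds distances and trees, and reports the
fraction of replicates containing each leaf bipartition; saturated
replicates are skipped and count against support.

**Linearization and dating.** The tree is midpoint-rooted if needed; each
node's height becomes the mean node-to-descendant-leaf path length,
children clipped at their parent (a simple strict-clock smoothing — no
two-cluster rate test is performed). A node of height d substitutions per
site dates to t = d/r years. The height is per lineage, so no factor of
two: a pair of strains separated for t years accumulates distance r·t on
each of the two lineages, and the node height estimates exactly that.
The default r = 4.7×10⁻⁹ site⁻¹·yr⁻¹ is the classical enterobacterial
calibration; dating output is reported in Myr.

## CRISPR arrays

Repeats are matched by Hamming distance only (no indels), default
`max_mismatch` = 2 against the built-in 36-nt Lsal1 and 29-nt Ldbu1
consensi — appropriate because genuine CRISPR repeats are near-exact
copies. Matches on either strand are chained into arrays when
consecutive repeats are separated by a spacer-length gap (default
20–58 nt); arrays need ≥ 3 repeats (2-repeat candidates can be requested
separately). Spacers are reported leader-proximal first: the leader is
placed opposite the most-mismatched terminal repeat (the trailer-side
repeat is typically degenerate); when both terminal repeats are equally
mismatched the reading order of the matched strand is kept and the array
is flagged ambiguous. Detection output is invariant under
reverse-complementing the contig, up to the strand flag.

Spacer comparison clusters unique spacers at ≤ 1 mismatch (equal length,
reverse-complement aware) and reports a strain × spacer incidence matrix
plus maximal runs of contiguous shared spacers with positions counted
from the leader (position 1 = leader-proximal). Protospacer search scans
supplied target sequences for near-matches of each spacer and records the
7 nt immediately up/downstream; the flank profile reports position-wise
base counts and the IUPAC code of the smallest base set covering ≥ 90% of
observations per position, excluding (and counting) matches truncated at
contig edges.

## Synthetic generators

- `simulate_pangenome` draws family classes from π and per-genome
  presence from Bernoulli(ρₖ) — exactly the mixture the estimator
  assumes. Defaults are a 17-genome panel at pan-size 9,072 (the scale of
  the motivating 17-strain panel) with illustrative K = 3 parameters
  π = (0.45, 0.35, 0.20), ρ = (0.08, 0.55, 0.99): a rare accessory
  class, an intermediate distributed class, and a near-core class.
- `simulate_genomes` materializes a pan-matrix as proteins: one random
  ancestral sequence per family (mean length 300 aa, Poisson), each
  genome's copy mutated by uniform residue substitution at the configured
  divergence (default 2%), laid on a single contig in a global family
  order (shared families therefore form conserved synteny blocks), with
  optional further-diverged paralog copies (default probability 0.02).
- `simulate_crispr` plants repeat-spacer arrays into random contigs, with
  designated strain groups sharing specified contiguous spacer blocks.
- `simulate_mlst` evolves codon sequences along a given ultrametric tree
  (branch lengths in years) by per-site Poisson substitution at the clock
  rate, rejecting stop-creating hits.

All generators are bit-reproducible per seed and emit machine-readable
truth. **What they do not emulate:** real annotation noise (gene-calling
errors, fragmented draft assemblies, chimeric contigs), rate
heterogeneity among sites or lineages, codon usage and transition bias,
insertion/deletion evolution, repeat degeneracy gradients within arrays,
and horizontally transferred families violating the independent-Bernoulli
presence model. Passing the recovery tests therefore demonstrates
correctness of the algorithms under their own model assumptions, not
robustness to every artifact of real draft genomes.

## Problem sizes and tolerances in the test suite

The suite runs entirely on synthetic data: orthology end-to-end uses 4
genomes × 50 families at 80-aa mean gene length (the built-in aligner is
quadratic, so fixtures stay small); mixture recovery uses G = 17 spectra
at pan 9,000 over 25 seeds (median pan error < 10%); clock-age recovery
uses a 5-taxon tree, 6 × 900-nt loci, 8 seeds (median node-age error
< 15%); CRISPR oracles use ~5-kb contigs. Tolerances on stochastic
recoveries were set from the spread of repeated runs; exact oracles
(enumeration, additive matrices, planted arrays) are asserted to
numerical precision.

## Known limitations

- The observed 1,715-core / 5,935-pan counts and the 9,072/1,600
  extrapolation of the motivating 17-strain panel depend on that study's
  assemblies, annotation and clustering settings; the package treats them
  as scale anchors and verifies its arithmetic and estimators on printed
  values and simulations instead.
- OLS/NNI minimum evolution explores topologies one interchange at a
  time and can in principle stop in a local optimum on non-additive
  matrices; at MLST scale (≤ ~20 taxa) this has not been observed on
  clock simulations.
- The built-in aligner is not a substitute for a real search tool at
  genome scale; precomputed tabular hits are the intended production
  input.
- Leader-end assignment for CRISPR arrays is heuristic (terminal repeat
  degeneracy); arrays with pristine terminal repeats at both ends are
  flagged rather than resolved.
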