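# Methods

## Model and rationale

Let x_s(g) be the expression of miRNA g in sample s. The only primitive the
core method uses is the within-sample ordering x_s(i) > x_s(j), which is
invariant under any strictly increasing per-sample transform — so platform
scale, normalisation and monotone batch distortions cannot change it.

Whole blood is modelled as a convex combination of leukocyte-subtype
profiles on the linear scale: x_blood = Σ_c p_c · x_c with proportions
p_c >= 0, Σ p_c = 1. If x_c(i) > x_c(j) in every subtype c, then
x_blood(i) > x_blood(j) for *every* proportion vector. Orderings stable
across all purified subtypes are therefore fixed points of mixing, and a
reversal of such an ordering in disease blood implies an intracellular
expression change, not a composition shift. That implication is the entire
inferential content of the method; everything else is counting and exact
tests.

## Procedure and statistical details

1. **Stable-pair mining.** A pair is stable when the strict ordering holds in
   every individual sample of every subtype. Ties count as a violation
   (consistent with treating "i <= j" as the complementary event
   everywhere). A per-subtype-mean reading is available
   (`per_subtype_mean=True`) but is not the default: the per-sample reading
   is the most stringent and standard in the rank-based literature. Pair
   sets from independent purified panels are intersected requiring identical
   orientation. Output order is lexicographic by (upper, lower) so files are
   reproducible.
2. **Consistency filter.** Retention requires maintenance in >= `min_frac`
   (default 0.9) of healthy whole-blood samples, boundary inclusive (a pair
   kept in exactly 90% of samples passes).
3. **Reversal test.** Per pair, the 2x2 table [[n1, m1], [n2, m2]] of
   maintained/lost counts in healthy/disease samples is tested with the
   two-sided Fisher exact test (scipy), with BH correction across all tested
   pairs — the population actually submitted to the test, i.e. everything
   that passed the consistency filter. Selection applies three inclusive
   criteria jointly: P_healthy >= 0.9, dP = P_healthy − P_disease >= 0.15,
   FDR <= 0.05. dP is signed, so only loss of the healthy orientation can
   qualify; the two-sided test plus the directional dP gate keeps the test
   conservative without a one-sided choice.
4. **Iterative extraction.** Each candidate miRNA's contingency aggregates
   the raw events expr(miRNA) > expr(partner) over all (partner, sample)
   combinations, where partners are all features paired with the candidate
   in the filtered reference set (reversal pairs are a subset of these, so
   counting spans stable and reversal pairs alike; `universe="reversal"`
   restricts counting to the current reversal partners). The minimum-p
   candidate is extracted; ties break first toward more reversal-pair
   memberships, then lexicographically, making the loop fully deterministic.
   Direction uses cross-products (down iff n1·m2 > n2·m1) to avoid division
   by zero; exact equality leaves the direction undetermined and the
   candidate is skipped for that iteration. The loop runs until the reversal
   set is empty — there is no significance floor inside the loop; users
   filter the output by its BH q-values.
5. **Permutation null.** Labels are shuffled preserving group sizes; the
   full test-and-select chain is rerun per permutation. The pairwise
   ordering matrix is computed once and only the partition is resampled,
   which is numerically identical to a from-scratch rerun.

Supporting operations: subtype marker signatures come from one-vs-rest
Welch's t-tests on log2 values with BH FDR per comparison, keeping features
with log2FC >= 0.26 (1.2-fold) and FDR <= 0.05, upregulation only — Welch's
t replaces a moderated-variance linear model deliberately; at the group
sizes involved the selection semantics are equivalent and the dependency
footprint smaller. The same test is the naive whole-blood baseline
(`two_group_de`). ssGSEA scores use the rank-weighted ECDF difference with
exponent alpha = 0.25, average ranks for ties, and no cross-sample min-max
rescaling (raw enrichment scores); scores depend only on within-sample
ranks. Overlap significance is the upper-tail cumulative hypergeometric
probability, accumulated in log space to stay accurate down to ~1e-300.

## Synthetic data generator

The simulator produces the two data shapes the workflow consumes, with full
ground truth.

*Purified panels.* Feature baselines are drawn once, log2 ~ N(6, 2.0) —
a realistic dynamic range for array intensities. Each subtype adds an
independent N(0, 0.2) deviation, each subtype's 10 markers get +4 log2
(16-fold), and samples add N(0, 0.15) measurement noise (replicate-level
array noise). The subtype deviation is deliberately kept at the same scale
as the noise: the premise of the reference-pair construction is that the
miRNA rank hierarchy is strongly conserved across leukocyte subtypes, so
stable pairs exist across the whole margin continuum — including the small
margins a 1-log2 intracellular change can reverse. Larger subtype
heterogeneity leaves only wide-margin pairs stable and makes *any* modest
intracellular effect invisible to the reversal test, which contradicts the
structure the method targets.

*Whole blood.* Per sample, proportions are drawn from a Dirichlet with mean
at a typical adult leukocyte composition (neutrophils 0.50, T 0.22,
monocytes 0.10, B 0.07, NK 0.07, eosinophils 0.04) and concentration 60
(coefficient of variation ≈ 13% for the neutrophil fraction). Mixing is on
the linear scale; disease spikes multiply the affected subtypes'
contributions by 2^shift *before* mixing, so the blood-level effect size of
a spike scales with the subtype's proportion — exactly the attenuation that
makes intracellular signals hard to detect; noise is added on the log scale
after mixing. Default cohorts are 100 healthy + 100 disease samples, 300
features, six subtypes × five purified samples — desk-scale sizes chosen so
the full chain runs in ~1 s per cohort while keeping the Fisher tests well
inside their asymptotic-free regime.

Three canonical scenarios are provided: `null_config` (no effect),
`composition_shift_config` (Dirichlet means of neutrophils/T cells moved by
∓0.12, no spikes) and `intracellular_spike_config` (identical priors, ten
non-marker features spiked ±1 log2 in the two most abundant subtypes, both
of mean proportion >= 0.15).

*What the generator does not emulate:* probe-level effects, background
correction, batch structure, inter-individual baseline variation of the
purified profiles, serum/exosome compartments, and correlated (co-regulated)
miRNA programs. Passing tests on this generator therefore demonstrate the
logical behaviour of the method under its own mixture model — composition
robustness, spike recovery, null calibration — not its operating
characteristics on any real platform.

## Numerical choices

- Fisher exact p-values are memoised per table; all tables in a run share
  margins, so at most (n_healthy+1) × (n_disease+1) distinct tables occur.
- BH adjustment via statsmodels' step-up implementation.
- Ties in expression count against maintenance everywhere (mining, filter,
  reversal counts, contingencies), one consistent convention.
- ssGSEA walks features in descending expression with ties ordered by
  feature index; tie *weights* use average ranks, so scores are
  deterministic and rank-invariant.
- The loaders reject missing values by default (row-mean imputation is
  opt-in) because silent missingness corrupts pair counts; duplicate
  identifiers and many-to-one renames are hard errors.
- Degenerate inputs: a feature constant in both groups gets p = 1 in the
  Welch tests; an empty reversal set yields an empty extraction (not an
  error); `fdr_max = 0` selects nothing.

## Known limitations

- The reference construction needs purified panels covering the subtypes
  that actually vary in blood; a missing abundant subtype re-opens the
  composition confound for pairs unstable in it.
- Extraction p-values aggregate over (partner, sample) events that are not
  independent (one sample contributes many partner events), so they are
  selection scores rather than calibrated tail probabilities; the q-values
  order candidates sensibly but should not be read as strict FDR on real
  data.
- With a single reversal pair and no stable-partner context, the two pair
  members are statistically symmetric; attribution then rests on the
  tie-break. More reversal partners resolve this quickly.
- The quadratic pair enumeration is fine to a few thousand features but is
  O(F²·S) in time and O(F²) in memory beyond that.
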