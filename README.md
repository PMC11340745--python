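# refmireo

Reference-based relative-expression-ordering (REO) detection of
leukocyte-derived differential miRNAs in whole-blood samples.

## The problem

Whole blood is a mixture: its measured miRNA expression is, on the linear
scale, a proportion-weighted composite of the expression profiles of the
circulating leukocyte subtypes (neutrophils, monocytes, T/B/NK cells, ...).
Disease states routinely shift those proportions — e.g. fewer myeloid cells,
more lymphoid cells — so a naive case/control differential test on whole
blood flags many miRNAs whose expression never changed *inside* any cell; the
mixture weights changed instead. `refmireo` is for researchers who want blood
miRNA markers that reflect genuine intracellular regulation, which is the
signal that survives replication and carries mechanistic meaning.

## The method

The package works on within-sample relative expression orderings, which are
invariant to any strictly monotone per-sample normalisation:

1. **Reference stable pairs.** From panels of purified leukocyte subtypes,
   mine every oriented miRNA pair (i, j) with expr(i) > expr(j) strictly in
   every sample of every subtype; intersect the pair sets of independent
   panels (same orientation required). Because a convex combination of
   profiles preserves any ordering shared by all components, these orderings
   are fixed points of mixing: no proportion shift alone can reverse them.
2. **Consistency filter.** Keep pairs maintained in at least 90% of healthy
   whole-blood samples (P_healthy(i > j) >= 0.9).
3. **Reversal pairs.** For each reference pair count healthy samples that
   maintain (n1) / lose (m1) the ordering and likewise for disease (n2, m2).
   Test [[n1, m1], [n2, m2]] with a two-sided Fisher exact test,
   Benjamini-Hochberg across all pairs, and select pairs with
   P_healthy >= 0.9, dP = P_healthy − P_disease >= 0.15 and FDR <= 0.05.
4. **DE miRNA extraction.** For every miRNA in a reversal pair, aggregate the
   raw events expr(miRNA) > expr(partner) over all its stable-pair partners
   and all samples into a healthy-vs-disease contingency table; extract the
   minimum-Fisher-p miRNA, call its direction by the cross-product rule
   (down in disease iff n1·m2 > n2·m1), remove its reversal pairs, and
   repeat until none remain. q-values are BH over the extracted list.

A label-permutation null, ssGSEA composition scoring of subtype marker
signatures, the naive Welch-t differential baseline, cumulative
hypergeometric overlap tests, and a synthetic whole-blood mixture simulator
with known ground truth round out the toolkit.

## Worked example

Simulate a cohort in which ten miRNAs are shifted by ±1 log2 unit inside the
two most abundant leukocyte subtypes (no proportion change), then run the
full chain:

```python
from refmireo import *
from refmireo.synth import intracellular_spike_config

cfg = intracellular_spike_config(seed=1)
leuk, leuk_ann, truth = generate_leukocyte_profiles(cfg)
blood, blood_ann, truth = generate_whole_blood(truth, cfg)

pairs = stable_pairs_within(leuk, leuk_ann)
healthy = blood.subset_samples(blood_ann.samples_in_group("healthy"))
reference = filter_by_consistency(pairs, healthy, min_frac=0.9)
reversals = select_reversals(reversal_stats(reference, blood, blood_ann))
de = extract_de_mirnas(reference, reversals, blood, blood_ann)

print(f"stable pairs: {len(pairs)}  after consistency filter: {len(reference)}")
print(f"reversal pairs: {len(reversals)}")
for d in de[:5]:
    print(f"{d.iteration}  {d.mirna}  {d.direction:>4}  p={d.p_value:.3g}  q={d.q_value:.3g}")
rep = evaluate_recovery(de, truth)
print(f"sensitivity={rep.sensitivity:.2f}  FDP={rep.false_discovery_proportion:.2f}  "
      f"direction accuracy={rep.direction_accuracy:.2f}")
```

Output:

```
stable pairs: 29781  after consistency filter: 29778
reversal pairs: 124
1  syn-miR-084    up  p=6.18e-216  q=6.18e-215
2  syn-miR-127    up  p=3.63e-52  q=1.81e-51
3  syn-miR-027    up  p=1.49e-32  q=4.96e-32
4  syn-miR-186    up  p=6.7e-28  q=1.58e-27
5  syn-miR-276  down  p=7.92e-28  q=1.58e-27
sensitivity=0.90  FDP=0.00  direction accuracy=1.00
```

29,781 pairs are stably ordered across all six purified subtypes; nearly all
survive the 90% healthy-blood consistency filter. The disease cohort reverses
124 of them, and iterative extraction attributes the reversals to individual
miRNAs: 9 of the 10 spiked miRNAs are recovered (none falsely), every
direction call matching the simulated ground truth. Run the same cohort
through `two_group_de` to see the contrast: under a pure proportion shift the
naive test flags ~20 miRNAs while `extract_de_mirnas` returns none.

The same stages are available from the shell:

```sh
refmireo simulate --scenario spike --seed 1 --out-dir sim/
refmireo run --leukocyte-expr sim/leukocytes.tsv --leukocyte-ann sim/leukocytes_annotation.tsv \
             --blood-expr sim/blood.tsv --blood-labels sim/blood_annotation.tsv --out-dir run/
refmireo overlap-test -N 777 -K 112 -n 78 -k 27
```

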