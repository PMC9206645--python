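# mcnkit

Maturational covariance network (MCN) analysis for neonatal brain
development, with a synthetic-cohort generator that makes the whole
pipeline testable without clinical MRI data.

## The problem

Extremely preterm infants (born before 28 weeks of gestation) spend their
"third trimester" in a neonatal intensive care unit, exposed to stressful
invasive procedures (heel lances, line insertions, ventilation,
suctioning). A way to ask whether that early-life stress reshapes brain
development is to look at *maturational coupling*: how similarly pairs of
brain regions grow between two MRI scans (around 30 and 41 weeks
post-menstrual age). `mcnkit` implements this analysis for 32 gray-matter
regions belonging to three canonical large-scale networks — the salience
network (SN, 12 nodes), default-mode network (DMN, 12 nodes) and executive
control network (ECN, 8 nodes).

## The method

For each subject and region, the weekly growth rate is

    rate = ((v2 − v1) / v1) / (age2 − age1)

with volumes in mm³ and scan ages in weeks. Clinical covariates (gender,
total brain volume, gestational age at birth, scan ages, intraventricular
hemorrhage, surgeries, pre-/postnatal corticosteroids, days of morphine)
are removed per region by OLS; the externally studentized residuals are
kept. Within each stress-exposure group (median split of the standardized
invasive-procedure score, weighted per day of NICU stay), the 32×32
association matrix holds the across-subject Pearson correlation
r_ij between regions i and j (zero diagonal), Fisher-transformed to
z = atanh(r).

Both groups' matrices are binarized at the same density K by keeping the
m = round(K·496) strongest edges. Per network block (within-SN,
within-DMN, within-ECN, SN–DMN, SN–ECN, DMN–ECN) the retained-edge
difference Δ = count_high − count_low is tested against a permutation null
(group labels reshuffled, full pipeline recomputed) with the two-tailed
smoothed p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (1 + n_perm), BH-FDR corrected
over the six blocks, swept over 0.10 ≤ K ≤ 0.30 and reported at K = 0.20.
A secondary edge-level comparison uses the independent-samples Fisher
r-to-z statistic Z = (z_high − z_low) / √(1/(n_high−3) + 1/(n_low−3)),
excluding edges with |r| < 0.10 in both groups.

## Worked example

```python
import mcnkit as mk

cohort = mk.simulate_cohort(mk.stress_effect_config(n_per_group=90), seed=7)
scores = mk.compute_stress_scores(cohort.stress["procedure_count"],
                                  cohort.stress["nicu_days"],
                                  subject_ids=cohort.stress.index)
labels = mk.assign_groups(scores, "median")          # 90 low / 90 high
rates  = mk.prepare_rates(cohort.volumes, cohort.covariates)
res    = mk.permutation_test(rates, labels, K_values=[0.20],
                             n_perm=2000, seed=8).set_index("block")
print(res[["delta", "p", "q"]])
```

prints

```
            delta         p         q
block
within_SN      62  0.000500  0.001499
within_DMN    -51  0.000500  0.001499
within_ECN      3  0.777111  0.777111
SN_DMN        -14  0.012994  0.025987
SN_ECN          1  0.655172  0.777111
DMN_ECN        -1  0.573213  0.777111
```

The generator planted a higher within-SN coupling (+0.3 on the rate
correlation), lower within-DMN (−0.3) and lower SN–DMN (−0.2) in the
high-stress group, and the pipeline recovers exactly that pattern:
positive Δ means more retained edges (tighter maturational coupling) for
the high-stress group at equal network density, and the three planted
blocks are the three significant ones after FDR.

The same workflow is available from the shell:

```
mcnkit simulate --seed 7 --out cohort/
mcnkit score --procedures cohort/stress.csv --scheme median --out groups.csv
mcnkit build-rates --volumes cohort/volumes.csv --covariates cohort/covariates.csv --out rates.csv
mcnkit compare-networks --rates rates.csv --groups groups.csv \
    --densities 0.10:0.30:0.01 --report-density 0.20 --n-perm 5000 --seed 8 --out results/
```

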