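# Methods

## Model and procedure

`mcnkit` analyzes *maturational covariance*: the tendency of pairs of
brain regions to grow at correlated rates across subjects. The pipeline
has five stages, each of which is a separate module with its own surface.

1. **Stress scoring** (`stress`). The cumulative count of invasive NICU
   procedures up to the first scan is divided by the length of the NICU
   stay (procedures per day), then standardized over the cohort. The
   division reading of "weighted on the duration of stay" is the standard
   rate interpretation; regression adjustment would be the alternative and
   is intentionally not implemented. Standardization uses the population
   SD (divisor n) by default, switchable via `ddof`. Groups come from a
   median split (primary), a zero-mean split (score < 0 vs ≥ 0), or a
   rank-based tertile split. Ties at a boundary are broken by sorting on
   (score, subject id), so group sizes are reproducible; with odd n the
   extra subject goes to the lower group, and remainders of the tertile
   split go to the lower groups first (180 → 60/60/60).

2. **Trajectories** (`trajectories`). The per-region growth rate is
   `((v2 − v1)/v1)/(age2 − age1)` — volume change normalized on the first
   scan, per week. Rates are computed first and then residualized on the
   covariates (the "studentized trajectory"); the alternative order,
   studentizing each timepoint's volumes before differencing, is available
   as `order="residualize_volumes"` but is not the default because
   annualization already absorbs inter-scan-interval differences.
   Residualization is OLS per region on an intercept plus ten columns:
   gender, total brain volume (taken at scan 1, a baseline normalizer),
   gestational age at birth, both scan ages (the design lists "age at
   scan" once but two scans exist; entering both is the conservative
   choice), IVH (binary), surgeries, prenatal and postnatal
   corticosteroids, days of morphine. The default residual is *externally*
   studentized — t_i = e_i / (s₍₋ᵢ₎ √(1 − h_ii)) with the leave-one-out
   SD in closed form from the hat diagonal — matching the strict meaning
   of "studentized"; internal standardization and raw residuals are
   options. A leverage of exactly 1 (e.g. a binary covariate with a single
   minority subject) makes the residual undefined and raises an error
   naming the subject rather than silently producing infinities.

3. **Covariance networks** (`covariance`). The group's association matrix
   is the across-subject Pearson correlation of studentized rates for
   every region pair, diagonal set to zero, with Fisher z = atanh(r)
   alongside. Perfect correlations — possible only in tiny synthetic
   fixtures — are clipped to ±(1 − 1e−7) before atanh with a logged
   warning; inside permutation loops, correlations that are undefined
   because a permuted column is constant are set to 0 under the same
   clipping convention, which keeps the loop alive on degenerate draws and
   is never triggered at realistic sample sizes.

4. **Network-level inference** (`inference`). At density K both groups
   retain their m = ⌊K·496 + 0.5⌋ strongest edges (signed z descending —
   strong *positive* covariance defines coupling; absolute-value ranking
   would conflate coupling with anti-coupling), ties broken by pair order
   for determinism. Retained edges are counted in the six network blocks;
   because both groups keep exactly m edges the six Δ values sum to zero,
   which is asserted on every call. Significance comes from reshuffling
   the group labels (sizes preserved) and recomputing the entire
   build→threshold→count pipeline, with the add-one smoothed two-tailed
   p = (1 + #{|Δ_perm| ≥ |Δ_obs|})/(1 + n_perm). BH-FDR is applied across
   the six blocks within one density (the narrowest defensible family; a
   sweep-wide family would mix 21 highly dependent copies of the same six
   tests). The Σ Δ = 0 constraint makes the six tests dependent; BH
   remains valid under this kind of positive dependence. The sweep runs
   0.10 ≤ K ≤ 0.30 in 0.01 steps with results reported at K = 0.20; the
   per-block consistency flag is the fraction of densities whose Δ sign
   *and* significance status match the reporting density.

5. **Edge-level inference** (`edges`). Each pair's correlations are
   compared with the independent-samples statistic
   Z = (atanh r_high − atanh r_low)/√(1/(n_high−3) + 1/(n_low−3)) and a
   two-sided normal p. Edges below the spurious-correlation threshold
   (default 0.10) are excluded only when |r| < 0.10 in *both* groups:
   excluding on either group would hide exactly the decoupling effects of
   interest (strong in one group, collapsed in the other). The filter uses
   |r|, not signed r, so strong negative correlations are not silently
   dropped. FDR is taken over all included edges of one run.

## Synthetic cohorts

The generator (`simulate`) emulates the statistical skeleton the analysis
assumes, not images or segmentation. Per group, latent weekly growth
rates are multivariate normal with a block-constant correlation matrix
(within- and between-network targets). Arbitrary block targets need not
be jointly positive semi-definite; the matrix is repaired by eigenvalue
clipping and re-standardization to unit diagonal, the repair is logged,
and the matrices actually used are stored in the cohort's ground truth.

Scales mimic the target population: birth gestational age ~ N(26.64,
0.99) truncated to [24, 28) weeks (truncation pulls the realized mean to
≈ 26.5), scans at ~30 and ~41 post-menstrual weeks with enforced
ordering, 43.3 % female, morphine exposure exponential with mean
3.14 days. Volumes are built as v1 ~ N(2500, 400) mm³ and
v2 = v1·(1 + rate·Δweeks), so recomputing rates from the written volumes
recovers the planted rates exactly. The default mean rate is 0.05/week
with residual SD 0.012 — volumes grow ≈ 55 % over the ~11-week interval,
a scale-plausible placeholder for rapid third-trimester gray-matter
growth; no empirical rate distribution is available to match. Covariate
confounding is a linear effect of z-scored covariates added uniformly to
all regions (default: small gestational-age and gender effects), which
the residualization stage should and does remove. Invasive-procedure
counts are Poisson with intensity 1.5/day (low group) vs 3.0/day (high
group) over the simulated NICU stay, so the high group's standardized
stress score stochastically dominates and a median split recovers the
true labels with ≈ 98 % accuracy; only this rank structure matters
downstream.

Two stock configurations exist: `null_config` (identical structure in
both groups, within 0.40 / between 0.20) for calibration, and
`stress_effect_config` with low-group targets SN 0.30, DMN 0.60, ECN
0.40, SN–DMN 0.35 (other cross-blocks 0.15) and high-group targets SN
0.60, DMN 0.30, SN–DMN 0.15 — i.e. planted differences of +0.3 within-SN,
−0.3 within-DMN and −0.2 SN–DMN, with base levels chosen so both matrices
are PSD without repair.

What the generator does *not* model: measurement error in the volumes
beyond rate noise, heavier-than-Gaussian rate tails, missing data,
regional heterogeneity of baseline volume or growth, and any spatial
autocorrelation between neighboring regions. Passing tests therefore
demonstrate the statistical machinery under the model's own assumptions,
not robustness of the scientific conclusion on real MRI data.

## Numerical choices and problem sizes

* m uses half-up rounding (⌊x + 0.5⌋), so K = 0.20 keeps 99 of 496 edges.
* Thresholding ranks z, which is monotone in r; the choice is
  output-irrelevant and made for symmetry with the edge statistics.
* Permutation p-values are smoothed (add-one), hence never zero, and
  integer-valued Δ makes them mildly conservative: under a null
  simulation at 200 permutations the measured per-block type-I error is
  ≈ 0.04–0.05 against the nominal 10/201 ≈ 0.0498.
* The test suite calibrates type-I error over 2000 null cohorts of
  45 + 45 subjects at 200 permutations each, and checks sign recovery of
  the planted pattern over 100 cohorts of 90 + 90; the acceptance script
  uses 2000 permutations for the headline sweep and 300 null cohorts for
  the calibration figure. These sizes put Monte-Carlo error well below
  the tolerances being asserted while keeping a full run under a minute.
* Degenerate synthetic cohorts (a binary covariate constant in all but
  one subject gives that subject leverage 1) are rejected by the
  residualizer with an explicit error; replicate loops redraw such
  cohorts from a derived seed. At the default covariate frequencies this
  affects roughly 0.2 % of draws.

## Known limitations

Group-level association matrices admit no per-subject network, so
inter-individual variability is out of reach by design. The six block
tests share one edge budget and are negatively coupled; interpreting a
single block's Δ in isolation ignores that retained edges are a zero-sum
resource. The edge-level Z compares two independent correlations and is
not valid for overlapping groups (e.g. tertile pairs sharing subjects).
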