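# Methods

## The integrated score

Each evidence component produces per-protein metric values with a declared
ranking direction. Within a component the proteins detected there are
ranked 1..x (ties receive the average of the covered positions, so every
rank vector sums to x(x+1)/2), and the integrated score of a protein is
the weighted mean of its component ranks, `Rscore = Σ r_i c_i / n`, with
smaller scores better. With all weights equal this is Borda-style
mean-rank consensus, which the test suite verifies against a brute-force
mean-rank oracle.

Defaults and their rationale:

* **Weights `c_i` = 1 for every component.** Weights are part of the
  config (`RscoreConfig.components`) and every run echoes them into the
  report provenance. No principled weighting was available, so the uniform
  default keeps the score interpretable as a mean rank.
* **`missing_policy = intersection`** (n = number of weighted components;
  only proteins ranked in all of them are scored). This matches the
  workflow of first intersecting the proteins detected in every dataset
  and then scoring the overlap. `adjusted_n` (per-protein n = number of
  available components) is provided for sparser inputs.
* **`rank_scale = absolute`.** Raw ranks match the score's definition, but
  components of very different size are then not commensurable: a rank of
  20 means something different in a 35-protein component than in a
  100-protein one. When component sizes differ by more than 2x the report
  carries a provenance note suggesting `rank_scale = percentile`
  (ranks divided by x before weighting).
* **Ties** in metric values get average ranks; ties in the final Rscore
  are broken lexicographically by accession so output is deterministic.

The pipeline ranks abundance and tumor-specificity over all proteins
detected in each dataset (after the gene-set restriction), intersects the
detected sets, and carries only the intersected candidates into the
survival stage — mirroring a workflow in which the overlapped top
candidates are the ones queried against clinical cohorts. The three
specificity statistics (p, fold change, absolute change) enter as three
separately weighted components; collapsing them into one can be emulated
by setting each weight to 1/3.

## Abundance normalization

`abundance_p = counts_p / (length_p / median(lengths))`, where counts are
the protein's summed values over the dataset's non-normal samples and the
median is over the proteins present in that dataset (midpoint convention
for even counts). Summing across samples, rather than averaging
per-sample normalized values, is the package's reading of per-dataset
spectral counting; it is deterministic and scale-equivalent. The
normalization is exactly invariant to rescaling all lengths and
homogeneous of degree one in counts (both property-tested). PSM-count and
spectral-count datasets are treated identically.

## Tumor specificity

Per protein: `abs_change = mean(tumor) − mean(normal)`,
`ratio = (mean(tumor)+ε)/(mean(normal)+ε)`, and a two-sided Welch
(unequal-variance) t-test on `log2(value+ε)`. Welch-on-logs is the
standard choice for MS intensity comparisons; the default pseudocount ε is
half the smallest nonzero abundance in the dataset, which keeps the zero
handling scale-aware. Proteins detected in only one group keep ratio and
absolute change (the undetected group's mean is 0) but get no p-value;
two identical constant groups get p = 1 by the zero-t-statistic
convention. No multiple-testing adjustment is applied because the score
consumes rank positions, which are invariant under any monotone
adjustment of p-values. Under the null the Welch p-value is calibrated
(type-I error 5% ± 1.5% at α = 0.05 in the suite's 2,000-protein
simulation with n = 5 per group).

## Survival association

* **Kaplan–Meier** estimation is delegated to lifelines and checked
  against hand-applied product-limit values.
* **Log-rank (Cox-Mantel)** is implemented in the package (the cutoff
  scan calls it in a tight loop) using exact hypergeometric moments per
  distinct event time; it is verified to 1e-10 against an independent
  risk-table oracle and against lifelines.
* **Hazard ratio** comes from a single-binary-covariate Cox
  partial-likelihood fit with Breslow tie handling, solved by safeguarded
  Newton iteration to 1e-8 on β. Monotone likelihoods (for example all of
  one group's events preceding the other's first event, or an eventless
  group) have no finite maximizer; such fits are flagged non-estimable
  and the protein is excluded from the survival components. The fit is
  verified against a grid-search maximization of the written-out partial
  likelihood and against lifelines on tie-free data.
* **Best-cutoff scan**: candidate cutoffs are the distinct observed
  expression values within the 10th–90th expression quantiles whose split
  ("high" = strictly greater than the cutoff) leaves both groups at least
  `max(5, 10% of cohort)` patients; the cutoff minimizing the log-rank p
  is selected, ties breaking toward the smaller cutoff. The scan is
  asserted identical to exhaustive brute force on seeded instances.

The scanned minimum p-value is **anti-conservative**: scanning many
cutoffs inflates type-I error, and no multiplicity correction is applied
(matching the cited plotting service's behavior). The p-values are
therefore ranking statistics, not calibrated tests; null calibration is
asserted only for a fixed median split (5% ± 1.5% over 2,000 simulated
null cohorts of n = 200). Proteins whose best split gives HR ≤ 1 cannot
show the adverse direction an oncogenic ranking requires; they stay in
the results table but are assigned worst-case component values (p = 1,
HR value 0) so every candidate keeps a complete rank vector.

## Synthetic studies

The generator emulates the statistical structure the pipeline consumes;
defaults (in `SyntheticParams`): 500 proteins, a 150-member gene set, 3
drivers; protein lengths log-normal(ln 400, 0.5) floored at 50 aa; base
abundances log-normal(ln 10, 1); counts negative binomial with
`var = µ + 0.2 µ²` and `µ = abundance × (length / median length) × depth`,
sample depths log-normal(0, 0.25). One tissue dataset (6 tumor + 6
normal samples), two cell-line datasets and one CTC dataset (3 samples
each) — sample counts chosen as typical small MS study sizes. Detection
dropout is protein-level per dataset, logistic in log abundance with
midpoint at the 20th abundance percentile and unit slope. The cohort has
200 patients; expression is log-normal around each protein's base
abundance; hazards are exponential at 0.02 per time unit, multiplied by
`hr_true = 2.5` above each driver's median expression, with censoring
uniform on (0, 60].

Drivers carry all three signals: base abundance drawn from above the 75th
percentile (`driver_abundance_quantile`), a tumor fold change of 4 in the
tissue dataset, and the expression-dependent hazard. They are exempt from
dropout so they are scoreable in every dataset — the pipeline only scores
proteins detected everywhere, and recovery experiments need the planted
truth to be scoreable. Because planted high abundance is itself a
distinguishing signal, the signal-free null condition used in the tests
sets `tumor_fold = 1`, `hr_true = 1` *and*
`driver_abundance_quantile = None`; under it, all-three-drivers-in-top-5
recovery collapses to the hypergeometric chance level. Counts scale with
length by construction, so the length normalization is exercised
non-trivially: a long protein with more raw spectra but lower molar
abundance must not outrank a shorter one (asserted as a fixture).

One global seed fans out through `numpy.random.SeedSequence.spawn` to
independent per-dataset streams; identical seeds give bit-identical
studies, and adding a dataset does not perturb the others.

What the generator does **not** emulate: peptide-level sampling,
retention-time or spectral realism, batch effects, correlated protein
modules, paired tumor/normal designs, informative censoring, or
missing-not-at-random intensity-dependent censoring *within* a detected
protein. Passing recovery tests therefore demonstrates the pipeline's
correctness and sensitivity under idealized signal structure, not
performance on real cohorts.

With the default conditions, all three drivers reach the top 5 in roughly
95 of 100 seeded studies; the shortfall comes from drivers legitimately
planted near the 75th abundance percentile, which places them mid-pack on
the abundance components.

## Numerical choices and degenerate inputs

* Missing-value token `NA`, decimal point `.`, UTF-8, tab-separated
  throughout; duplicate gene symbols within one dataset collapse to the
  row with the highest total abundance (logged).
* Welch p-values are floored at 1e-300 so zero-variance-unequal-means
  degeneracies stay inside (0, 1].
* Log-rank returns (χ² = 0, p = 1) when no events exist; an empty group is
  an error.
* Cox β is clipped per Newton step to ±2 for stability and declared
  non-estimable beyond |β| > 20.
* Constant expression or no admissible split raises `NoValidCutoff`; an
  empty cross-dataset intersection yields an empty report and exit code 0.
* Problem sizes in the test suite (e.g. 2,000 null cohorts of n = 200,
  200 Cox-recovery cohorts of n = 1,000, 100 end-to-end studies) were
  chosen to give decisive Monte-Carlo bounds at small desk-scale runtimes.

## Known limitations

* Absolute ranks across datasets of very different detected-protein
  counts bias the aggregate toward large components (see `rank_scale`).
* The best-cutoff p-value is optimistically biased by design; downstream
  interpretation should treat it as a prioritization signal.
* Isoform/accession collapse to one entry per gene symbol is a package
  convention; other collapse rules (e.g. summing isoforms) are not
  implemented.
* Only two-group, single-covariate survival comparisons are supported —
  no multivariable Cox models, time-varying covariates or competing
  risks.
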