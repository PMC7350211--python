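# Methods

## The model

Dynamic network biomarker (DNB) theory describes a reproducible
statistical signature of a system approaching a critical transition: a
small, dominant group of molecules (the DNB module) whose

1. standard deviations inflate strongly,
2. mutual correlations (in absolute value) rise sharply, and
3. correlations with molecules outside the group collapse.

The landscape DNB (l-DNB) construction makes this signature measurable in
a *single* sample, which is what clinical use requires. It has two layers.

### Single-sample networks

Given `n` reference samples (here, the control group), the reference
correlation of molecules x and y is the Pearson coefficient `PCC_n(x,y)`.
Adding one new sample `d` and recomputing gives `PCC_{n+1}(x,y)`; the
differential correlation

    sPCC_n(x, y) = PCC_{n+1}(x, y) - PCC_n(x, y)

measures how much the single sample `d` perturbs that pair's correlation.
The standardized statistic is

    z = sPCC_n * (n - 1) / (1 - PCC_n^2).

Under the null that `d` comes from the reference distribution, `z` is
asymptotically (in `n`) distributed as the *product of two independent
standard normals* — the heavy-tailed "volcano" distribution with density
`K0(|t|)/pi` — because the dominant term of the perturbation is
`z_x * z_y / n`, the product of the new sample's standardized deviations.
That product does **not** become Gaussian as `n` grows; treating `z` as
standard normal rejects at ~7.7% instead of the nominal 5% (measured at
n = 50). Edge p-values therefore default to the exact product-normal
tail, computed from the closed form
`P(|Z| > t) = 1 - t*(K0(t)*L_{-1}(t) + K1(t)*L_0(t))`
(modified Bessel/Struve functions); a standard-normal option
(`tail="normal"`) and a bootstrap-resampling option
(`tail="permutation"`, an extension for very small references) are kept.
The measured null rejection rate of the default test at alpha = 0.05,
n = 50 is ~0.055 (batched over fresh reference draws): slightly
anticonservative because the reference moments are themselves estimated,
which the limiting law ignores.

Molecule pairs with `p < alpha` (default 0.05, uncorrected, as a
selection rule rather than an inference) form the sample's SSN. Pairs
with `|PCC_n| = 1` are degenerate for this statistic and are excluded
and logged; molecules constant across the reference are dropped up
front.

### Local and global DNB scores

For each molecule x with first-order SSN neighbors `N_x` (size `n_x`) and
second-order neighbors `M_x` (size `m_x`; neighbors-of-neighbors minus x
and `N_x`, so the sets are disjoint by construction), the three DNB
conditions are estimated per sample as

    sAD_in   = mean |deviation from reference mean| over {x} ∪ N_x
    sPCC_in  = mean |sPCC(x, y)|, y in N_x
    sPCC_out = mean |sPCC(y, z)|, y in N_x, z in M_x  (all pairs,
               significant or not)

and combined into the local DNB score

    Is(x) = sAD_in * sPCC_in / max(sPCC_out, 1e-6).

Only molecules with `n_x >= 3` and `m_x >= 1` are scored. The sample's
global DNB score is the arithmetic mean of its local scores over exactly
the eligible molecules; a sample with no eligible module gets 0 with a
warning. Individuals with a global score above 1.0 are flagged high-risk.

Design choices behind this, where the design was genuinely open:

- **Ratio vs product.** The score combines the three conditions so that
  a *rising* `sPCC_out` should *lower* the score (condition 3 is a
  decrease). The classical multi-sample DNB index is
  `SD_in * PCC_in / PCC_out`; we use the analogous ratio form as default
  and keep `score_form="product"` for the bare three-factor product.
- **Absolute values.** Conditions 2–3 are stated on correlations in
  absolute value; signed averaging would let opposite-signed
  perturbations cancel. `|sPCC|` is the default, `absolute_spcc=False`
  the signed alternative.
- **Standardization.** Abundances are z-scored per molecule against the
  reference mean/SD before deviations are taken (default). Metabolite
  intensities span orders of magnitude; without standardization the
  global score's scale — and any fixed high-risk cutoff — would be
  dominated by the brightest ions. Raw-scale deviations
  (`standardize=False`) reproduce the formulas verbatim.
- **sPCC_out floor.** `epsilon = 1e-6` guards the ratio against a
  denominator that is numerically zero when a module has a single
  near-zero cross pair; floored modules are counted and logged.
- **Eligible-only mean.** The global score averages over scored
  molecules only (not unscored ones as zeros); with sparse networks the
  zero-filled alternative would measure network density more than
  deviation.
- **Shared reference for controls.** Control samples are scored against
  the full reference including themselves (appended as an extra
  observation, like any sample), keeping one reference network for all
  groups. This biases control scores *low* — a self-referenced sample
  perturbs its own reference less — which the `leave_one_out` option
  removes; see Limitations.
- **Candidate edge universe.** All molecule pairs are tested; the
  reference "network" is the full PCC matrix, not a pre-thresholded
  graph. `reference_edge_filter="pcc_pvalue"` restricts the universe to
  pairs with significant reference correlation for users who want a
  sparser prior.

### Cohort-level inference

- **Tipping point**: the group with the highest mean global score
  (means ± SEM reported; exact ties reported together with a warning).
- **Classification**: high-risk iff global score strictly exceeds the
  threshold (default 1.0). TPR is the flagged fraction of the positive
  (predisease) group, FPR the flagged fraction of all other groups
  pooled.
- **Ranking robustness**: for k = 5, 10, ..., 500 (100 sizes), each
  sample's global score is recomputed as the mean of its k largest local
  scores and the target sample is ranked (ties broken by sample ID; k is
  truncated with a warning when a landscape has fewer scores).
  `prob_top(m)` is the fraction of the grid with rank <= m.
- **Candidate selection**: each predisease sample contributes its top-50
  molecules by local score (ties broken by molecule ID); molecules in at
  least 3 lists are candidates, and candidates present in at least half
  of the samples' lists form the core set.

## The synthetic cohort generator

No public cohort accompanies the method at desk scale, so the package
carries a generator that plants exactly the structure the theory posits.
Cohorts are drawn from block-structured multivariate Gaussians over
`n_molecules` (default 200) with three groups (19/15/14 samples:
control, predisease, disease):

- **Control**: unit variance, compound-symmetric correlation
  (`background_rho = 0.2` everywhere, module included).
- **Stage A (predisease)**: the planted module (default 10 molecules)
  has SD multiplied by `sd_inflation = 3`, internal correlation raised
  to `rho_in_predisease = 0.8`, and module-to-background correlation
  dropped to `rho_out_predisease = 0.02`.
- **Stage B (disease)**: second-order structure returns to baseline
  while each molecule's mean shifts by `mean_shift_disease = 0.2`
  latent SD with a molecule-specific random sign.

Latent values are exponentiated to log-normal intensities by default
(`exp(7 + 0.25 * z)`, i.e. ~1100-count intensities with ~25% CV —
positive and right-skewed like real relative quantification);
`log_normal=False` emits the raw Gaussians. Correlation targets are
validated as positive semidefinite at construction; slightly indefinite
cross-block combinations are repaired by eigenvalue clipping (warned),
and rejected outright if the repair moves any entry by more than 0.05.
An optional `dropout_rate` censors a uniform fraction of entries at each
molecule's detection floor.

Why these effect sizes: the predisease block values are the strong-effect
conditions used throughout the benchmarks. The disease-stage shift of
0.2 SD per molecule is deliberately modest: a single-sample
differential-correlation statistic responds to a coherent mean shift of
size s with spurious co-deviation of order s² plus an sAD inflation, so a
large shift would *raise* disease-group scores and erase the defining
property of the disease state here — first-order change with relaxed
second-order structure, so that global scores drop back after the
tipping point. At 0.2 SD the leak is below ~0.1 score units, an order of
magnitude under the planted module's contribution.

What the generator does **not** emulate: LC-MS peak artifacts, retention
time/mass axes, batch effects, structured missingness, heavy-tailed or
multimodal abundance distributions, and modules with heterogeneous
per-molecule effect sizes. Passing benchmarks therefore demonstrate that
the implementation detects the DNB signature where it exists as posited;
they do not certify sensitivity on real cohorts.

## Benchmarks and problem sizes

Three standing experiments (in `ldnb.experiments`, rerun by
`scripts/acceptance.py` and `analysis/05_benchmarks.py`):

- **Null calibration**: rejection rate of the edge test over 10,000
  independent Gaussian pairs, 50-sample references drawn fresh per batch
  of 100 trials (averaging over references estimates the test's
  calibration rather than its behavior conditional on one draw, which
  varies by ±0.02 from reference noise alone).
- **Recovery**: 20 replicate strong-effect cohorts at the default
  conditions; fraction with stage A as the top-scoring group and the
  mean fraction of planted molecules reaching the candidate set.
- **Null specificity**: 20 no-effect cohorts; Kruskal-Wallis test on the
  three groups' replicate-level mean global scores. Scored with
  leave-one-out references — under the shared-reference rule the control
  group is biased low by construction (measured p ~ 1e-8 under the
  null), so only leave-one-out scoring makes the groups exchangeable and
  specificity interpretable.

Problem sizes (200 molecules, 48 samples, 20 replicates) keep each
benchmark in the tens of seconds on one CPU while leaving the per-cohort
pair count (~20,000 hypothesis tests per sample) large enough to
exercise the sparse-network edge cases.

## Numerical choices

- All PCC matrices via `numpy.corrcoef`; perturbed correlations are
  recomputed directly on the concatenated (n+1)-column matrix (the
  defining form), and property-tested against a pure-Python evaluation
  of the sum formula at 1e-9.
- The volcano tail is tabulated once from the closed form on a dense
  grid (geometric near 0 where the log-tail slope diverges) and
  log-interpolated; relative error < 1e-5 wherever p > 1e-9. Beyond
  t = 26 the closed form cancels catastrophically and the one-term
  asymptotic tail is used (p < 1e-12 there).
- Determinism: same inputs and config give byte-identical outputs; all
  randomness (generator, permutation test, experiment replicates) flows
  through seeded `numpy.random.Generator`s, with replicate seeds derived
  via `SeedSequence`.
- Ties: sample ranking breaks ties by sample ID, top-N lists by molecule
  ID, so every reported ranking is reproducible.
- Degenerate inputs: < 3 reference samples, unknown IDs, non-numeric
  cells, duplicate IDs, and all-positive-group classifications raise
  with the offending names; empty landscapes and truncated k-grids warn
  and continue.

## Limitations

- The shared-reference rule (all groups scored against the same control
  reference, controls included in their own) biases control scores low.
  This matches the published procedure and inflates apparent
  control-vs-rest contrast; `leave_one_out=True` is the clean
  alternative and is what the specificity benchmark uses. Conclusions
  that rest on control-group contrasts alone should use it.
- The fixed high-risk cutoff of 1.0 is on the clinical study's score
  scale; on other data (including the synthetic cohorts, where nearly
  all samples exceed 1.0) the group contrast is meaningful but the
  absolute cutoff is not, and should be recalibrated.
- Edge p-values are selection thresholds, not corrected inferences:
  ~5% of all pairs become edges under the null by design, and edge
  counts are logged so density can be audited.
- The volcano null ignores estimation noise in the reference moments;
  the residual anticonservativeness (~0.055 at n = 50) shrinks with
  reference size but is not corrected.
- Local scores are not comparable across molecules with very different
  neighborhood sizes; rankings within a sample (as used for candidates)
  are the supported use.
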