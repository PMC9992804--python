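# Methods

## Model

`spidnmf` factorizes up to three sample-aligned non-negative views
X_l (n samples × p_l features) as X_l ≈ W H_l with a single shared
basis W (n × k) and view-specific coefficients H_l (k × p_l), all
non-negative. The full objective is

    Γ = Σ_l ‖X_l − W H_l‖²_F
      + α Σ_l ‖H_l H_lᵀ − I‖²_F
      + γ₂ Σ_l Σ_ij H_l,ij
      + γ₁ ‖W‖²_F
      − λ₁ Tr(H₁ A₁ H₂ᵀ) − λ₂ Tr(H₁ A₂ H₃ᵀ)
      + β Tr(Wᵀ L W).

Assumptions built into this form:

- **Shared sample geometry.** All views are driven by the same latent
  sample factors (rows of W). This requires exact row correspondence,
  which `assemble_dataset` enforces by intersecting sample IDs and
  reordering all views to one canonical (lexicographic) order.
- **Non-negativity.** Parts-based decomposition; data must be
  non-negative (enforced at I/O with the offending cell named).
- **Cross-modal coupling as a reward.** A₁ and A₂ hold |Pearson r|
  between image features and miRNA/mRNA features; the trace terms
  reward factor loadings that align correlated feature pairs across
  views. They enter with a minus sign, so for large λ the monitored
  objective can go negative — it is a monitoring quantity, not a
  norm.
- **Stage smoothing.** The sample graph connects same-stage samples
  (A_ij ∈ {0,1}, diagonal 1 — self-loops are penalty-neutral because
  Tr(WᵀLW) = ½ Σ_ij A_ij ‖w_i − w_j‖² and the i = j terms vanish).
  β Tr(WᵀLW) pulls same-stage rows of W together. The quadratic is
  over *rows* of W (samples); that is the only reading dimensionally
  consistent with an n × n Laplacian.

## Optimization

Multiplicative updates, one Gauss–Seidel sweep per iteration: W first,
then H₁, H₂, H₃, each using the freshest co-factors. The W update is

    W ← W ⊙ (Σ_l X_l H_lᵀ + β A W) / (Σ_l W H_l H_lᵀ + γ₁ W + β D W)

i.e. the Laplacian gradient 2βLW = 2β(D − A)W is split with the
positive part (βAW) in the numerator and βDW in the denominator — the
standard construction for graph-regularized NMF, and the only
arrangement that keeps the iterates non-negative (L itself has negative
off-diagonal entries). The H updates are

    H₁ ← H₁ ⊙ (WᵀX₁ + 2αH₁ + (λ₁/2) H₂A₁ᵀ + (λ₂/2) H₃A₂ᵀ)
              / (WᵀWH₁ + 2α H₁H₁ᵀH₁ + (γ₂/2) E)

with H₂, H₃ analogous (one coupling term each). Denominators are
floored at ε = 1e−10. The three methods share this engine with
method-specific weights forced to zero (`jnmf`: all extras; `mdjnmf`:
β), which makes the nesting *bit-exact*: `spid` with β = 0 produces
identical iterates to `mdjnmf`, and `mdjnmf` with all extras zero to
`jnmf`; with all weights zero the sweep reduces to the classical
multiplicative NMF update on the column-concatenated matrix, which
carries the classical monotone-descent guarantee. For the penalized
objective no descent proof is asserted; the trajectory is recorded and
monitored instead.

**Initialization** is non-negative double SVD (positive/negative part
splitting of the top-k singular triplets of the concatenated matrix),
with zeros floored at 1e−6 so multiplicative updates can move every
entry. It is fully deterministic: identical inputs give bit-identical
factors and therefore bit-identical fits.

**Convergence** is declared when the change in relative error
‖X − WH‖_F/‖X‖_F between iterations drops below `tol` (default 1e−5),
or at `max_iter` (default 200). The normalized ratio is used rather
than a raw squared norm because it is scale-free and comparable across
datasets; `relative_error(..., squared=True)` returns the raw squared
form. Grid search adds per-fit early stopping: stop when the error has
not improved by `tol` for `patience` (default 5) consecutive
iterations.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| k | rank / number of modules | required | ≈ min(n, p)/10 is a common heuristic (k = 7 at n ≈ 69) |
| α | H orthogonality weight | 0.01 | not usually swept; redundancy control |
| λ₁, λ₂ | coupling weights (A₁, A₂) | 0 | swept over {0.001, 0.01, 0.1, 1} |
| β | stage-graph weight | 0 | swept likewise; `spid` only |
| γ₁ | ‖W‖² weight | 0 | swept likewise |
| γ₂ | H entry-sum sparsity | 0 | swept likewise |
| tol | convergence threshold | 1e−5 | on the relative-error change |
| ε / init floor | numerical floors | 1e−10 / 1e−6 | configurable |
| z_threshold | module membership | 2.0 | see below |

The five tunables sweep a 4-value grid → 4⁵ = 1024 combinations,
enumerated in fixed odometer order (λ₁ slowest … γ₂ fastest) so a
combination index uniquely identifies a setting.

## Module extraction and scoring

Feature j joins factor i's module in view l iff
H_l[i,j] > mean(H_l[i,·]) + z·sd(H_l[i,·]), z = 2 by default. This
per-row z-score rule is the standard membership criterion in the
joint-NMF module literature but it has a structural consequence worth
stating: for a two-level coefficient row with active fraction f, the
active entries sit ≈ √((1−f)/f) standard deviations above the mean, so
z = 2 can only ever flag a *minority* block (f < 0.2). Modules are by
construction sparse feature sets, not partitions of the feature space.
Modules are scored per view by |Pearson| between the original and
reconstructed submatrices restricted to member columns (flattened),
and ranked by the mean over member-bearing views.

## WSI aggregation

Per nucleus, ten cell-level features (area; major/minor axis lengths
and their ratio; mean R, G, B pixel values; mean/max/min distance to
neighbouring nuclei). Per patient, each feature yields 10 histogram
fractions plus mean, sd, median, min, max → 150 features named
`<feature>_<agg>` (e.g. `area_bin1` = fraction of the smallest nuclei,
`area_bin10` the largest). Bin boundaries default to the pooled-cohort
deciles (9 internal cut points, outer bins open-ended, boundary ties
fall to the lower bin); a fixed edge set can be supplied for
cross-cohort comparability. Deciles are a documented default, not a
claim about how any particular published cohort was binned.

## Survival analysis

Patients with follow-up ≤ 90 days are dropped (strictly-greater
filter). Each candidate feature is screened with a univariate Cox
proportional-hazards fit (delegated to lifelines); features with
p < 0.05 — deliberately uncorrected, as the screen feeds a joint
multivariate model — are retained with HR and 95 % CI. The
multivariate Cox fit supplies coefficients for the linear risk score
Σ coef_n·x_n; the training-cohort median splits patients into high
(score > median) and low (≤ median, ties low) risk groups. Group
assignment is invariant under monotone transforms of score and cutoff.

## Synthetic data

The generator plants exactly the structure the model assumes: W_true
rows are uniform(0.1, 0.5) background plus `stage_strength` (default 1)
added to the factor indexed by the sample's stage (stages round-robin,
3 by default, so groups are balanced and runs deterministic);
each factor loads uniform(1, 2) on a narrow contiguous feature block
(~10 % of the view's features, disjoint across factors) and 0
elsewhere; X_l = W_true·H_true + max(0, N(0, σ)) noise, σ = 0.05 by
default. Active loadings are bounded away from zero and blocks are kept
sparse deliberately — the z-score membership rule is only well-posed
for minority blocks (see above). Survival times are exponential with
log-hazard proportional to one factor column (slope `effect_size`,
baseline mean one year), with independent censoring at a set rate.

What passing tests on this generator do show: the solver descends,
respects non-negativity, the method nesting is exact, planted
low-rank structure and sparse modules are recovered, the stage prior
has its intended monotone effect, and the survival screen is
calibrated. What they do not show: performance on real sequencing
count distributions, correlated or heteroscedastic noise, batch
effects, or real histology feature statistics — no claims are made
about real-cohort effect sizes or error levels.

## Numerical and design choices

- **Update order** (W, then H₁…H₃, freshest co-factors) is fixed for
  reproducibility; other orders converge to similar but not
  bit-identical iterates.
- **Sparsity bookkeeping**: the H-update denominators use (γ₂/2)E
  while the monitored objective reports γ₂·ΣH. The constant-factor
  mismatch affects the reported objective value only, never the
  iterates, and is kept so the update rule matches its standard
  printed form.
- **Constant columns** have undefined Pearson correlation; cross-modal
  prior entries involving them are set to 0 (no coupling) with a
  warning counting affected pairs. The same convention (return 0)
  applies wherever a flattened correlation hits a constant side.
- **Ties**: grid-search ties break to the lowest combination index;
  module-score ties to the lowest factor index; risk-group ties at the
  cutoff go to the low group.
- **Degenerate inputs**: all-zero datasets are rejected where a norm
  ratio would divide by zero; constant H rows yield empty module
  membership; single-nucleus patients get sd = 0, not an error; an
  empty post-filter survival table is allowed but logged.
- **Problem sizes** used by the test suite and the acceptance script
  (n = 60 samples, p = (50, 80, 100) features, k = 4, 10-seed
  replication; screens at n = 200–300 with 200 replicates) are chosen
  so the planted structure is comfortably identifiable yet a full run
  completes in minutes on a laptop.

## Known limitations

- No convergence proof for the full penalized objective; descent is
  monitored, not guaranteed, when penalties are active.
- The coupling terms are unbounded below in principle; extreme λ
  values can drive the monitored objective negative while the
  iterates remain finite and non-negative (denominator floors).
- k is fixed during a sweep; choosing k is left to the user (the
  min(n, p)-based heuristic above is a convention, not an optimum).
- Dense matrices only; no sparse or GPU paths.
- The univariate screen's raw p < 0.05 rule is a faithful default, not
  a recommendation; a Benjamini–Hochberg flag is available.
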