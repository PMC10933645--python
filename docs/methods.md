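# Methods

## Setting and data model

The package analyses twice-daily experience-sampling (EMA) studies: each
participant is prompted in the morning (~7:00) and afternoon (~16:00) on
nine consecutive weekdays, yielding up to 18 occasions per person.  Four
constructs form the network nodes, all on a 0–100 scale:

* **self_control** — a four-item self-report composite (one item, "I lost
  control of myself", reverse-coded before averaging);
* **anger_rumination** — a two-item self-report composite;
* **anger** — a single momentary item;
* **response_inhibition** — no-go accuracy from an ambulatory Go/No-go task
  (four main blocks of 50 trials, 10 no-go trials per block, i.e. 20% of
  trials, preceded by an unscored training block; responses after the
  1200 ms stimulus window count as no response).

Observations are keyed by `(person, day, slot)` with `slot ∈ {AM, PM}`; no
clock timestamps are stored because the design is slot-based.  Missingness
is per occasion and per modality (the whole self-report survey or the whole
task is missed); no imputation is performed anywhere — rows are used where
available.

## Two-step node-wise multilevel VAR

Lag-1 pairs are formed **within days only** (AM predicting PM of the same
day).  Overnight PM→next-AM transitions are never modelled, because the
night interval differs qualitatively from the within-day interval and would
contaminate the lag-1 coefficient.  Each person's mean over *all* their
observed occasions (both slots) estimates the trait level m̂_{p,k}; the
within-person predictor is the centered morning value
c_{p,d,k} = AM_{p,d,k} − m̂_{p,k}.

**Step one** fits, for each node j, the linear mixed model (REML)

    y_{p,d,j} = ν_j + Σ_{k≠j} γ_{jk} m̂_{p,k} + Σ_k (β_{jk} + u_{p,jk}) c_{p,d,k}
              + b_{p,j} + ε_{p,d,j}

with a person random intercept b and mutually independent random slopes u
(diagonal random-effects covariance; the fully correlated structure is
available as `FitOptions(correlated_slopes=True)` but is unstable at four
nodes with ~9 lag rows per person).  The fixed β̂ matrix is the directed
**temporal network**; the reported "SD" of each edge is the random-slope SD
τ̂_{jk}.  The person-mean coefficient pairs (γ̂_{jk}, γ̂_{kj}) give the
**between-person network** via the signed geometric mean
sign(γ_{jk})·√(γ_{jk} γ_{kj}), which equals the partial correlation of the
person means exactly under Gaussian node-wise regression and is invariant to
variable rescaling.  Pairs with conflicting signs are set to 0 and flagged
(`sign_conflict`) rather than averaged, because the conflicted product has
no coherent sign.

**Step two** takes conditional residuals (observed minus fixed plus
predicted random effects — the within-person innovations) from all node
fits, aligns them on the intersection of used (person, day) rows, and
regresses each node's residual on all the others with a person random
intercept.  The coefficient pairs are converted to the **contemporaneous
network** by the same signed-geometric-mean rule.

Fixed-effect p-values are Wald z tests — the convention of common
multilevel-VAR implementations and portable across optimizers.  Inference
for variance parameters is not attempted.

### Numerical choices

* Optimizer ladder powell → cg → lbfgs.  The powell optimizer is tried
  first because gradient-based optimizers often fail to converge when slope
  variances sit near the boundary (the common case: many true slope SDs are
  zero).  A fit is accepted only if the optimizer reports convergence and
  all fixed-effect standard errors are finite and positive.
* Non-convergence fallback ladder: random slopes are removed one at a time,
  smallest estimated variance first (deterministic), then the model falls
  back to random-intercept-only; every fallback is recorded in the
  `NetworkSet` metadata.  A node that fails the whole ladder raises
  `UnestimableNode`.
* With both random terms disabled the fit reduces to ordinary least
  squares; tests use this path to verify exact agreement (≤1e-6) with
  closed-form least squares, and the partial-correlation assembly against
  precision-matrix inversion (≤0.02 at 10⁴ rows).
* Default minima: 10 lag rows across 5 persons per node (configurable).
* Variables are fitted on their raw 0–100 scale; `standardize=True`
  rescales every variable by its grand SD first.  Recovery tests generate
  and estimate on the same scale, so the choice does not affect them.
* Estimated partial correlations are clipped to [−1, 1]; symmetric network
  matrices have an undefined (NaN) diagonal.

## Edge selection

All p-values are Benjamini–Hochberg adjusted before display.  Adjustment is
pooled **within each network** by default: the V² temporal p-values, and
the 2·C(V,2) directional p-values of each symmetric network (global pooling
across all three networks is available).  Temporal edges are significant
when their own adjusted p < .05.  Symmetric edges use the **or** rule: the
edge is shown when either direction's adjusted p < .05 (an **and** rule is
available; the or-selected set always contains the and-selected set).  The
reported weight of a symmetric edge is the signed-geometric-mean partial
correlation, not either directional coefficient.

## Reliability statistics

Cronbach's α uses the covariance form with listwise deletion.  Split-half
reliability for the task outcome correlates each person's odd-day mean with
their even-day mean across persons and steps up with Spearman–Brown
SB = 2r/(1+r); the person is the unit because the statistic describes
trait-level stability of a repeated ambulatory measure (an occasion-level
split is available via `unit="occasion"`).

## Synthetic-data generator

Because no raw data are distributable, a generator with known ground truth
stands in for the study, and correctness is established by parameter
recovery.  The generative process mirrors the estimator's assumptions:

    m_p      ~ MVN(μ, Σ_B)                    person means
    B_p      = B + Δ_p,  Δ_{jk} ~ N(0, T²_{jk})   person-specific lag matrix
    δAM_{pd} ~ MVN(0, Σ_AM)                   fresh each day
    δPM_{pd} = B_p δAM_{pd} + ε_{pd},  ε ~ MVN(0, Σ_C)
    value    = m_p + δ;  occasion observed with per-modality compliance

Σ_B and Σ_C are constructed from target partial-correlation matrices and SD
vectors by inverting the implied precision matrix (`build_covariance`), so
the generator's partial correlations are exact by construction.  Fresh
morning deviations each day (no overnight carryover) match the estimation
model; an `overnight_carryover` knob exists to study misspecification but
is off by default.

**Default preset** (the study conditions): 62 persons × 9 weekdays × 2
slots; grand means (74.61, 56.14, 10.97, 12.59) and total SDs (21.35,
23.80, 21.95, 23.01) for (self_control, response_inhibition, anger,
anger_rumination); temporal matrix with self-loops (.170, .184, −.006,
.268), cross-lags RI→SC = .174 and RUM→ANG = .189, slope SDs (.065, .240,
.089, .415, .141, .302) on those edges and 0 elsewhere; contemporaneous
partial ANG–SC = −.138; between partials ANG–SC = −.491, ANG–RI = −.150,
ANG–RUM = .291; compliance .85 (self-report) and .793 (task).

Two generator parameters are not identified by published descriptives and
were fixed once as follows:

* **Variance split.**  Only total SDs are published.  The preset uses
  between SD = 0.8 × total and within (innovation and morning-deviation)
  SD = 0.6 × total, so the implied total variance matches the published one
  (0.8² + 0.6² = 1) and the intraclass correlation is 0.64 — consistent
  with the high (≈0.96) split-half trait stability the preset reproduces.
* **Morning-deviation dispersion** Σ_AM defaults to Σ_C (nothing in the
  descriptives constrains it separately); it is an explicit config knob.

Values are **not clipped** to [0, 100] by default: clipping truncates the
Gaussian tails and biases linear-model recovery.  A `clip=True` option
exists for realism demonstrations.  Consequently file round-trips of
synthetic panels use `check_range=False` (CLI flag `--allow-out-of-range`);
range validation stays on by default for real data.

Item-level panels add independent N(0, σ²_item) noise to the composite
value (reverse items stored flipped), giving a closed-form Cronbach's α of
kλ/(1+(k−1)λ) with λ = var(composite)/(var(composite)+σ²_item).  Trial
logs draw each no-go response as Bernoulli(value/100) withholds, go
responses at .95, and lognormal RTs as nuisance.

### What the generator does and does not emulate

It reproduces the design (slot structure, compliance as per-modality
Bernoulli block missingness, composite/item layering, trial counts) and the
second-order structure the estimator targets.  It does **not** emulate
floor effects and skew of low-base-rate affect items (real anger ratings
pile up at 0), circadian or day-of-week trends, autocorrelated compliance
(missingness is independent Bernoulli, i.e. ignorable by construction), or
reactivity.  Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not robustness
to those real-data features.

## Problem sizes in the checks

Recovery runs use 600 persons × 60 days at full compliance — large enough
that every nonzero preset coefficient is recovered within ±0.05 (temporal,
contemporaneous) or ±0.07 (between; at 600 persons the sample partial
correlation of the drawn person means itself has an SD of ≈0.03–0.07, which
dominates the tolerance).  Null-model calibration uses 200 replications at
the study's own scale (62 × 9, compliance .85/.793) with
random-intercept-only fits, checking a ≈5% Wald type-I rate per coefficient
and a controlled false-edge rate after FDR selection.  Oracle-equivalence
checks run at 10⁴ rows.

## Known limitations

* Wald z inference is anti-conservative in small samples compared to
  Satterthwaite or Kenward–Roger corrections; at the study scale the
  measured type-I rate is nevertheless close to nominal.
* The between-network p-values inherit the occasion-level mixed model's
  effective sample size approximation; with few persons they are rough.
* The signed-geometric-mean rule discards information when directional
  coefficients conflict in sign (the edge is zeroed and flagged).
* No support for lags beyond 1, overnight edges, person-specific
  (idiographic) networks, or Bayesian estimation.
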