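# Methods

`omicstack` implements a late-integration ("stacked generalization")
pipeline for predicting a continuous physiological clock — gestational age
in weeks at the time of sampling — from several omics modalities measured
longitudinally on the same subjects, together with the diagnostics and
model-reduction machinery that make such a model interpretable. This note
documents the models, the defaults and why they are what they are, the
numerical choices, and what the synthetic testbed does and does not show.

## The statistical problem

Each of M modalities (cell-free transcriptome, plasma/serum cytokine
panels, microbiome, mass-cytometry immunome, metabolome, proteome, ...)
yields a samples x features matrix X_m on a shared sample set; metadata
gives the subject, the visit (trimesters T1/T2/T3, optionally a postpartum
visit PP) and the outcome Y (gestational age in weeks). Feature counts
differ by orders of magnitude across modalities and features within a
modality are heavily intercorrelated, which we summarize by the
*modularity* diagnostic: the number of principal components of the
column-standardized matrix needed to reach 90% of total variance
(correlation-matrix PCA, so the metric is unit-free and comparable across
modalities; the scaling is our choice — the source procedure does not fix
one).

## Elastic net

Per modality we fit the penalized linear model minimizing

    L(α, λ, β) = ||Y − Xβ||² + λ[(1 − α)||β||² + α||β||₁]

with an unpenalized intercept. λ ≥ 0 sets overall penalty strength
(sparsity); α ∈ [0, 1] mixes the L1 subset-selection and L2 grouping
penalties — with α < 1 correlated informative features share weight instead
of one arbitrary representative being selected. Note the *raw*
residual-sum-of-squares convention (no 1/(2n)); λ values are therefore only
meaningful relative to λ_max = 2·max_j |z_jᵀ(Y − Ȳ)| / max(α, 10⁻³), the
smallest λ that zeroes every coefficient, computed per training fold.

Features are standardized to zero mean / unit variance *inside* fit on
training data only (the penalties are scale-sensitive); the scaler is
stored with the model so prediction never refits. Y stays on the week
scale, so coefficients read as weeks per standardized-feature unit.

Numerics: λ = 0 falls back to `lstsq`; α = 0 uses the ridge closed form;
otherwise scikit-learn coordinate descent (parameters mapped by
sk_alpha = λ(2−α)/(2n), l1_ratio = α/(2−α)) followed by exact cyclic
coordinate-descent polishing until the elastic-net subgradient (KKT)
residuals are below 1e-9 relative to the null-gradient scale. `check_kkt`
verifies optimality independently of the solver; the test suite holds it
below 1e-6 across seeded problems. Zero-variance features are dropped with
a warning and receive exact zero coefficients.

## Two-layer leave-one-subject-out cross-validation

A subject's three trimester samples share a random subject effect, so
random splits leak identity information. The outer loop therefore holds
out *all* pregnancy samples of one subject per fold (fold order: sorted
subject id; construction is RNG-free). Within each training fold an inner
leave-one-subject-out grid search selects (α, λ) by the RMSE of pooled
inner blinded predictions; ties prefer larger λ, then smaller α (sparser,
smoother). The inner criterion is our choice — the outward metric is
Spearman's ρ, but RMSE is smooth and on the outcome scale. Default grid:
α ∈ {0, 0.1, …, 1}, 50 λ values log-spaced over three decades below λ_max;
tests and the acceptance run use smaller grids (3 α values, 8–15 λ values
over two decades), which is a problem-size choice, not a different method.

Two prediction flavors per sample: the **blinded** prediction from the one
model whose training excluded the sample's subject, and the **training**
prediction, the median over the (n_subjects − 1) models that included it.
Evaluation reports Spearman ρ (average ranks), its p-value — the
t-approximation for n > 10 and the exhaustive n!-permutation distribution
for n ≤ 10 — and RMSE in weeks. Constant predictions are flagged
degenerate (ρ = 0, p = 1) rather than erroring.

## Stacked generalization

The M per-modality gestational-age estimates become the features of a meta
elastic net. Folds are synchronized across layers: the meta model of fold
f is trained on fold-f base-model predictions of the training samples and
applied to fold-f base-model predictions of the held-out subject, so the
stacked blinded prediction of a subject involves no model that ever saw
that subject — at either layer. (Training the meta layer on out-of-fold
base predictions instead would route the held-out subject's outcomes into
its own stacked prediction through the other folds' base models; we
verified this invariant by bitwise-comparing predictions after perturbing
a held-out subject's outcomes.) A summary meta model fit on the full
out-of-fold blinded prediction matrix supplies the modality weights; since
the elastic net standardizes its inputs, those coefficients are comparable
across modalities.

**Application / postpartum.** Fitted fold models are retained; any sample
(notably PP visits, which never enter any training or test fold) is scored
by the median over the fold models of all other subjects. Applied to the
pregnancy visits this exactly reproduces the training predictions.

**Ablation.** Iteratively remove the modality with the largest (or
smallest) absolute summary-meta coefficient, re-fit the meta layer on the
remainder, and record coefficients and blinded performance. Base CV
results do not depend on which modalities remain and are computed once.
Ties break lexicographically and are flagged.

## Missing-value interpolation

Iterative per-feature random forests (the missForest scheme): initialize
missing cells with feature means, visit features from least- to
most-missing, regress each on all others using its observed rows, and
overwrite only the missing cells; stop when the normalized change between
successive completed matrices rises (reverting to the previous iterate),
drops below tolerance, or after `max_iterations`. Defaults (100 trees, 10
iterations) follow the reference procedure, the only principled anchor
since no hyperparameters are stated at the source. Imputation runs once on
each full matrix before cross-validation, matching the pipeline order of
the original analysis; per-modality seeds derive from the config seed and
the modality name so modalities never perturb one another.

## Bootstrap model reduction

For each modality, 100 bootstrap resamples of the pregnancy samples
(draw size = training sample count by default; the parameter is exposed)
are refit at the modality's full-data inner-selected (α, λ) — re-tuning
inside every draw would multiply cost ~100x for no inferential gain — and
the per-feature mean |coefficient| forms a stability profile. A threshold
sweep retains features with profile ≥ t for the unique positive profile
values (optionally quantile-thinned), re-running the *same-fold-plan*
nested CV per subset. The retained count is chosen at the knee of a
two-segment continuous linear fit of −log10(blinded Spearman p) (RMSE
available) against feature count: every observed count is tried as the
breakpoint, total SSE decides, ties break toward fewer features.

## Correlation network

The union of selected features across modalities is summarized by a
minimum spanning tree over the complete graph with edge distance
1 − |Spearman ρ| — the tree's weight choice is ours; the source fixes only
the edge-width display, −log10(p) (capped at 12), so both full matrices
are retained in the output and alternative weightings are recomputable.
Edge p-values are Bonferroni-adjusted; the denominator defaults to the
number of pairs tested (conservative) with a flag for the feature count.
Distance ties break lexicographically by node key, making the tree
deterministic. Node size encodes |ρ| of the feature with the outcome.
Layout is Fruchterman–Reingold under a fixed seed, for export only.

## Synthetic cohort generator

The generator is first-class, tested code that reproduces the statistical
design the pipeline assumes: default 17 subjects x visits in windows
T1 [7, 14], T2 [15, 20], T3 [24, 32] weeks (outcomes uniform per window),
optional PP visit, 7 modalities. Each modality is a latent-block factor
model: features are partitioned into n_latent blocks; informative block
latents are signal_strength · ga + a per-(subject, block) N(0, 1) random
intercept (the dependency LOSO exists to guard against); uninformative
latents are N(0, 3²) noise plus the subject effect; features load on their
block latent with a random ±Uniform(0.5, 1.5) loading plus N(0, noise_sd²)
noise; missingness is MCAR. The clock is linear in gestational age because
the downstream models are linear — nonlinear ground truth is a config
extension, not a default. The postpartum latent interpolates by
recovery_rate between the T3 endpoint (no recovery) and the week-0
extrapolation of the linear clock (full recovery — by construction *below*
the T1 level, making the "reverts below the first trimester" phenomenon
literally testable).

Default modality parameters (features / latent blocks / signal / noise /
missing rate / recovery): cellfree_rna 150/25/0.6/1.0/0/0.2,
plasma_luminex 40/6/0.5/1.0/0/0.5, serum_luminex 30/5/0.4/1.0/0/0.5,
microbiome 120/40/0.3/2.0/0/0.9, immunome 80/8/0.8/0.8/0/0.1, metabolome
100/15/0.7/1.0/0.01/0.8, proteome 60/10/0.9/0.7/0.01/0.3. Feature counts
are scaled down from assay-realistic magnitudes so nested CV at the
51-sample design is tractable while the qualitative contrasts (differing
dimensionality, modularity, signal, recovery speed) survive; signal and
noise levels are chosen for testability — no quantitative anchor exists
for them.

**What passing tests show, and what they do not.** The generator is
Gaussian, linear and MCAR: no compositional microbiome structure, count
noise, batch effects, nonlinear trajectories or informative missingness.
Tests on it establish the pipeline's *contracts* (blinding, fold
synchronization, optimality, recovery of planted structure), not
performance on real assay data; blinded ρ values on the default cohort are
far higher than any real cohort would give because the planted signal is
clean.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → impute → per-modality CV → stack →
ablate → reduce → network, writing deterministic CSV/JSON/GraphML
artifacts plus a manifest with per-stage SHA-256 output digests and wall
times. One global seed fans out to per-stage seeds via a stable hash of
the stage name, so two runs with the same config are byte-identical and
adding a stage never shifts earlier randomness. With `resume=True`, stages
whose recorded input digests match and whose outputs verify are reloaded
from disk (fold models round-trip through JSON), so deleting downstream
outputs recomputes only downstream stages.

## Known limitations

- Single imputation only; no uncertainty propagation from imputed cells.
- Imputation precedes cross-validation (matching the source pipeline); a
  leakage-averse user should re-impute within folds — `rf_impute` can be
  applied per training fold but the pipeline does not automate it.
- The reduction sweep's breakpoint needs ≥ 5 distinct thresholds; profiles
  with few unique values return no selection.
- Exact permutation p-values are computed only for n ≤ 10 (n! growth).
- Inner selection shares one λ grid per (fold, α); with `fixed_lambdas`
  the caller takes responsibility for scale-appropriateness.
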