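# Methods

## The estimation problem

After complete macroscopic cytoreductive surgery for advanced high-grade
serous ovarian cancer, residual microscopic peritoneal metastases (mPM) are
invisible to the surgeon and detectable only by pathology of biopsied
tissue. The data are per-patient counts: of n ≤ 13 biopsies of
macroscopically healthy peritoneum (at most one per Peritoneal
Carcinomatosis Index region), how many contained mPM. The target of
inference is the cohort-level distribution p(K) of the number K of
mPM-bearing "sub-surfaces" — 4 cm² peritoneal patches, the area sampled by
one biopsy — among the N patches that tile the peritoneum.

## Model structure and assumptions

**Completion.** The model assumes a common number of biopsies per patient.
Patients with fewer than 13 are padded with artificial mPM-negative
biopsies. This conserves positives and can only dilute them, so the
downstream residual-disease probability is, if anything, underestimated;
the padding-bias test in the suite checks this direction empirically on
simulated cohorts.

**Count model.** The completed positive counts (19 patients with 0, four
with 1, two with 2, one with 7, out of 26) form a relative histogram on
0..13. A Poisson distribution is adjusted to it by least squares on the
probability scale:

    lambda* = argmin_{0 <= lambda <= 13}  sum_x (Pois(x; lambda) - f(x))^2,

solved by bounded scalar minimisation (`scipy.optimize.minimize_scalar`,
xatol 1e-10) and verified in the tests against an independent grid search
(step 1e-4). On the reference cohort lambda* = 0.2752. The
maximum-likelihood alternative (the histogram mean, 15/26 ≈ 0.5769) is
available as a cross-check; it fits the zero-inflated histogram less well
in the least-squares sense. The fitted pmf is truncated to 0..13 and
renormalised so that the inversion input q is a proper distribution; for
lambda ≤ 3 the truncation constant exceeds 0.999, so this is cosmetic.

The choice to invert the *fitted* q rather than the raw histogram follows
the reference procedure; the raw histogram (a spike at x = 7 with zeros at
3–6) lies outside the hull of hypergeometric columns and its direct
inversion behaves erratically.

**Geometry.** Peritoneal surface area is taken equal to body surface area
(BSA). Du Bois (0.007184 · W^0.425 · H^0.725) is the default formula,
Mosteller (sqrt(H·W/3600)) the alternative; they agree within 5% over the
relevant height/weight range. The cohort-average area, pre-rounded to two
significant figures (16,500 → 16,000 cm²), divided by the 4 cm² biopsy
area gives N = 4000. Reference mode pins area = 16,000 cm² and N = 4000 as
configuration constants; data mode computes them from patient height and
weight.

**Forward model and inversion.** Conditional on K affected sub-surfaces,
biopsies sample without replacement, so the positive count is
hypergeometric, and q = H p with H[x, K] = Hyp(x; N, K, n) a column-
stochastic 14 × 4001 matrix (built with `scipy.stats.hypergeom`, which
works in log space). The burden distribution solves

    min_{p >= 0, sum p = 1}  ||H p - q||^2  ( + lam_reg ||p||^2 ).

## Underdetermination and the tie-break

Fourteen observables cannot identify 4001 probabilities: the minimiser set
is a face of the simplex. What *is* identified (when the fit is exact) are
the first 13 factorial moments of K, because hypergeometric sampling maps
them linearly to the moments of x; in particular E[K] = lambda·N/n and
Var(K) follow from q alone. `analysis/05_identifiability_bounds.py`
certifies by linear programming that, for the reference q, every exactly
fitting solution has p(0) ≤ 0.00215 — residual-disease probability
≥ 99.79% — with E[K] = 84.7 and sd(K) = 26.1 pinned.

The package's default selection is the minimum-Euclidean-norm point of the
optimal face, i.e. the limit of the Tikhonov-penalised program as
lam_reg → 0⁺. Rationale: it is unique, solver-independent, preserves the
exact fit (penalised solutions trade fit residual ~lam_reg against norm,
which breaks forward-inversion consistency checks at the 1e-10 level), and
maps q = δ₀ to p = δ₀ exactly. The penalised program is implemented as
well (`lam_reg > 0`), solved by a damped semismooth-Newton method on its
15-dimensional dual; it converges to KKT residuals ~1e-12 for
lam_reg ≥ 1e-6 and is intended for that range.

**Numerics of the default solver.** Stage one solves the fit by
non-negative least squares on H augmented with a sum-to-one penalty row
(weight 1e4), yielding the optimal fit value and a sparse vertex of the
optimal face. Stage two computes the minimum-norm point of
{p ≥ 0 : Hp = y*, Σp = 1} through its smooth concave dual (15 variables),
by L-BFGS-B (gtol 1e-12) plus a semismooth-Newton polish; if the primal
feasibility residual still exceeds 1e-6, an exact NNLS refinement of the
projection (equality rows weighted 1e6) is run. The returned vector is
renormalised (deviations of Σp from 1 are ≤ 1e-9). The whole reference
inversion takes seconds on one CPU and is fully deterministic: re-running
an identical configuration produces byte-identical reports.

**Summaries.** S(n) = P(K > n) is the survival function of p; the spread
indicator for tail level α is the smallest n with S(n) ≤ α. Since S is a
step function, exact equality has measure zero and this tie rule makes the
indicator well defined and non-increasing in α.

## Relation to the reported reference values

The reference analysis reports P(K ≥ 1) = 98.14% and spread indicators
(125, 105, 97, 91, 69) at tail levels (5, 25, 50, 75, 95)%. Those values
are mutually consistent only with a solution whose fit residual is *not*
negligible: they imply p(0) = 0.0186 (nine times the LP-certified exact-fit
maximum) and a burden standard deviation ~17–21 (below the pinned 26.1).
The exact constrained-least-squares formulation used there is described in
an appendix not available to this implementation; experiments with
Tikhonov weights from 1e-2 to 1e-12, interior-point (log-barrier) central
paths, sparse NNLS vertices and analytic centres reproduce the qualitative
shape (a bump of order 100 sub-surfaces, ~1–3% of the surface) but not the
printed numbers. The package therefore reports its own converged values —
P(K ≥ 1) ≈ 100%, n(95%) = 50, n(25%) = 100 — and treats the residual gap
as a property of the unavailable regularisation, not as a target to tune
toward.

## Synthetic-data generator

`simulate.sample_cohort` draws, per patient: K from a configurable burden
law (default a two-point mixture, 98% at K = 300 and 2% at K = 0), a
biopsy count uniform on 3..13 (so completion is always exercised), the
positive count from Hypergeom(N, K, n_i), and height/weight from normal
laws (162 ± 6 cm, 61 ± 10 kg) calibrated so Du Bois BSA averages 1.65 m²
with SD ≈ 0.12, matching the reference cohort's body habitus. Each patient
consumes an independent RNG substream keyed by (seed, patient index), so
enlarging a cohort preserves earlier patients.

What the generator does *not* emulate: spatial clustering of lesions on
the peritoneum (only counts matter to the model), per-patient variation in
N, pathology false negatives/positives, and any dependence of biopsy
placement on disease. Passing recovery tests therefore validate the
inferential machinery under the model's own assumptions, not robustness to
these real-data features.

`recovery_experiment` runs the full pipeline per replicate and scores the
estimated residual-disease probability against the generating truth
1 − burden_law(0). Under the default truth of 0.98, 200 replicate
26-patient cohorts give a mean estimate of 0.995 (bias +0.015, RMSE 0.072):
the estimator saturates near 1 whenever positives are observed, because
the minimum-norm tie-break places no atom at K = 0; its error is bias-,
not variance-dominated, and RMSE improves only weakly with cohort size.
This saturation is the main known limitation of the default tie-break as a
point estimator of P(K ≥ 1); the identifiability bounds show any exact-fit
tie-break shares it.

## Problem sizes and tolerances used in the tests

The suite exercises the full N = 4000 grid for the reference pipeline and
matrix properties; solver cross-checks against an exhaustive simplex grid
(step 0.05) use N = 6, n = 3, the largest size at which full enumeration
(230,230 grid points) is practical. Monte-Carlo checks use 100–200
replicate cohorts or 1500 simulated patients, sized to keep the whole
suite within a few minutes while leaving 3-standard-error margins.
Histogram normalisation is checked to 1e-12, column stochasticity of H to
1e-10, forward-inversion consistency to 1e-10, and simplex feasibility of
returned solutions to 1e-8.
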