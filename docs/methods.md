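# Methods

`dosecopula` analyses the joint dosing behaviour of a two-herb drug pair
(the motivating pair is *Panax ginseng* and *Atractylodes macrocephala*
Koidz.) across historical Chinese medicine prescriptions.  The question it
answers is distributional, not causal: when a physician raised the dose of
one herb, how strongly — and in which part of the dose range — did the dose
of the partner herb move with it?

## Model

Let X and Y be the two gram doses with marginal CDFs F and G.  By Sklar's
theorem the joint CDF factorises as H(x, y) = C(F(x), G(y)) for a copula C,
a bivariate CDF on the unit square with uniform margins.  The copula
isolates the dependence from the margins, which matters here because dose
distributions are strongly right-skewed and non-normal, so a linear
(Pearson) correlation is not a faithful dependence summary.

Five candidate families are fitted:

| family   | parameter(s)      | tail behaviour |
|----------|-------------------|----------------|
| Clayton  | α > 0             | lower-tail dependent |
| Frank    | α ≠ 0             | tail-symmetric, no tail dependence |
| Gumbel   | α ≥ 1             | upper-tail dependent |
| Gaussian | ρ ∈ (−1, 1)       | tail-independent |
| Student-t| ρ ∈ (−1, 1), ν ≥ 1| symmetric upper and lower tail dependence |

Model-implied rank correlations are the copula functionals
τ = 4∫∫C dC − 1 and ρ_S = 12∫∫C du dv − 3.  Closed forms are used where
they exist: Clayton τ = α/(α+2); Gumbel τ = 1 − 1/α; Frank
τ = 1 − (4/α)(1 − D₁(α)) and ρ_S = 1 − (12/α)(D₁(α) − D₂(α)) with Dₙ the
Debye functions (evaluated by adaptive quadrature to ~1e-10); Gaussian
τ = (2/π)arcsin ρ and ρ_S = (6/π)arcsin(ρ/2); Student-t τ = (2/π)arcsin ρ.
The Student-t ρ_S is computed numerically because the Gaussian arcsine law
is not exact at finite ν.  A generic quadrature implementation of both
functionals is retained as an independent cross-check of every closed form.

## Pipeline

1. **Unit conversion.** Historical doses ("1 Liang and 3 Qian") are parsed
   and converted linearly to grams with a per-dynasty table (Tang, Song,
   Yuan, Ming, Qing) shipped as a versioned JSON config.  The table is used
   verbatim even where internally odd (Tang Qian = 1.721 g is not Tang
   Liang/10); correcting historical conversion constants is out of scope.
   Unknown units or dynasties are errors, never guesses.
2. **Screening.** Records are filtered to one indication (exact lowercase
   label match) with both doses resolvable to grams; every rejection is
   counted by reason.
3. **Descriptives and normality.** Median, Hazen-interpolated IQR and a
   seeded bootstrap 95% percentile CI (of the mean by default; the basis of
   the published intervals is unstated and they are not symmetric about the
   median, so the CI statistic is a config switch and no claim of
   reproducing the published intervals is made).  Normality is screened
   with a Kolmogorov–Smirnov test against a fitted normal — its p-value
   Lilliefors-corrected by seeded Monte-Carlo null simulation, since the
   naive p is invalid with estimated parameters and the table-based
   correction is not seedable — plus Shapiro–Wilk.  The naive KS p is also
   reported for transparency.
4. **Marginals.** Pseudo-observations u = F̂(x), v = Ĝ(y) come from either
   a Gaussian-kernel CDF (default, Silverman rule-of-thumb bandwidth
   0.9·min(sd, IQR/1.34)·n^(−1/5)) clamped to [1/(2n), 1 − 1/(2n)], or
   midranks/(n+1).  The kernel route mirrors the study's smoothed-marginal
   fit; the rank route is kept because dose data is heavily tied and ranks
   keep the margins exactly exchangeable.
5. **Fitting.** Canonical pseudo-maximum likelihood: maximise
   Σ log c_θ(uᵢ, vᵢ).  One-parameter families use bounded derivative-free
   search bracketed by Kendall-τ inversion of the tie-adjusted (τ-b) sample
   τ, convergence tolerance 1e-6; the t copula profiles ν over
   {2,3,5,8,12,20,40} and refines (ρ, log ν) with L-BFGS-B, ν constrained
   to [1, 100] (ν ≥ 100 delegates to the Gaussian formulas; fitted ν in
   practice is 2–7).  A fit on the parameter boundary (e.g. comonotone
   degenerate data) is flagged, not reported as converged.
6. **Selection.** Families are ranked by the squared Euclidean distance
   d² = Σᵢ[Cₙ(uᵢ,vᵢ) − C_θ(uᵢ,vᵢ)]² between the empirical copula
   Cₙ(u,v) = (1/n)#{i: uᵢ≤u, vᵢ≤v} and the fitted copula, evaluated at the
   n sample pseudo-observations (the Cramér–von-Mises-type evaluation grid;
   a lattice would be the other defensible choice).  Ties break by higher
   pseudo-log-likelihood, then family name order.  Reported τ/ρ_S are
   model-implied from the fitted parameters, never re-estimated from data.

## Numerical choices

* **Elliptical copula CDFs** are quadrant probabilities of the bivariate
  normal/t distribution, computed as the one-dimensional integral of the
  conditional distribution (h-function) over the smaller argument,
  C(u,v) = ∫₀^min(u,v) h(max(u,v)|t) dt, with a composite Gauss–Legendre
  rule geometrically graded toward both endpoints.  Exchangeability keeps
  the conditional transition out of the integration range; the graded
  panels handle the algebraic (t^(2/ν)-type) approach to the boundary
  limit.  Verified against adaptive quadrature to ~1e-10 and against
  scipy's QMC quadrant integrator at its own (coarser) tolerance.
* **τ/ρ_S quadrature** uses a tensor product of the same corner-graded rule,
  refined (8 → 12 → 20 points per panel) until successive values agree to
  1e-5; strong-dependence densities concentrate at the (0,0)/(1,1) corners
  and defeat a single global rule.
* **Frank copula** log-density and CDF are evaluated in a factored form
  that avoids catastrophic cancellation at large α (important because the
  optimiser probes α up to 4× the τ-inversion bracket); α = 0 is an
  explicit independence special case.  Clayton is restricted to α > 0:
  the data context is positive dependence and the negative branch would
  activate the max(·, 0) truncation.
* **Sampling**: Clayton via gamma frailty, Gumbel via positive-stable
  frailty (Chambers–Mallows–Stuck), Frank by conditional inversion,
  Gaussian/t by correlated normal/χ² transforms; all driven by one
  `numpy.random.Generator`.

## Synthetic data

The prescription database behind the published tables is not deposited, so
a generator stands in for it: copula draws mapped through log-normal
marginals parameterised by median and IQR in grams, rounded to a 0.5 g tie
grid (reproducing the clumping of real doses at round values with one
knob), optionally re-encoded as historical unit strings by greedy
Liang/Qian/Fen decomposition.  Presets fix the study conditions per
indication — Student-t copulas (ρ, ν) = (0.9789, 6.0473), (0.9608, 4.0089),
(0.9179, 2.6696) with n = 110, 78, 91 — and marginals on the published
median/IQR scale.  The published insomnia partner-herb median is printed
as 9.2 g alongside an interval and a companion median of 19.2 g; the preset
uses 19.2 g, consistent with the published observation that the pair is
dosed near 1:1 for that indication.

What the generator does not emulate: co-ingredient structure, dynasty
frequencies, secular dose trends, and transcription noise in historical
sources.  Passing recovery tests therefore show the estimator chain is
sound under known dependence with realistic skew and ties — not that the
historical data satisfies any particular family.

## Validation scale

Recovery and selection studies use n = 2000 (parameter recovery, 20 seeded
replicates per family, 10% relative tolerance, ν ± 2) and n = 1000
(selection consistency, 20 seeds); these sizes make the pseudo-MLE sampling
error comfortably smaller than the tolerances while keeping the studies
quick to re-run.  Distances at the published n ≈ 100 land on the same
0.01–0.1 scale as the published tables.

## Known limitations

* Squared-Euclidean distances and parameter estimates for the real
  prescriptions cannot be reproduced without the original database; only
  the dependence-measure identities implied by the printed parameters are
  checked exactly.
* The distance criterion has no significance calibration here (no
  parametric bootstrap p-values); it ranks, as in the source analysis.
* One published Kendall column (the insomnia table) is internally
  inconsistent with its printed parameters under the standard closed forms
  and is excluded from exact checks.
* Only the bivariate case is implemented; no rotated/survival copulas or
  vine constructions.
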