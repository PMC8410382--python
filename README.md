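# dosecopula

Copula-based dose-correlation analysis for paired herbal prescription doses.

In traditional Chinese medicine, the *drug pair* — two herbs prescribed
together — is the smallest unit of compatibility, and the dose ratio between
the two herbs carries clinical meaning.  Historical prescription books
record thousands of such doses, but in dynasty-era units (Jin, Liang, Qian,
Fen) whose gram value changed between dynasties, and the resulting dose
distributions are right-skewed, heavily tied at round gram values, and far
from normal.  `dosecopula` is for epidemiologists and pharmacometricians
who want to quantify how strongly the two doses co-move, including in the
tails, where linear correlation is uninformative.

The core method: convert every dose to grams with a per-dynasty unit table;
map each margin to the unit interval via a kernel-smoothed CDF (or ranks);
fit five bivariate copula families — Clayton, Frank, Gumbel, Gaussian,
Student-t — by pseudo-maximum likelihood; rank them by the squared
Euclidean distance d² = Σᵢ[Cₙ(uᵢ,vᵢ) − C_θ(uᵢ,vᵢ)]² to the empirical
copula Cₙ; and report the best family's model-implied Kendall τ and
Spearman ρ_S, computed from the copula functionals
τ = 4∫∫C dC − 1 and ρ_S = 12∫∫C du dv − 3 (Debye-function closed forms for
Frank, arcsine laws for the elliptical families).  A synthetic prescription
generator with known copula ground truth makes the whole pipeline testable
without access to any proprietary database.

See `docs/methods.md` for the model, estimation and numerical details.

## Worked example

Generate a synthetic dataset at the diabetes-indication study conditions
(Student-t copula ρ = 0.9789, ν = 6.0473; n = 110; log-normal marginals
with median 20 g; doses tied on a 0.5 g grid), then analyse it:

```bash
dosecopula convert --dynasty Qing --dose "1 Liang and 3 Qian"
# 47.97 g

dosecopula simulate --indication diabetes --seed 42 --out sim.csv
dosecopula analyze --input sim.csv --indication diabetes --seed 0 --out outdir
```

which prints:

```
  family  squared_euclidean_distance            parameters  kendall_tau  spearman_rho  converged
 Clayton                      0.1268         alpha=11.3727       0.8504        0.9661       True
   Frank                      0.0828         alpha=29.5708       0.8723        0.9797       True
  Gumbel                      0.0946          alpha=7.5155       0.8669        0.9745       True
Gaussian                      0.0947            rho=0.9822       0.8796        0.9804       True
StudentT                      0.0968 rho=0.9826, nu=3.9240       0.8811        0.9785       True
best family: Frank (tau=0.8723, rho_S=0.9797)
```

Each row is one candidate family: its distance to the empirical copula
(smaller = better fit), its fitted parameters, and the rank correlations
implied by those parameters.  Here all families agree the doses are very
strongly positively dependent (τ ≈ 0.87); at n = 110 with heavy ties the
distance ranking between close competitors is noisy — at n = 2000 with the
tie grid off, the generating Student-t family is recovered as best in the
large majority of seeds (see `tests/test_acceptance.py`).  `outdir/`
receives `report.json`, per-table CSVs, and (with `--figures`) diagnostic
plots of the marginal fits, pseudo-observations and fitted copula density.

The same analysis is available as a library:

```python
from dosecopula.marginals import to_pseudo_observations
from dosecopula.fitting import select_best

ps = to_pseudo_observations(dose_a_grams, dose_b_grams, method="rank")
report = select_best(ps)
print(report.best.family, report.best.tau, report.best.rho_s)
```

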