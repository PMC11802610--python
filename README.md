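# orcx

Structural identifiability and observability (SIO) analysis of nonlinear ODE
models, with extensions that encode experimental information a priori, plus
numerical diagnostics of practical identifiability.

The toolbox treats unknown parameters as constant extra states, builds the
symbolic observability-identifiability matrix from Lie derivatives of the
outputs, and evaluates the observability rank condition at generic (or
user-specialized) points.  On top of the classic rank test it supports:

* **multiple experiments** — replicated states/outputs/inputs with shared
  parameters, including the reduced minimum derivative count;
* **input constraints** — per-input bounds on the number of nonzero time
  derivatives (constant, ramp, polynomial or fully generic signals);
* **unknown inputs** — lifting an unknown input and its derivatives into the
  augmented state as a derivative chain;
* **specific initial conditions** — rank tests at a numeric point with
  derivative-count escalation (a sufficient-only test: the classic stop
  criterion is lost at non-generic points);
* **per-output derivative caps** — identifiability relative to a limited
  number of measurable output derivatives;
* **SVD diagnostics** — singular value spectrum, condition number and
  numerical rank of the numerically specialized matrix;
* **bootstrap practical identifiability** — simulate, perturb with Gaussian
  noise, and refit unknowns per realization with multistart nonlinear least
  squares.

Six small example models (`M32`, `M33A`, `M33B`, `M33C`, `M34`, `M35`) are
packaged as plain-text fixtures, together with three reproducible bootstrap
study designs (`orcx.studies`).

## Library quick start

```python
import orcx

model = orcx.load_fixture("M34")

# step-wise generic rank analysis (full rank at 4 derivatives)
report = orcx.analyze(model, seed=0)
print(report.rank, report.n_derivs_used, report.per_variable)

# two experiments need only 3 derivatives
report = orcx.analyze(model, orcx.ExperimentSet(2), seed=0)

# rank test at a specific initial condition (sufficient-only)
riccati = orcx.load_fixture("M33C")
orcx.analyze_specialized(riccati, {"x": 0}, extra_derivs_max=2, seed=0)

# SVD of the numeric matrix at the packaged nominal point
glucose = orcx.load_fixture("M35")
svd = orcx.svd_observability(glucose, orcx.nominal_point(glucose))
print(svd.singular_values, svd.condition_number)

# bootstrap practical identifiability study
result = orcx.run_study("M35", n_realizations=20, seed=0)
print(result.summaries())
```

## Command line

```sh
orcx fixtures                             # list packaged models
orcx fixtures --export models/            # write .cfg files
orcx analyze M33B --seed 1 --json out.json
orcx analyze M32 --input-deriv-bound u=0  # constant-input analysis
orcx analyze M33C --ic x=0 --extra-derivs 2
orcx analyze M34 --caps 3                 # derivative-capped analysis
orcx analyze M34 --experiments 2
orcx svd M35 --csv singular_values.csv
orcx simulate M32 --n-real 3 --seed 1 --out scratch/m32
orcx bootstrap M34 --n-real 20 --seed 0 --out scratch/m34
```

Model files use a flat sectioned text format; see the packaged fixtures
(`orcx fixtures --export`) for examples.  Powers are written `^` or `**`,
and derivatives of an input `u` are named `u_d1`, `u_d2`, ...

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property-based tests (hypothesis)
for the engine invariants, brute-force oracles (fraction-exact Gaussian
elimination, Gram-matrix SVD) and an acceptance battery
(`tests/test_acceptance.py`).  The bootstrap acceptance tests are stochastic
and run three scaled-down studies (20 noise realizations each); they take a
few minutes.

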