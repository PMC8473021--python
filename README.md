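# dentage

Estimation of chronological (metric) age of children and adolescents —
48 to 144 months — from panoramic dental radiographs (pantomograms),
for clinicians, forensic odontologists and anthropologists who need an
objective alternative to atlas-based dental-age staging.

The method works on manually annotated landmarks, not pixels: 36 named
points on the upper-right canine (FDI 13) and the lower-right canine,
second premolar, first and second molar (FDI 43/45/46/47) define a set
of 21 dimensionless ratio indicators

```
X01 = |C13C43| / |C15C45|,  …,  X07 = |C43A43| / |P43A43|,  …,
X21 = |A45M45| / |A46M46|
```

where `C` is a crown point, `A` a root apex, `M` a mandibular-border
point, `CeM`/`CeD` the mesial/distal cemento-enamel junctions and a
leading `P` the projected reference counterpart.  Because every
quantity is a ratio of Euclidean distances, the indicators are
invariant to image translation, rotation and magnification.

Age in months is then regressed on these indicators (plus binary sex
for the combined model) with a radial-basis-function network

```
f(x) = b + Σ_j w_j exp( −‖x − c_j‖² / 2σ_j² )
```

fitted on min–max–scaled inputs with k-means centers, nearest-center
widths and a ridge-regularized linear output layer.  The workflow
follows the original modelling protocol: a random 2:1:1
train/validation/test split, a seeded "designer" search over candidate
hidden-layer sizes retaining the best networks by validation RMSE, a
sensitivity analysis that scores each input by the error quotient

```
q_k = RMSE(input k mean-substituted) / RMSE(full model)
```

and an input-pruning step that drops low-quotient variables and
retrains.  Model reports give, per partition, the "quality" (Pearson
correlation between predicted and observed age) and the RMSE on the
unit-scaled output (0.036 ≈ 3.5 months over the 96-month span).

The clinical images behind the original models are private, so the
package ships a synthetic cohort generator emulating the study
population (619 cases: 296 girls, 323 boys; monotone maturation
trajectories per indicator) together with the published sensitivity
rankings of the three final models as reference fixtures.

## Worked example

```sh
dentage simulate --out cohort.csv --seed 1
dentage run --indicators cohort.csv --outdir results --seed 1
```

prints (to stderr)

```
wrote 619 cases to cohort.csv
INFO dentage: cohort: 619 cases, 22 inputs
INFO dentage: split 309/154/156 (train/valid/test)
INFO dentage: designer search: kept 10 candidates; best RBF 22:22-15-1:1 (validation RMSE 0.0163)
INFO dentage: pruned RBF 22:22-15-1:1 -> RBF 22:22-15-1:1
final model RBF 22:22-15-1:1: testing quality 0.9984, testing error 0.0161; bundle in results
```

The topology string `RBF 22:22-15-1:1` reads inputs:inputs–hidden–
outputs:outputs — here 22 inputs (X01–X21 + SEX) and 15 Gaussian
units.  Testing quality 0.9984 is the correlation between predicted
and true age on the 156 held-out cases; testing error 0.0161 on the
scaled output corresponds to about 1.5 months RMSE.  `results/`
contains the model JSON, the six-row report CSV (initial and pruned
model), the sensitivity ranking CSV (`variable,quotient,rank`), the
per-case predictions CSV and a run log with the full configuration —
re-running with the same seed reproduces every file byte for byte.

The same steps are available as library calls (`generate_cohort`,
`run_pipeline`, `fit_rbf`, `sensitivity_analysis`, …) and as separate
subcommands (`indicators`, `train`, `sensitivity`, `prune`,
`predict`) for landmark CSV exports of real measurements.

## Limitations

The models are valid only for ages 48–144 months (enforced at
ingestion, with an override flag), and synthetic-cohort results
demonstrate recovery of a known monotone growth signal, not clinical
accuracy; see `docs/methods.md` for the generator's assumptions and
the numerical details.
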