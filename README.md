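# augbin

Augmented binary analysis of tumour-response endpoints in phase II
oncology trials.

Solid-tumour trials usually dichotomise each patient's continuous tumour
measurements into responder / non-responder, discarding most of the
information in the data.  The augmented binary approach keeps the
dichotomised *endpoint* (so results stay clinically interpretable) but
estimates its probability from a joint model for the continuous tumour
log size ratios and the discrete progression events (new lesions), which
typically shrinks confidence intervals by 15–30% — equivalent to a
substantially larger trial.

The package implements:

- **eAugbin** — the extended augmented binary method: the response
  probability is an integral of the multivariate-normal model for the
  log tumour size ratios weighted by logistic new-lesion factors that
  depend on the (latent) previous tumour size, evaluated by adaptive
  quasi–Monte Carlo cubature.
- **mAug** — the modified augmented binary method: a factorisation into
  per-visit no-new-lesion probabilities times a multivariate-normal
  rectangle probability, with a trimmed-average chain for visits beyond
  a patient's follow-up.  Much cheaper than eAugbin and extends cleanly
  to best-observed-response endpoints with many visits.
- **Comparators** — the plain binary method (Wilson interval / logistic
  regression) and Karrison's continuous tumour-change test.
- **Endpoints** — fixed-time response, best observed response (BOR), and
  confirmed BOR, with an optional intermediate no-growth constraint.
- **Simulation machinery** — named scenario presets, closed-form and
  Monte-Carlo truth oracles, single-arm operating-characteristic studies
  and two-arm type-I error / power studies, all exactly reproducible
  from a seed.

Supported designs: single-arm and two-arm randomised trials, monotone
missingness (patients leave the study at progression or dropout and do
not return).

## Data format

Long-format CSV, one row per visit:

```
patient_id,arm,visit,tumour_size,new_lesion
p00000,,0,0.625095466604667,0
p00000,,1,1.2720826613955856,0
p00000,,2,1.7329066606166466,0
```

Visit 0 is baseline; `tumour_size` is the RECIST sum of longest
diameters (strictly positive); `new_lesion` is 1 at the first visit a
new lesion is detected; `arm` is empty for single-arm trials, 0/1 for
randomised ones.  Follow-up must stop at (or before) new-lesion
progression — the model treats later visits as missing.

## Worked example

Simulate a 75-patient single-arm trial from a named preset and analyse
the fixed-time response endpoint at visit 2:

```sh
$ augbin simulate --preset table1-T2-a --seed 7 --out trial.csv
wrote 75 patients (table1-T2-a-1.5-g0.0) to trial.csv

$ augbin analyze trial.csv -T 2 --methods bin,maug
{
  "bin": {
    "estimate": 0.38666666666666666,
    "ci": [
      0.284552171134325,
      0.4998252331617777
    ],
    "logit_se": 0.23711155403200465,
    "method": "bin",
    "endpoint": "fixed_time",
    "n": 75
  },
  "maug": {
    "estimate": 0.36265062812181176,
    "ci": [
      0.2822139563569784,
      0.45158960960688693
    ],
    "logit_se": 0.18858917234504374,
    "method": "maug",
    "endpoint": "fixed_time",
    "n": 75
  }
}
```

The mAug interval (width 0.169) is about 21% narrower than the binary
Wilson interval (width 0.215) on this dataset.  The fitted joint model
can be inspected directly:

```sh
$ augbin fit trial.csv -T 2
n = 75, arms = 1, converged = True
log-likelihood = -200.933
beta  = [-0.194  -0.4241]
omega = -0.1435
Sigma =
[[0.4088 0.4728]
 [0.4728 0.9895]]
new-lesion alpha = [-1.7714 -0.8215]
new-lesion gamma = [ 0.4209 -1.2858]
```

The same analysis from Python:

```python
from augbin import (EndpointSpec, binary_estimate, fit_model,
                    read_trial_csv, response_ci)

ds = read_trial_csv("trial.csv")
spec = EndpointSpec("fixed_time", T=2)
fit = fit_model(ds, T=2)
print(response_ci(ds, fit, spec, engine="maug"))
```

which prints `mAug estimate 0.363, 95% CI (0.282, 0.452)` versus the
binary `0.387, 95% CI (0.285, 0.500)`.

## Simulation studies

`augbin study` runs a replicated study from a YAML config:

```yaml
# study.yaml
kind: single_arm
preset: table1-T2-a
endpoint: {kind: fixed_time, T: 2}
methods: [bin, maug]
```

```sh
augbin study --config study.yaml --reps 1000 --seed 1 --workers 4 --out results.csv
```

The output CSV reports, per method, the mean estimate, empirical
coverage of the true response probability, mean CI width and the
percent width reduction versus the binary method.  Two-arm configs
(`kind: power`) report rejection rates over a grid of treatment
effects.  Results are invariant to the worker count: each replicate
draws its random numbers from a seed sequence derived from
`(seed, replicate)`.

`scripts/acceptance.py --seed 1 --out results.json` recomputes the
headline operating characteristics (truth oracle, Table-1-style width
reductions and coverage, and two-arm type-I errors) from scratch.

## Testing

```sh
python -m pytest tests/                        # full suite
python -m pytest tests/ --ignore=tests/test_acceptance.py   # fast subset (~25 s)
```

`tests/test_acceptance.py` re-runs the replicated simulation studies and
takes around 15 minutes on one CPU.

## Package layout

| module | contents |
| --- | --- |
| `augbin.data` | patient records, endpoint definitions, CSV I/O, classification |
| `augbin.cohort` | generative scenarios, presets, truth oracles |
| `augbin.mvnfit` | maximum-likelihood fit of the joint model |
| `augbin.probability` | eAugbin / mAug response-probability engines |
| `augbin.inference` | delta-method CIs, bootstrap, two-arm Wald tests |
| `augbin.comparators` | binary method, Karrison test, permutation checks |
| `augbin.study` | replicated simulation studies |
| `augbin.cli` | `augbin` command-line interface |
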