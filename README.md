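# ralisim — linking Rasch-scaled longitudinal test forms

`ralisim` is a Monte-Carlo laboratory for a question that panel studies and
other small-item-pool assessments face constantly: when a latent competence
is measured at several waves with *different* short test forms that overlap
only in a handful of common ("anchor") items, how well do the standard
IRT linking methods recover the growth of the latent mean and the latent
variance — and how many anchors are enough, especially when the Rasch
model's equal-discrimination assumption is mildly violated?

It is written for psychometricians and methodologists who want a fast,
fully reproducible pipeline: synthetic data generation, Rasch estimation,
four linking methods, and bias/RMSE evaluation, each usable on its own.

## The model and the methods

Responses follow the Rasch model
`P(X_ni = 1 | β_n, δ_i) = exp(β_n − δ_i) / (1 + exp(β_n − δ_i))`
with person ability β and item difficulty δ on a common logit scale
(misfitting data are generated from the 2PL, `logistic(α_i (β_n − δ_i))`
with α_i ~ N(1, 0.14²), but fitting is always Rasch). Calibration is
marginal maximum likelihood with a normal latent distribution, maximized by
the Bock–Aitkin EM algorithm on Gauss–Hermite (or quasi-Monte-Carlo)
quadrature.

Four linking methods place the waves on the first wave's scale:

- **FPC** (fixed parameter calibration): each new form is calibrated with
  its anchors fixed at the previous form's linked estimates, estimating the
  latent mean and variance directly;
- **m/m** (mean/mean): the constant `v = M(δ̂_B,anchors) − M(δ̂_A,anchors)`
  shifts form A onto reference form B;
- **wm/m** (weighted mean/mean): as m/m with anchors weighted by the
  inverse of their squared standard errors;
- **CC** (concurrent calibration): one joint multi-group fit with anchor
  difficulties constrained equal and a latent normal per wave.

Recovery is scored by bias, relative bias and RMSE of the common-scale
latent mean and variance across replications (see `docs/methods.md` for
the formulas, the truth references, and every numerical choice).

## Worked example

Twenty replications of one condition — Rasch-conform data, 5 of 25 items
serving as anchors, N = 500 per wave — comparing the three separate
calibration methods:

```python
import ralisim as rl

config = rl.StudyConfig(
    methods=("fpc", "mean_mean", "weighted_mean_mean"),
    misfit_conditions=(False,),
    anchor_counts=(5,),
    sample_sizes=(500,),
    n_replications=20,
    master_seed=42,
)
frame = rl.run_study_frame(config)
summary = rl.aggregate(frame, by=["method"], truth="sample")
cols = ["method", "timepoint", "bias_mean", "rmse_mean",
        "bias_variance", "rmse_variance"]
print(summary[summary.timepoint > 1][cols]
      .to_string(index=False, float_format=lambda v: f"{v:7.3f}"))
```

```
            method  timepoint  bias_mean  rmse_mean  bias_variance  rmse_variance
               fpc          2      0.008      0.047         -0.003          0.061
               fpc          3     -0.007      0.096          0.005          0.052
               fpc          4      0.005      0.114          0.001          0.055
         mean_mean          2      0.005      0.048         -0.006          0.061
         mean_mean          3     -0.005      0.094          0.008          0.052
         mean_mean          4      0.006      0.116         -0.000          0.057
weighted_mean_mean          2      0.005      0.048         -0.006          0.061
weighted_mean_mean          3     -0.009      0.097          0.008          0.052
weighted_mean_mean          4      0.002      0.114         -0.000          0.057
```

Reading the table: none of the methods is systematically biased (bias of
the latent mean within ±0.01 logits of zero, variance likewise), the three
methods are practically interchangeable, and the RMSE of the linked mean
grows from ≈0.05 logits at wave 2 to ≈0.11 at wave 4 because each
additional link in the chain t2→t1, t3→t2, t4→t3 adds independent anchor
noise. The variance RMSE (≈0.06 at N=500) is flat across waves, since a
translation link cannot touch the scale.

The same machinery is exposed piecewise — `build_item_banks`,
`simulate_responses`, `fit_mml_em`, `fit_concurrent`, `run_fpc`,
`run_separate_linking`, `mean_mean_constant`, … — and from a shell:

```sh
ralisim demo                     # 2-replication smoke study, all methods
ralisim run --reps 100 --out results/
ralisim summarize --in results/ --group-by method,anchor_count
```

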