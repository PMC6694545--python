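# dynapred

Dynamic landmark survival prediction with censoring-robust accuracy
evaluation, plus a synthetic longitudinal cohort generator for end-to-end
testing.

The package compares two ways of predicting event-free survival over a
2-year horizon from a landmark time `t0`:

- **static model** — a single baseline Cox proportional hazards model
  (baseline categoricals + baseline labs), applied at later landmark times by
  plugging in the current lab values;
- **dynamic (landmark) model** — a Cox model refit at each `t0` on the
  subjects still at risk, with change-from-baseline lab covariates.

Accuracy at each `(t0, tau = t0 + horizon)` is estimated with inverse
probability of censoring weighting (IPCW): time-dependent AUC, Brier score, a
survival extension of the Hosmer-Lemeshow statistic, and the continuous net
reclassification improvement (NRI), wrapped in repeated 2/3-1/3
train/test splitting with subject-level bootstrap confidence intervals for
the dynamic-minus-static differences.

## Layout

| module | contents |
| --- | --- |
| `dynapred.cohort` | synthetic cohort generator: config, biomarker random walks, piecewise-exponential event times, interval detection, censoring |
| `dynapred.cox` | Cox partial-likelihood engine (Newton-Raphson, Efron/Breslow ties), Breslow baseline hazard, survival predictions, hazard-ratio tables |
| `dynapred.landmark` | landmark risk sets, change-from-baseline covariates, static/dynamic predictions |
| `dynapred.metrics` | censoring KM, IPCW weights, AUC, Brier, Hosmer-Lemeshow, NRI |
| `dynapred.protocol` | train/test splitting, cross-validated estimates, bootstrap differences, full study report |
| `dynapred.io` / `dynapred.cli` | CSV schemas, report output, `dynapred` command line |

## CLI

```bash
# simulate a cohort (two CSVs: subjects.csv, labs.csv)
dynapred simulate --seed 1 --n 1000 --out data/

# run the full static-vs-dynamic comparison
dynapred run-study --cohort data/subjects.csv --labs data/labs.csv \
    --seed 1 --out report/

# score externally supplied predictions
dynapred metrics --predictions preds.csv \
    --cohort data/subjects.csv --labs data/labs.csv --out metrics.csv
```

`simulate` and `run-study` accept `--config cfg.yaml` (YAML or JSON) mirroring
`CohortConfig` / `ProtocolConfig`. Reports are written as `report.json`,
`report.csv` and a metrics-vs-`t0` plot.

## Python API sketch

```python
import dynapred as dp

cohort = dp.generate_cohort(dp.CohortConfig(n_subjects=1000, seed=1))
frame = dp.build_landmark_frame(cohort, t0=1.0, horizon=2.0)
dyn_fit = dp.fit_landmark_model(frame)
stat_fit = dp.fit_static_model(cohort)

pred_d = dp.predict_dynamic(dyn_fit, frame)
pred_s = dp.predict_static_at_landmark(stat_fit, frame)

print(dp.auc_ipcw(pred_d, frame).value, dp.brier_ipcw(pred_d, frame).value)
print(dp.nri_components(pred_d, pred_s, frame).nri)

report = dp.run_full_study({"placebo": cohort}, dp.ProtocolConfig(seed=1))
```
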