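# carvemetrics

Wearable-sensor biomechanics of alpine ski carving, built for studies that
compare ski-boot designs (here: a cable/dial wrap closure, "BOA", against a
conventional four-Buckle shell) on snow and in the lab.

During carving, skiers alternate left/right turns on the ski's edge; how
quickly and how hard they load the outside (downhill) ski is a performance
signature, and how the boot shell distributes pressure over the foot is a fit
signature. `carvemetrics` turns two wearable streams and one lab measurement
into those signatures:

* **Boot roll gyroscopes (1,125 Hz)** — turn segmentation from the 0.5-Hz
  zero-lag Butterworth-filtered roll rate (local maxima mark the ski-flat
  instants), then per-turn peak edge angles by integrating the 6-Hz-filtered
  roll rate with an endpoint-anchored linear drift correction.
* **Pressure insoles (100 Hz, 3 regions per foot)** — per-foot total normal
  force, coarse 0.5-Hz turn apices with left/right alternation enforcement,
  then per-turn features from the 6-Hz-filtered force: peak downhill force,
  peak uphill force in the same symmetric 1-s window, rate of force
  development (RFD, the secant slope from the previous force minimum to the
  peak), time to peak, and average force. Trials with fewer than five
  detected turns are excluded.
* **Static pressure grids** — an 18 × 10 dorsal pad (mean/SD/total/peak
  pressure, contact area) and a 235-sensel plantar insole reduced to eight
  regions (medial/lateral × heel, midfoot, metatarsals, toes).

Configuration effects are estimated with linear mixed-effects models (REML,
via statsmodels MixedLM) and reported as percent differences between
estimated marginal means (EMMs):

```
eq1:  Outcome ~ Config + TurnDirection + TrialNo + (Config | Subject)   # on-snow turns
eq2:  Outcome ~ Config + (1 | Subject)                                  # subjective scores
eq3:  Outcome ~ Config + Overlap + (1 | Subject)                        # static pressures
```

Because the underlying human-subject recordings are not public, the package
ships a first-class synthetic cohort generator (`carvemetrics.synthetic_data`)
that emulates the study design — subject random intercepts and
configuration slopes, turn-direction and trial covariates, shell-overlap
readings — with exact per-turn ground truth, so every stage of the pipeline
is testable by parameter recovery.

## Worked example

Simulate 8 subjects × 2 configurations × 3 runs, extract per-turn force
features, and fit the on-snow model for peak downhill force:

```python
import pandas as pd
from carvemetrics import SimConfig, fit_model
from carvemetrics.force_features import apply_exclusions
from carvemetrics.pipeline import run_force_pipeline
from carvemetrics.synthetic_data import simulate_run

cfg = SimConfig(n_subjects=8, seed=42)
frames = []
for s in range(8):
    for config in ("BOA", "Buckle"):
        for trial in (1, 2, 3):
            run = simulate_run(s, config, trial, sim_config=cfg, include_imu=False)
            meta = {"subject_id": run.subject_id, "config": config, "trial_no": trial}
            frames.append(run_force_pipeline(run.force_left, run.force_right, meta))
turns, report = apply_exclusions(pd.concat(frames, ignore_index=True))
print(f"{len(turns)} turns from {turns.subject_id.nunique()} subjects")
est = fit_model(turns, "eq1", "peak_downhill_force")
print(f"peak downhill force: EMM BOA {est.emm_boa:.1f} N vs Buckle {est.emm_buckle:.1f} N")
print(f"percent difference: {est.percent_difference:+.2f}% (p = {est.p_value_config:.4f})")
```

Output:

```
384 turns from 8 subjects
peak downhill force: EMM BOA 782.3 N vs Buckle 751.6 N
percent difference: +4.08% (p = 0.0000)
```

The generator injects a +30 N (4%) configuration effect on a 750 N baseline
peak; the pipeline recovers +4.08% from the noisy traces, and the Wald test
on the configuration coefficient is decisive at this effect size.

The same workflow is available from a shell:

```bash
carvemetrics simulate --out cohort/ --seed 7 --subjects 8
carvemetrics validate cohort/
carvemetrics report --cohort cohort/ --out report/
carvemetrics segment-imu --input cohort/cohort/S00/BOA/trial1/imu_left.csv \
    --side left --out turns.json
```

`report/summary.csv` holds one row per outcome × model with both EMMs, the
percent difference, and the configuration p-value.

## Layout

| module | contents |
| --- | --- |
| `signal_core` | `UniformSeries`, zero-lag Butterworth filtering, thresholded local extrema |
| `imu_edge` | turn windows and per-turn edge angles from boot roll rate |
| `force_features` | per-foot total force, alternation-enforced apices, turn features, exclusions |
| `static_pressure` | pressure grids, dorsal metrics, eight-region plantar scheme |
| `effects_stats` | eq1/eq2/eq3 mixed models, EMMs, percent differences, score transform |
| `synthetic_data` | cohort generator with exact ground truth |
| `config` / `pipeline` / `cli` | pipeline configuration, orchestration, command-line surface |

See `docs/methods.md` for the modelling choices, generator design and known
limitations.
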