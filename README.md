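# vestigait

Dynamic-stability gait analysis for vestibulopathy cohorts.

Patients with bilateral (BV) or unilateral (UV) vestibulopathy suffer
chronic imbalance that standard clinical scales capture only coarsely.
`vestigait` turns 3-D motion-capture marker trajectories recorded during
walking tasks (the Functional Gait Assessment battery plus self-selected
walking speeds and dual tasks) into a battery of 20 biomechanical
parameters across four families, then evaluates which task/parameter
combinations are worth a clinician's time:

- **dynamic stability** — medio-lateral CoM range of motion; margins of
  stability `MoS = BoS − xCoM` with the extrapolated center of mass
  `xCoM = CoM + v/ω₀`, `ω₀ = √(g/l)` (inverted-pendulum eigenfrequency);
  whole-body angular momentum `L = Σᵢ mᵢ(rᵢ−r_CoM)×(vᵢ−v_CoM) + Iᵢωᵢ`
  over a 13-segment model, reported as per-plane ranges;
- **spatial** — zone-based CoM and foot scores (nested medio-lateral floor
  bands about the walkway midline), step width, maximum medio-lateral
  distance between ipsilateral steps (catch-up steps), tandem step count;
- **temporal** — walking speed, double-support time, task time;
- **kinematic** — head anchoring index
  `AI = (σ_r − σ_a)/(σ_r + σ_a)` per plane (σ_a: SD of head-in-space
  orientation, σ_r: SD of head-on-trunk orientation; +1 = head stabilized
  in space, −1 = head and trunk move "in block"), normalized head/trunk
  angular-velocity RMS, and GaitSD (root mean between-cycle variance of 9
  lower-body kinematic curves, time-normalized to 101 points per cycle).

Validity statistics follow a nonparametric design: Shapiro–Wilk screening,
Kruskal–Wallis across the three groups (BV/UV/HS) per task × parameter,
Dunn post-hoc tests with Holm correction when significant, Pearson
correlations with the Dizziness Handicap Inventory (DHI) per patient
group, categorical thresholds (excellent/good/moderate/fair/poor), and a
relevance synthesis: a cell is *relevant* when it discriminates between
groups (≥ moderate), correlates with the DHI (≥ moderate), and has
excellent clinical applicability — the cells that survive form a
short-form FGA task report.

Because raw patient recordings are not required, the package ships a
synthetic kinematic walker (`vestigait.synthetic_gait`) that renders the
full marker set at 100 Hz with group-programmable walking speed, step
width, sway, head–trunk coupling, catch-up steps and severity-linked DHI
scores, plus ground-truth sidecars — every pipeline stage is testable
end to end without downloads.

## Worked example

```python
import numpy as np
from vestigait import synthetic_gait as sg, pipeline as pl
from vestigait.trial_io import SubjectMeta
from vestigait.validity_stats import simulate_kw_power

# one severely affected bilateral-vestibulopathy walker, eyes closed
profile = sg.PRESETS["BV"]
rng = np.random.default_rng(0)
draw = sg.draw_subject(profile, "BV", "BV01", rng)
trial, truth = sg.generate_trial(profile, "eyes_closed", draw, seed=7)
meta = SubjectMeta("BV01", "BV", affected_side="both",
                   height=draw.height, mass=draw.mass)
params = pl.compute_trial_parameters(trial, meta)
for name in ("Walking_speed", "Step_width", "ML_CoM_rom", "MoS_ML",
             "HeadAI_yaw", "GaitSD"):
    print(f"{name:14s} {params[name]: .3f}")
print(f"programmed speed {truth['programmed']['speed']:.3f} m/s, "
      f"width {truth['programmed']['step_width']:.3f} m")

power = simulate_kw_power([(1.09, 0.22, 10), (1.05, 0.17, 10),
                           (1.29, 0.09, 10)], alpha=0.05, n_sim=20000, seed=1)
print(f"Kruskal-Wallis power: {power:.3f}")
```

prints

```
Walking_speed   1.065
Step_width      0.205
ML_CoM_rom      0.182
MoS_ML          0.156
HeadAI_yaw     -0.555
GaitSD          0.491
programmed speed 1.050 m/s, width 0.221 m
Kruskal-Wallis power: 0.914
```

Reading the numbers: the walker progresses at 1.07 m/s (the pipeline
recovers the programmed 1.05 m/s from the detected foot strikes and the
9-segment CoM trajectory); eyes-closed widens the base of support to
0.21 m and the CoM sways over an 0.18 m medio-lateral range; the ML
margin of stability is positive (mechanically stable — patients buy
stability with wide steps); the negative yaw anchoring index says the
head rides rigidly on the trunk ("en bloc" stabilization, typical of
vestibular loss); GaitSD quantifies stride-to-stride kinematic
variability in degrees.  The last line is the Monte-Carlo power of a
three-group Kruskal–Wallis test at the groups' comfortable walking-speed
distributions (n = 10 per group, α = 0.05).

## Command line

```bash
vestigait all --seed 42 --out results/        # synthetic end-to-end run
vestigait generate --seed 42 --out cohort/    # fixture trials + cohort CSV
vestigait analyze cohort/ cohort/cohort.csv --out parameters.csv
vestigait stats parameters.csv cohort/cohort.csv --out stats/
vestigait report stats/relevance_matrix.csv --parameters parameters.csv
```

`all` writes the long-form parameter table, the Kruskal–Wallis/Dunn
discriminant grid, the DHI correlation table, the relevance matrix (CSV +
heatmap PNG), the short-form task report, and a metadata file recording
every methodological switch (filter, zones, thresholds, normalizations).

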