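# crossgaze

Head–eye movement analysis of pedestrian street-crossing behaviour in visual
impairment, as measured with a head-mounted VR display with integrated eye
tracking.

People with central, peripheral, or combined visual-field/acuity loss scan a
traffic scene differently: central loss provokes shorter, more frequent
saccades; combined loss produces severe under-scanning (fewer head turns,
reduced total saccade amplitude) and delayed recognition of safe crossing
gaps. `crossgaze` packages the whole analysis chain needed to study this —
from raw gaze/head streams to group statistics — together with a calibrated
synthetic-behaviour generator, so the pipeline can be exercised and validated
end-to-end without access to participant recordings.

## What is in the box

* **scenario** — the 45 s traffic scene: 10 car passes (3 red) described by
  azimuth tracks, a ±45° hazard zone, and derivation of the car-free safe
  crossing windows ([16, 25] s and [34, 45] s for the default schedule).
* **synthetic** — cohort and trace generator: 120 Hz gaze and 90 Hz head
  streams built from fixational drift, Poisson-timed microsaccades,
  scene-driven macrosaccades with main-sequence kinematics, head-yaw ramps,
  correlated tracker noise, and verbal responses; every injected event is
  recorded in a ground-truth log.
* **detection** — I-VT segmentation: saccades are runs of angular gaze
  velocity > 50 °/s (central difference on the great-circle angle), split
  into microsaccades (amplitude < 1.2°) and macrosaccades (≥ 1.2°);
  fixations are the pauses between macrosaccades; head turns are signed
  yaw-velocity excursions with ≥ 5° net amplitude.
* **metrics / scoring** — per-viewing summaries (counts, total/average
  amplitudes, velocities, fixation durations) and task scores: crossing
  times CT1/CT2 (earliest in-window response) and red-car count correctness.
* **clinical** — logMAR conversion, visual-field averaging, functional
  impairment typing (central / peripheral / combined / control) and WHO
  category assignment with most-severe-criterion tie-breaking.
* **stats** — Shapiro–Wilk annotation, Mann–Whitney U (exact when feasible),
  Kruskal–Wallis, Bonferroni pairwise contrasts vs controls, Spearman ρ, and
  covariate-limited OLS (group + age + MoCA, controls as reference).

## Worked example

```python
import crossgaze as cg

sim = cg.simulate_study(seed=20251015)          # 59 participants x 2 tasks
summary = cg.summarize_study(sim)               # detect + summarize + score
cohort = cg.augment_cohort(cg.synthetic.cohort_to_frame(sim.cohort))
m = summary.merge(cohort, on="participant_id")

sc = m[m.task == "safe_crossing"]
for group in ("control", "central", "peripheral", "combined"):
    g = sc[sc.group == group]
    print(f"{group:10s} ct1 {g.ct1.median():5.2f} s   "
          f"macrosaccades {g.n_macrosaccades.median():5.0f}   "
          f"total amplitude {g.total_macrosaccade_amplitude.median():6.0f} deg")
r = cg.mann_whitney(sc[sc.group != "control"].ct1, sc[sc.group == "control"].ct1)
print(f"patients vs controls CT1: U={r.statistic:.0f}, p={r.p_value:.2g}")
```

prints

```
control    ct1 17.81 s   macrosaccades   188   total amplitude   3143 deg
central    ct1 19.07 s   macrosaccades   222   total amplitude   2886 deg
peripheral ct1 18.89 s   macrosaccades   200   total amplitude   3070 deg
combined   ct1 19.19 s   macrosaccades   183   total amplitude   2215 deg
patients vs controls CT1: U=688, p=3.1e-08
```

CT1 is the time (seconds from scene start) at which a participant first
declares the road safe to cross; controls respond ~1.3 s earlier than
patients. Central-impairment cohorts make more macrosaccades (eccentric
viewing), while combined impairment shows the lowest total macrosaccade
amplitude — the under-scanning phenotype.

## Command line

```sh
crossgaze pipeline --seed 20251015 --out run/   # simulate -> detect -> analyze
crossgaze simulate --config config.yaml --out run/
crossgaze detect run/traces --out run/
crossgaze analyze run/summary.csv run/cohort.csv --out run/
```

Outputs are plain CSV/JSON with a config-hash header; reruns with the same
seed and configuration are byte-identical.

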