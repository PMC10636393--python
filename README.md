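# parcelstim

Planning toolkit for **personalized, parcel-guided repetitive transcranial
magnetic stimulation (rTMS)** in depression. Starting from parcellated
resting-state BOLD time series (one row per cortical/subcortical parcel),
the package

1. cleans the parcel signals (DVARS frame scrubbing, polynomial
   detrending, CompCor-style confound regression),
2. embeds each subject's functional-connectivity matrix in the **tangent
   space** of the SPD manifold at a healthy reference cohort's geometric
   mean,
3. z-scores every connectivity edge against a **normative model** fitted
   to the reference cohort — after excluding the noisiest third of edge
   pairs — and flags 3-sigma outliers as hyper- or hypoconnected,
4. converts network-restricted anomaly matrices into a ranked
   prescription of at most **three cortical stimulation targets** within
   30 mm of the scalp, assigning inhibitory **cTBS** to predominantly
   hyperconnected parcels and excitatory **iTBS** to hypoconnected ones,
5. builds the theta-burst pulse trains and the accelerated 5 x 5 session
   schedule, and
6. classifies clinical outcomes (BDI response = >= 47 % decrease from
   baseline, remission = BDI <= 12; EQ-5D trajectories; Mann-Whitney
   comparison of percent change between treatment-resistant and other
   patients).

It is written for methods researchers who want a fully testable,
self-contained model of this planning pipeline: a synthetic-cohort module
generates reference cohorts, patients with *injected* edge anomalies of
controlled tangent-space magnitude, parcel geometry, and outcome records,
so every stage runs and is validated without any scan data.

## The model

For subject $s$ with regularized covariance $C_s$ and reference geometric
mean $G$ (Fréchet mean under the affine-invariant metric), the tangent
representation is

$$T_s = \log\!\big(G^{-1/2}\, C_s\, G^{-1/2}\big).$$

The normative model stores, for every upper-triangle edge $e$, the
cross-subject mean $\mu_e$ and sample SD $\sigma_e$ over the reference
cohort, plus an exclusion mask covering the top $\lceil E/3\rceil$ edges
by variance. A patient edge is anomalous when

$$z_e = \frac{t_e - \mu_e}{\sigma_e}, \qquad |z_e| > 3,$$

with $z_e > 3$ read as hyperconnectivity (treated with cTBS at the most
burdened incident parcels) and $z_e < -3$ as hypoconnectivity (iTBS).

## Worked example

```bash
parcelstim run --out demo/ --seed 3
```

runs the full synthetic study (200 reference subjects, 60 parcels, 128
volumes at TR 2.8 s) end to end: it fits the normative model, generates a
patient carrying a hyperconnected 4-clique plus one hypoconnected edge
(all calibrated to z = 5), scores it, and writes the atlas, normative
model, anomaly matrix + heatmap, prescription and protocol. The
prescription it prints for seed 3:

```
rank  parcel     protocol  hyper  hypo  depth_mm
   1  LDMN000    cTBS          3     0      22.8
   2  LDMN002    cTBS          3     0      23.9
   3  RDMN005    cTBS          3     0      22.5
```

Three of the four clique parcels are prescribed (the cap is three), all
cTBS because their anomalous edges are hyperconnections. The attached
protocol delivers 1800 pulses per cTBS target (600 three-pulse 50-Hz
bursts at 5 Hz), 5400 pulses per session over ~8 minutes, and 25 sessions
(5/day x 5 days, 1-h gaps) for 135,000 pulses in the course, all at 80 %
of resting motor threshold.

The published cohort's target table ships with the package:

```bash
parcelstim report
```

prints the 19 target rows (76 targets over 26 patients; 69 cTBS / 7 iTBS;
L8Av shared by 19 patients, 22.4 % of targets in its cTBS form) and flags
the one row whose printed label and full name disagree on hemisphere.

Synthetic outcome records reproduce the cohort's headline rates; from
`summarize_cohort(generate_outcomes(26, seed=1))`:

```
Response (post)            31%
Remission (post)           62%
Response (follow-up)       58%
Remission (follow-up)      68%
BDI   baseline             25.92 +/- 7.43
TRD vs non-TRD %change (post): U=36.0 p=0.0824
```

i.e. 8/26 post-treatment responders, 16/26 remitters, and 11/19 vs 13/19
among follow-up completers, with no significant TRD difference — the
structure the outcome analysis expects.

## Layout

| Module | Role |
| --- | --- |
| `parcelstim.cohort` | synthetic reference cohorts, anomaly-injected patients, outcome records |
| `parcelstim.preprocess` | DVARS scrubbing, detrending, CompCor-style confound regression |
| `parcelstim.connectivity` | correlation/covariance, shrinkage, Fréchet mean, tangent embedding |
| `parcelstim.normative` | normative model fit, 3-sigma anomaly scoring, network restriction, heatmaps |
| `parcelstim.prescribe` | anomaly burden, target ranking, cTBS/iTBS assignment |
| `parcelstim.protocol` | pulse trains, sessions, accelerated course |
| `parcelstim.outcomes` | response/remission rules, severity bands, cohort summaries, rank-sum test |
| `parcelstim.reporting` | published cohort target table and its arithmetic |
| `parcelstim.pipeline` / `parcelstim.cli` | end-to-end driver and `parcelstim` command |

See `docs/methods.md` for the model details, the synthetic-data design
and the package's numerical choices.
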