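# wallmap

3D mapping of wall shear stress (WSS), wall thickness (WT) and vessel
diameter on carotid-bifurcation surface meshes, with cohort-averaged
atlas statistics, subject-level bootstrap inference, and linear
wall-model prediction of individual WT maps.

## The problem

Atherosclerotic wall thickening concentrates where blood flow is
disturbed — classically the lateral wall of the internal carotid artery,
where WSS is low. Within a single subject, per-vertex scatter of WT
against WSS is dominated by measurement noise and shows little
structure. Averaging the maps over a cohort on a shared surface
geometry suppresses uncorrelated noise and reveals the underlying
spatial relationship, but vertex-wise statistics on averaged maps are
invalidated by spatial autocorrelation; the appropriate inference
resamples *subjects*, not vertices.

`wallmap` implements that workflow end to end and couples it to a
synthetic-cohort generator with known ground truth, so every stage —
WSS estimation, map extraction, atlas averaging, bootstrap inference
and prediction — can be verified against closed forms and generating
parameters.

## Model and statistics

Per vertex of each subject's lumen surface:

* **WT** — shortest point-to-surface distance to the outer
  (adventitial) wall [mm];
* **D** — twice the distance to the nearest lumen centerline point
  [mm];
* **WSS** — `μ · |∂v/∂n|` at the wall [Pa], with the velocity gradient
  from smoothing splines fitted through the in-plane velocity at three
  equidistant points along the inward normal spanning one local radius.

The wall model is the interaction regression

```
WT_i = β0 + β1·WSS_i + β2·D_i + β3·WSS_i·D_i + ε_i          (per subject i)
```

fitted by OLS per subject, and — after resampling subjects with
replacement and averaging maps on the shared geometry — per bootstrap
replicate *b* on the cohort-averaged maps. The B = 1000 replicate
coefficients give ensemble means and percentile 95% CIs; the ensemble
mean coefficients applied to a subject's own WSS and D maps predict
that subject's 3D WT map. Correlations use Spearman's ρ (mid-rank
ties); per-subject ρ values are tested by Student's t after the Fisher
z-transform, and cohort-level ρ is significant when the bootstrap
percentile 95% CI excludes 0. Agreement between predicted and measured
WT maps is summarised by ρ, Bland–Altman mean difference and limits of
agreement (1.96 × SD of paired differences), and the "maximum WT"
(mean of the top 5% of vertex values).

## Worked example

```bash
python examples/cohort_statistics.py
```

prints, for a 20-subject synthetic cohort at default conditions:

```
individual rho(WT,WSS) = -0.37 +/- 0.18 (p = 2.1e-07)
individual rho(WT,D) = +0.39 +/- 0.18 (p = 6.1e-08)
individual rho(WSS,D) = -0.50 +/- 0.37 (p = 5e-05)
bootstrap rho(WT,WSS) = -0.69 [-0.83, -0.47] (significant)
bootstrap rho(WT,D) = +0.77 [+0.66, +0.83] (significant)
bootstrap rho(WSS,D) = -0.72 [-0.87, -0.38] (significant)
```

The per-subject WT–WSS correlation (−0.37 on average) is diluted by
vertex noise; after bootstrap cohort averaging the same negative
coupling is much stronger (−0.69) and its 95% CI excludes 0. The other
examples demonstrate cohort generation (`simulate_cohort.py`),
per-subject map estimation against ground truth (`estimate_maps.py`),
and WT-map prediction from cohort coefficients
(`predict_wall_thickness.py`), which recovers the generating
coefficients (e.g. b1 = −0.142 mm/Pa for a truth of −0.15) and reports
per-subject prediction agreement.

A thin CLI wraps the same pipeline:

```bash
wallmap run-all --out run/ --seed 1 --bootstrap 1000
```

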