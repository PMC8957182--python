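# septostrain

Strain-based discoordination imaging of the inter-ventricular septum,
built for exercise echocardiography studies.

In dyssynchronous heart failure (typically left bundle branch block),
the septum shortens early and is then stretched by the late-activated
free wall while the valves are still closed. That *systolic rebound
stretch* is wasted work and predicts response to cardiac
resynchronization therapy — but it is almost always measured at rest,
while symptoms appear during exertion. Measuring it during exercise is
hard: image quality degrades, only single cycles are usable, and aortic
valve closure cannot be timed by Doppler mid-exercise.

This package implements the full measurement chain and the statistics
needed to ask "how reproducible is this during exercise?":

- **Discoordination indices.** Septal longitudinal strain ε(t) over the
  systolic window [MVC, AVC] is decomposed into shortening and stretch
  segments; systolic shortening SS = Σ|Δε⁻|, septal rebound stretch
  SRSsept = Σ Δε⁺ after shortening onset, and the septal discoordination
  index SDI = SRSsept / SS — the ratio of wasted to effective
  deformation, robust to the strain-amplitude loss at higher afterload.
- **Speckle tracking.** An 11 × 31 mesh over the segmented septum,
  tracked by normalized-cross-correlation block matching with sub-pixel
  refinement; cumulative longitudinal strain by a least-squares
  spatial-derivative estimator; image-quality grading and an exclusion
  rule for incomplete septal views.
- **Valve timing under exercise.** Smoothing-spline fits of systolic /
  diastolic duration versus heart rate rescale the resting systolic
  window to any exercise heart rate.
- **Agreement statistics.** Bland–Altman, ICC(A,1) with F-based CI,
  Cohen's kappa, paired t-tests, normalized curve correlation, and
  feasibility tallies for test–retest / intra- / inter-observer designs.
- **Synthetic data.** A scatterer-based speckle simulator driven by
  analytically known septal deformation, plus a two-visit cohort
  generator with controlled physiological and observer variability — so
  the whole chain is testable against ground truth without any data
  download.

See `docs/methods.md` for the models, estimators and their limitations.

## Worked example

```python
import numpy as np
import septostrain as st

# an LBBB-type cycle: 14% systolic shortening, 4% rebound stretch
pattern = st.StrainPattern(family="lbbb_type", target_ss=14.0, target_srs=4.0)
timing = st.resting_timing(70.0)                      # MVC at t=0, AVC from the phase model
truth = st.make_ground_truth(pattern, timing, frame_rate=90.0,
                             image_size=(800, 600), seed=1)

# render the speckle loop and track it back
cond = st.AcquisitionCondition("baseline", heart_rate=70.0, frame_rate=90.0,
                               noise_level=0.0, dropout_fraction=0.0)
loop = st.synthesize_cine_loop(truth, cond, image_size=(800, 600), seed=1)
field = st.estimate_displacements(loop, truth.mesh, block_size=21, search_radius=5)
curve = st.accumulate_strain(field, truth.mesh, timing=timing, frame_rate=90.0)

result = st.analyze_curve(curve)
rmse = np.sqrt(np.mean((curve.strain - truth.strain_curve.strain) ** 2))
print(f"SS  = {result.ss:.2f} %   (target 14.00)")
print(f"SRS = {result.srs_sept:.2f} %   (target 4.00)")
print(f"SDI = {result.sdi:.3f}     (target 0.286)")
print(f"strain-curve RMSE vs truth = {rmse:.2f} % strain")
```

prints

```
SS  = 13.76 %   (target 14.00)
SRS = 3.95 %   (target 4.00)
SDI = 0.287     (target 0.286)
strain-curve RMSE vs truth = 0.12 % strain
```

i.e. the tracker recovers the prescribed discoordination to a fraction
of a percent strain on a noise-free loop. A full synthetic study —
cohort, two visits, five exercise intensities, quality exclusion,
agreement statistics — runs from one config:

```bash
septostrain run --config cfg.yaml --out results/
# or, for single loops:
septostrain simulate --pattern lbbb --hr 60 --frame-rate 90 --noise 0.1 --seed 7 --out sim/
septostrain track --input sim/loop --segmentation sim/segmentation.json \
                  --timing sim/timing.json --out tracked/
```

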