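# kinemetrics

Quantitative analysis of infant spontaneous movements from 2D pose-keypoint
time series.

Spontaneous movements in the first months of life reflect the integrity of
the developing nervous system: reduced movement *complexity* and abnormally
synchronized (cramped) limb movements are early markers of
neurodevelopmental risk in preterm infants. Expert video assessment of these
movements requires certified raters; `kinemetrics` implements the
quantitative alternative: starting from per-frame joint keypoints produced
by any 2D pose estimator (AlphaPose/COCO-17 JSON or long-format CSV), it
computes interpretable kinematic indices per infant and relates them to a
neurological outcome score across a cohort. It is aimed at researchers in
developmental neurology and movement science who have pose-estimation
output and outcome scores, and want reproducible complexity/similarity
statistics rather than a black-box classifier.

## What it computes

For each of the 8 angle-bearing joints (bilateral shoulders, elbows, hips,
knees), the interior joint angle θ(t) ∈ [0°, 180°] is formed by the joint
and two adjacent joints (e.g. the right elbow angle uses the right shoulder
and right wrist). Angles are invariant to camera distance, framing and
mirroring. Keypoints with detection confidence < 0.5 are discarded; the
angle series is repaired and denoised with locally weighted linear
regression (tricube weights, single pass), and angular velocity
ω(t) = (θ(t+Δ) − θ(t−Δ)) / 2Δ in deg/s follows by the symmetric difference
quotient. Per infant the pipeline reports:

* **Descriptive statistics** — max, min, mean, sd of each angle and
  velocity series (64 values);
* **Complexity indices** — sample entropy
  SampEn(m, r) = −ln(A/B), where B and A count pairs of length-m and
  length-(m+1) template vectors within Chebyshev tolerance r
  (defaults m = 2, r = 0.2·sd; 16 values). Lower SampEn = more regular,
  less complex movement;
* **Similarity indices** — Pearson correlations between all 28 joint pairs
  for angles and for velocities (56 values), quantifying inter/intra-limb
  synchronization.

At the cohort level, infants are grouped by the Hammersmith Infant
Neurological Examination global score (HINE, 0–78; scores < 60 flag risk)
and each index is compared between groups (Student's t / Mann–Whitney U,
auto-selected by a Shapiro–Wilk gate) and correlated with the HINE score
(Pearson, two-sided t-based p). Categorical cohort characteristics use
chi-squared (uncorrected) or Fisher's exact test.

Because no public dataset of this kind exists, the package ships a
first-class synthetic cohort generator: quasi-periodic limb oscillations
with a tunable irregularity mixing weight λ (which monotonically drives
measured sample entropy), tunable inter-joint coupling κ (ipsilateral
hip–knee by default), confidence-scored dropout with temporally clustered
occlusions, and an outcome model linking irregularity to the HINE score.
Forward kinematics projects the scripted angles onto a 12-keypoint 2D
skeleton so that the full pipeline can be validated against known ground
truth.

## Worked example

```python
import warnings
from kinemetrics import SynthConfig, generate_cohort, RunConfig, run_extract, run_cohort

cfg = SynthConfig(n_infants=8, duration_s=120.0, frame_rate=30.0, seed=42)
rc = RunConfig(min_duration_s=60.0)
cohort = generate_cohort(cfg, out_dir="demo")       # writes keypoint CSVs + outcomes.csv
features = run_extract(cohort.series, rc)           # 8 rows x 136 feature columns
bundle = run_cohort(features, cohort.outcomes, rc)  # tables + JSON summary

print(features[["se_angle_right_knee", "se_vel_right_knee",
                "rho_angle_right_hip__right_knee"]].round(3).head(4))
```

```
            se_angle_right_knee  se_vel_right_knee  rho_angle_right_hip__right_knee
infant_id
infant_000                0.045              0.194                            0.871
infant_001                0.040              0.176                            0.913
infant_002                0.035              0.159                            0.881
infant_003                0.040              0.202                            0.900
```

Right-knee angle complexity sits at a few hundredths (velocity complexity a
few tenths), and the requested ipsilateral hip–knee coupling of 0.9 is
recovered at ρ ≈ 0.87–0.91. The cohort layer then yields, for example:

```
print(bundle["group_comparison"][["index", "mean_low", "mean_high", "p", "method"]].head(3).round(4))
                     index  mean_low  mean_high       p method
0  se_angle_right_shoulder    0.0333     0.0465  0.0910      t
1   se_angle_left_shoulder    0.0309     0.0513  0.0122      t
2     se_angle_right_elbow    0.0338     0.0480  0.0658      t
```

i.e. infants in the low-HINE group show lower movement complexity — the
designed property of the generator, recovered end to end from noisy
keypoints. With only 8 infants some comparisons are not significant;
`scripts/acceptance.py` runs the full 65-infant design.

The same pipeline is available from the shell:

```bash
kinemetrics simulate --seed 7 --n 8 --out demo/
kinemetrics extract --in demo/ --format csv --fps 30 --out features.csv
kinemetrics cohort --features features.csv --outcomes demo/outcomes.csv --out report/
kinemetrics report --in report/
```

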