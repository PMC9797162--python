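# detrack — dual-energy markerless tumor tracking, end to end

`detrack` is a simulation and evaluation toolkit for markerless lung-tumor
tracking (MTT) on dual-energy (DE) kV projections, aimed at medical-physics
researchers studying how DE noise-reduction techniques and template-matching
parameters interact.  Clinical fast-kV-switching acquisitions are rarely
shareable, so the package pairs the full analysis chain with a synthetic
thorax phantom whose tumor motion is exactly known, making every stage of the
pipeline quantitatively testable.

## What it computes

Given paired high/low-kVp projections `I_H`, `I_L`, the soft-tissue and bone
DE images are formed by weighted logarithmic subtraction:

    I_DEST = ln I_H − w_ST · ln I_L        (bone suppressed,   w_ST = 0.42)
    I_DEB  = −ln I_H + w_B  · ln I_L       (tissue suppressed, w_B  = 0.70)

Four noise-reduction variants operate on these images:

* **SS** — 3×3 median filter on `I_H` before subtraction;
* **ACNR** — anticorrelated noise reduction,
  `I_DEST + w_n · (I_DEB − box₂₀ₓ₂₀(I_DEB))` with `w_n = 0.35`: Poisson noise
  from `ln I_H` enters the two DE images with opposite signs, so adding the
  high-pass of the complementary image cancels part of it;
* **NC** — noise clipping: with 17×17 median backgrounds, any pixel whose
  high-energy contrast exceeds its low-energy contrast is clipped to the
  latter (true structures attenuate more at low energy);
* **NC-ACNR** — clipping followed by ACNR.

The tumor is tracked per frame by scanning a per-degree template (projected
from the phantom at the motion reference state) over a search window, after
band-pass filtering both with a difference of Gaussians
(`G(σ_low) − G(σ_high)`, σ in mm); the placement maximizing the
zero-normalized cross-correlation (NCC) is the tracked position, and a peak
below the NCC threshold flags the frame as missing.  Ground truth is either
the simulator's exact trajectory or a constant-acceleration Kalman filter
estimate (state `[p, v, a]` per axis, prediction `x̂ = F x + G u`,
`P̂ = F P Fᵀ + Q`; correction through the Kalman gain
`K = P̂ Hᵀ (H P̂ Hᵀ + R)⁻¹`), as used for clinical data where truth is
unobservable.  Tracking is scored by

* **TSR** — % of tracked frames with 2D error < 2 mm,
* **RMSE** — root-mean-square 2D error over tracked frames (mm),
* **missing** — % of frames without a confident match,

and technique pairs are compared with the two-sided Wilcoxon matched-pair
signed-rank test over the band-pass grid
(σ_low ∈ {0.2, 0.4, 0.6, 0.8} mm × σ_high/σ_low ∈ {2, 3, 4, 5}).

## Worked example

```python
import detrack
from detrack.phantom import AcquisitionSpec
from detrack.tracking import BandPassParams, SearchConfig, track_sequence
from detrack.kalman import KFConfig, estimate_ground_truth
from detrack.metrics import evaluate_tracking

phantom = detrack.default_phantom()            # thorax + ribs + 10 mm tumor
motion = detrack.default_motion()              # 10 mm SI cosine, 4 s period
acq = AcquisitionSpec(n_pairs=60, seed=1)      # 60 pairs over the 180° arc

pairs, gt = detrack.simulate_sequence(phantom, motion, acq)
bank = detrack.generate_templates(phantom, range(0, 181), acq)
frames = [detrack.apply_technique("ACNR", p.high, p.low,
                                  angle_deg=p.angle_deg, time_s=p.time_s)
          for p in pairs]
track = track_sequence(frames, bank,
                       SearchConfig(search_half_width=25.0, ncc_threshold=0.5),
                       BandPassParams(sigma_low=0.8, sigma_high=4.0))
gt_kf = estimate_ground_truth(track, KFConfig(dt=acq.dt))
report = evaluate_tracking(track, gt)
```

This prints:

```
tracked 58/60 frames (missing 3.3%)
TSR  = 86.2%   (2D error < 2 mm vs simulator ground truth)
RMSE = 1.14 mm
RMSE vs Kalman-estimated ground truth = 0.56 mm
```

58 of 60 frames produced an NCC peak above 0.5; of those, 86.2% landed
within 2 mm of the true tumor center, with a 1.14 mm RMS error.  Scored
against the Kalman-filter estimate instead of the exact truth — the only
option on clinical data — the apparent RMSE halves, illustrating why the
estimated ground truth flatters absolute numbers while remaining useful for
comparing techniques.

The same pipeline is scriptable from the shell:

```bash
detrack sweep --out results/ --seed 1          # full technique × σ grid
detrack summarize results/results.csv --out results/
detrack compare results/results.csv -a ACNR -b unprocessed
```

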