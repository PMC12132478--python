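# papaquant

Quantification pipeline for **proximity-assisted photoactivation single-molecule
tracking (PAPA-SMT)**, with companion analyses for diffusion spectra and
fluorescence recovery after photobleaching (FRAP).

PAPA is a live-cell single-molecule assay for protein–protein proximity. Two
proteins carry self-labeling tags with a "sender" dye (green-excited) and a
"receiver" dye (far-red). Red light shelves the receiver into a dark state;
a green pulse reactivates receivers that sit within ~20 nm of a sender
(PAPA), while a violet pulse reactivates receivers indiscriminately (direct
reactivation, DR). Counting reactivated molecules in the two pulse channels,
after correcting for spontaneous dark-state recovery, measures how often the
two proteins are in molecular proximity — sensitively enough to capture the
weak, transient interactions of intrinsically disordered regions that escape
most biochemical methods.

This package implements the full quantification chain for such experiments
and a synthetic-data generator that emulates the raw imaging outputs with
known ground truth, so every stage is testable without microscope data.

## The quantities computed

Imaging cycles consist of four 50-frame windows at 10 ms/frame (three cycles
by default):

```
baseline | violet pulse (DR) | baseline | green pulse (PAPA)
```

* **Background correction.** Spontaneous reactivation of the dark-state dye
  decays exponentially; each pooled baseline count series is fit to
  c(t) = A·exp(−k·t) and extrapolated into the adjacent pulse window. The
  projected background is subtracted from the pulse-window counts and
  negative results are truncated to zero.
* **GV ratio.** Corrected green (PAPA) detections divided by corrected
  violet (DR) detections, pooled over retained cells and cycles.
* **Proximity index.** A condition's GV ratio normalized to that of a
  non-interacting control: PI = GV_exp / GV_ctrl. PI = 1 means no proximity
  enrichment. Uncertainty comes from bootstrap resampling of individual
  cells (100 replicates; 2.5th/97.5th percentiles).
* **Cell QC.** Nuclei are excluded if their area is below 5,000 px, their
  leakage score (mean far-red intensity in a 4-px ring around the nucleus
  over the nuclear mean) exceeds 0.7, their detection count is atypical, or
  they touch the top/bottom image edge.
* **Diffusion spectrum.** Jump magnitudes r between consecutive frames
  follow a Rayleigh law with per-coordinate variance 2·D·Δt + 2·σ_loc².
  Occupations over a log-spaced grid of diffusion coefficients are estimated
  by jump-count-weighted EM; the occupation below 0.1 μm²/s is the **slow
  fraction**, a proxy for chromatin-bound molecules.
* **FRAP.** Drift-corrected (integer-pixel cross-correlation), background-
  subtracted spot/nucleus double ratio, normalized to the mean over
  pre-bleach frames 1–15.

## Worked example

```python
import papaquant as pq

schedule = pq.IlluminationSchedule()          # 4 x 50 frames, 3 cycles, 10 ms
photo    = pq.PhotophysicsParams()            # shelving/reactivation rates
motion   = pq.MotionParams()                  # bound/free 2-D diffusion
layout   = pq.grid_layout()                   # 20 nuclei on a 512x512 field

cells = {}
for name, interacting, seed in [("exp", True, 0), ("ctrl", False, 1)]:
    det, traj, images, mask, gt = pq.simulate_papa_experiment(
        schedule, photo, motion, layout, interacting, seed=seed)
    assigned, _ = pq.assign_detections(det, mask)
    cells[name] = list(pq.window_counts(assigned, schedule).values())

res = pq.quantify_condition(cells["exp"], cells["ctrl"], schedule, seed=0)
print(f"proximity index = {res.proximity_index:.2f} "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}], n = {res.n_cells} cells")
```

prints (seed 0):

```
proximity index = 2.86 [2.51, 3.24], n = 20 cells
```

i.e. the interacting condition shows a ~2.9-fold proximity enrichment over
the non-interacting control — consistent with the generator's analytic
ground-truth enrichment for the default photophysics
(`gt.true_gv_enrichment` ≈ 2.87) — with a 95% cell-bootstrap interval from
100 replicates.

The same objects drive the mobility and FRAP analyses
(`pq.split_by_reactivation`, `pq.fit_spectrum`, `pq.frap_trace`), and the
whole chain can be run from the shell:

```bash
papa run-all --seed 0 --out papa_run     # simulate -> ... -> report
```

which writes `proximity_results.csv`, `scatter_points.csv`,
`slow_fractions.csv`, `frap_mean.csv`, figures under `report/`, and a
`manifest.json` hashing every output.

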