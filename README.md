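# condenskit

Quantitative analysis of biomolecular condensates in live-cell fluorescence
microscopy. The package covers the four measurement families used to
characterize liquid–liquid phase separation (LLPS) of nuclear proteins such
as TDP-43:

- **FRAP kinetics** (`condenskit.frap`) — background correction, simple and
  double (easyFRAP-style) normalization, quality-control gating (bleach
  efficacy > 60%, gap ratio > 60%, R² > 0.7), and one-/two-component
  exponential recovery fits yielding the half-time of recovery
  *t*½ and the mobile fraction (plateau − f₀)/(1 − f₀).
- **Single-molecule tracking** (`condenskit.smt`) — trajectory filtering
  (≥ 7 localizations), per-track diffusion coefficients from the first four
  positions (MSD = 4·D·Δt + offset), mobile/immobile classification at
  log₁₀D = −0.5, 2-/3-state jump-length mixture models
  p(r|Δt) = Σₛ fₛ·r/(2(DₛΔt+σ²))·exp(−r²/(4(DₛΔt+σ²))), and censoring-aware
  dwell-time (residence-time) survival analysis
  S(t) = f·e^(−t/τ_long) + (1−f)·e^(−t/τ_short).
- **3D morphometry** (`condenskit.morphology`) — nucleus segmentation
  (Otsu on the nuclear-marker channel), difference-of-Gaussians condensate
  detection, per-object volume, equatorial area, marching-cubes surface area
  and sphericity ψ = π^⅓(6V)^⅔/A, nucleo-cytoplasmic signal partitioning,
  line plot-profiles, diffuse/total nuclear intensity ratio, and radial
  profiles with anisosome (shell) classification.
- **Condensate dynamics** (`condenskit.dynamics`) — greedy nearest-neighbour
  linking of detections over time, track speeds (nm/s), and fusion/fission
  event detection with mass-balance gating.

Because live-imaging recordings of this kind are rarely deposited, the
package ships a first-class synthetic-data generator
(`condenskit.simulate`): seeded, ground-truth-carrying simulators for FRAP
traces, multi-state Brownian trajectories, dwell-time mixtures, and 3D/4D
two-channel image stacks with scripted fusion/fission events. Every analysis
stage is validated by parameter recovery against that truth
(see `docs/methods.md`).

## Worked example

Simulate a FRAP experiment with known kinetics and recover them:

```python
from condenskit import frap, simulate as sim

params = sim.frap_params_for_t_half(t_half=50.0, mobile_fraction=0.83, seed=1)
trace, truth = sim.simulate_frap(params)

norm = frap.normalize_double(trace)
qc = frap.compute_qc(trace, norm)
fit = frap.fit_recovery(norm, model="two_component")
print(f"t_half = {fit.t_half:.1f} s   (truth {truth.truth['t_half']:.1f} s)")
print(f"mobile fraction = {fit.mobile_fraction:.2f}")
print(f"bleach efficacy = {qc.bleach_efficacy:.2f}, gap ratio = {qc.gap_ratio:.2f}")
```

prints

```
t_half = 49.6 s   (truth 50.0 s)
mobile fraction = 0.83
bleach efficacy = 0.75, gap ratio = 0.98
```

The fitted half-time and mobile fraction recover the generating values
(50 s, 0.83) within a few percent at 2% intensity noise; both QC gates pass
(efficacy above 0.60, gap ratio above 0.60), so the trace would enter a
per-condition summary.

The same round trip exists for each modality from the shell:

```bash
condenskit sim frap  --out data/frap --n-traces 12 --seed 7
condenskit frap      --traces data/frap --norm double --model two_component --out out/frap

condenskit sim smt   --out data/smt --seed 7
condenskit smt       --tracks data/smt/tracks.csv --dt 0.02 --out out/smt

condenskit sim stack --out data/stack --seed 7
condenskit morph     --stack data/stack/stack.tiff --out out/morph
```

or as one reproducible run from a JSON config
(`condenskit run --config run.json`), which writes result tables plus a
provenance log (config hash, seed, versions, QC exclusions). Reruns with the
same config and seed are byte-identical.

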