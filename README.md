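# thzdyn

Analysis toolkit for **THz-timescale (picosecond) protein–solvent
dynamics** in molecular-dynamics trajectories of hydrated globular
proteins — the fast collective fluctuations (≤ 250 cm⁻¹) that couple a
protein to its hydration shell around the protein glass transition.

It is aimed at structural-bioinformatics and biophysics users who have
MD trajectories (multi-model PDB or GRO series) and want the standard
battery of fast-dynamics observables without an MD engine in the loop:

* **Vibrational spectra from the velocity autocorrelation function.**
  The VACF, C_v(τ) = ⟨v_i(t+τ)·v_i(t)⟩/⟨v_i²⟩ averaged over atoms and
  time origins, is Fourier-transformed (Hann window, 4× zero padding)
  onto a wavenumber axis; peaks locate the underlying mode frequencies.
  Rotational ACFs (P₁/P₂) of inter-atom vectors are included.
* **Hydrogen-bond kinetics.** Bonds are detected by the standard
  geometric criterion — d(D,A) < 3.5 Å, d(H,A) < 2.6 Å, donor angle
  < 30° — classed as protein–protein / protein–water / water–water, and
  restricted to hydration shells (e.g. waters within 3.8 Å of the
  protein surface). The intermittent H-bond ACF
  C_hb(τ) = ⟨hb_i(t+τ)·hb_i(t)⟩/⟨hb_i²⟩ yields lifetimes via a
  plateau + (1−plateau)·e^(−τ/τ₀) fit.
* **Correlated residue motion.** Cross-correlation coefficients
  C_ij = ⟨Δr_i·Δr_j⟩/(⟨Δr_i²⟩⟨Δr_j²⟩)^(1/2) of Cα displacements (after
  rigid-body superposition), thresholded into residue networks
  (|C_ij| ≥ 0.35 or 0.25), and essential-dynamics PCA with per-residue
  square fluctuations of PC1.
* **Experimental-side helpers.** Percent-transmittance to absorbance
  conversion, A = −log₁₀(%T/100), and harmonic/anharmonic classification
  of peak-position temperature trends (red-shift ⇒ anharmonic).
* **Synthetic generators with known ground truth** — harmonic mode
  trajectories, Ornstein–Uhlenbeck baths, two-state Markov H-bond
  timelines, planted-correlation displacement fields and exact toy
  H-bond geometries — so every stage is validated against closed forms.

See `docs/methods.md` for conventions, estimator choices and limits.

## Worked example

Generate a trajectory with planted modes at 40 and 90 cm⁻¹, recover
them, and fit a hydrogen-bond lifetime from a two-state timeline with
true τ = 1/(k_on+k_off) = 2.9 ps:

```python
import numpy as np
from thzdyn import (HarmonicSpec, MarkovHBondSpec, make_harmonic_trajectory,
                    make_markov_hbond_timeline, vacf, spectrum_from_acf,
                    find_peaks, hbacf, fit_hbond_lifetime)

traj = make_harmonic_trajectory(HarmonicSpec(
    modes=((40.0, 0.3, 0.0), (90.0, 0.2, 1.0)), dt=0.01, n_frames=4096, seed=17))
spec = spectrum_from_acf(vacf(traj, np.arange(8), max_lag=10.0))
peaks = find_peaks(spec, min_prominence=0.05, band=(10, 200))
print([float(round(p.position, 2)) for p in peaks.peaks], "bin:", round(spec.bin_width, 3))

tl = make_markov_hbond_timeline(MarkovHBondSpec(
    k_on=1/5.8, k_off=1/5.8, dt=0.01, n_frames=100_000, n_bonds=100, seed=3))
fit = fit_hbond_lifetime(hbacf(tl, max_lag=12.0), fit_window=(0.5, 8.0))
print(round(fit.tau, 3), "ps, plateau", round(fit.plateau, 3))
```

prints

```
[39.94, 90.07] bin: 0.833
2.961 ps, plateau 0.497
```

— both planted wavenumbers are recovered within one spectral bin
(0.83 cm⁻¹), and the fitted lifetime sits within ~2% of the true 2.9 ps
with the plateau at the stationary occupancy 0.5, as the two-state
closed form C(τ) = p + (1−p)e^(−(k_on+k_off)τ) predicts.

The same workflows run from the shell:

```sh
thzdyn synth traj.pdb --mode 40 0.3 --mode 90 0.2 --frames 4096
thzdyn vacf traj.pdb acf.tsv --dt 0.01 --selection calpha --max-lag 10
thzdyn spectrum acf.tsv spec.tsv && thzdyn peaks spec.tsv --band 10:200
thzdyn run config.yaml          # full workflow from a YAML config
```

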