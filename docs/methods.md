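# Methods

`thzdyn` analyses picosecond (THz-timescale) protein and hydration-water
dynamics in MD trajectories of a hydrated globular protein. This note
documents the models, conventions and numerical choices behind each
stage, what the synthetic generators emulate, and where the open design
decisions were resolved.

Units are fixed package-wide: lengths in Å, times in ps, frequency axes
in wavenumber (cm⁻¹). Readers convert on ingestion (GRO nm × 10); the
wavenumber conversion uses the exact constant c = 2.99792458×10⁻² cm/ps,
so 1 ps⁻¹ = 33.356 cm⁻¹.

## Trajectories and selections

A `Trajectory` is a frames × atoms × 3 coordinate array with a strictly
positive, constant frame spacing `dt`, optional velocities (Å/ps) and an
optional orthorhombic box. Multi-model PDB and frame-concatenated GRO
files are parsed through mdtraj; a light pre-scan of PDB MODEL blocks
reports atom-count mismatches with the offending frame index. Because a
wrong time step corrupts every downstream frequency axis, `dt` must be
given explicitly for formats that do not encode time — PDB never does,
GRO only via `t=` header stamps; fabricated frame indices are never
accepted as times.

Hydration-shell membership is decided per water **molecule** through its
oxygen: a water belongs to the shell when its oxygen lies within the
cutoff of any protein atom (minimum-image when a box is present). An
any-atom probe mode exists as a flag. The 3.8 Å cutoff corresponds to a
first hydration layer, 8.0 Å to two layers. Shell selections are
monotone in the cutoff by construction.

When stored velocities are absent they are derived by central
differences, v(t) = (x(t+dt) − x(t−dt))/(2dt) (exact for quadratic
motion, O(dt²) otherwise), with one-sided differences at the ends; the
result is flagged `velocities_derived`. Both paths — stored and derived
velocities — are supported because archived trajectories frequently
drop velocities.

## Autocorrelation functions and spectra

The generic engine computes C(τ) = ⟨s(t+τ)·s(t)⟩/⟨s(0)²⟩ per channel via
FFT, then averages channels. Two estimators are exposed:

* **biased** (divide by n; the default for spectra): the estimated ACF
  is positive semidefinite, which guarantees a non-negative power
  spectrum, at the cost of a deterministic (n−τ)/n taper;
* **unbiased** (divide by n−τ; the plain mean over time origins): used
  where the long-lag level carries meaning, in particular for H-bond
  ACFs whose plateau feeds the lifetime fit.

The VACF correlates the 3 Cartesian components per atom, sums them (a
dot-product correlation), normalises by that atom's mean squared speed
and averages atoms. Zero-variance (static) atoms are excluded with a
warning rather than poisoning the average with NaNs. Generic series are
mean-removed before correlation (drift protection); velocities are not,
since their mean is already ~0 and detrending would distort the
definition.

The rotational ACF of an inter-atom unit vector is ⟨û(t+τ)·û(0)⟩ at
order 1 or the Legendre P₂ of the dot product at order 2. The field
reads either order depending on the experiment being mimicked; order 1
is the default and the order is a flag.

Spectra are obtained by tapering the one-sided ACF with the decaying
half of a Hann window (1 at lag 0, 0 at the last lag), zero-padding 4×
and applying a real FFT. The default `kind` is the power spectrum
(squared magnitude); amplitude spectra and a no-window/no-pad mode are
selectable, and every choice is recorded in the spectrum metadata. With
no window and no padding the transform satisfies a Parseval identity
against the sum of squared ACF values to 1e-8 relative, which the tests
verify. Peak positions are refined by 3-point parabolic interpolation,
so well-resolved lines are located to a fraction of a bin; the peak
tests all use "within one bin width" as the acceptance radius.

A peak's temperature trend is classified from the least-squares slope of
position vs temperature: *anharmonic-like* when the fitted total shift
across the measured range is a red-shift larger than the tolerance
(default 2 cm⁻¹, matching a typical 4 cm⁻¹ spectral resolution),
*harmonic-like* otherwise. The classification is invariant to the input
ordering.

Absorbance follows A = −log₁₀(%T/100) with %T = 100·I/I₀. %T ≤ 0 is an
error; %T > 100 (possible with experimental noise) is kept, producing a
small negative A with a warning — clamping would hide the noise.

## Hydrogen-bond detection and kinetics

A bond D–H···A is accepted when **all three** strict inequalities hold:
d(D,A) < 3.5 Å, d(H,A) < 2.6 Å, and the angle at the donor between D→H
and D→A < 30°. Two conventions required interpretation:

* the heavy-atom distance is taken between donor and acceptor heavy
  atoms (a molecular centre-of-mass mode for water–water pairs is a
  flag; a molecular COM is ill-defined for protein partners);
* the angular test defaults to the acceptance-cone convention at the
  donor, which matches the 30° magnitude; the angle-at-hydrogen
  alternative is a flag.

Donors are N/O atoms with a hydrogen within 1.2 Å in the first frame
(covalent topology is assumed static); acceptors are all N/O atoms.
Bonds are classed protein–protein / protein–water / water–water by the
partners' residue categories, and the three classes partition the
unfiltered detections — a property the tests assert. The interfacial
water–water timeline restricts both partner oxygens to the hydration
shell, re-evaluated every frame.

The H-bond ACF uses the **intermittent** definition: raw 0/1 occupancies
correlated with no history erasure, so a bond that breaks and re-forms
keeps contributing. Each bond's curve is normalised by its own mean
occupancy and curves are averaged over bonds (per-bond default; a pooled
variant sums numerators and denominators first). A continuous-lifetime
reading would decay faster; the intermittent form is the literal reading
of a 0/1 correlation and is the default throughout.

Lifetimes come from least-squares fitting C(τ) = p + (1−p)·e^(−τ/τ₀)
over a window of 0.5–8 ps by default. The free plateau p absorbs the
long-lag asymptote of equilibrium two-state kinetics (C(∞) = stationary
occupancy); a plateau-free variant is selectable. The lower window edge
skips the earliest lags where non-exponential transients live; the fit
reports its RMS residual.

## Synthetic generators (what they emulate, and what not)

* **Harmonic trajectories**: sums of cosine modes at prescribed
  wavenumbers, each atom along its own random direction with random
  per-mode phases, plus optional white positional noise. Velocities are
  stored analytically, so VACF → spectrum → peaks must return each
  planted wavenumber within one bin — the package's primary end-to-end
  oracle. Mode wavenumbers are validated against the Nyquist limit
  1/(2·dt·c).
* **Langevin (Ornstein–Uhlenbeck) baths**: exactly discretised OU
  velocities with stationary variance σ²/(2θ) and VACF e^(−θτ),
  emulating broadband solvent-coupled relaxation.
* **Two-state Markov H-bond timelines**: independent chains with
  per-step switch probabilities 1−e^(−k·dt), started from stationarity.
  The normalised intermittent ACF is exactly
  p + (1−p)·e^(−(k_on+k_off)τ), giving a closed-form oracle for the
  lifetime fit with τ_true = 1/(k_on+k_off). Sojourn times are sampled
  as alternating geometric runs — distributionally identical to
  stepping frame by frame, and fast. The generator enforces
  dt·(k_on+k_off) < 0.5 for discretisation validity.
* **Correlated displacement fields**: white noise coloured by the
  symmetric eigen-square-root of a planted PSD correlation matrix, the
  same factor for x/y/z, making the cross-correlation coefficient's
  numerator and denominator analytically predictable (and exact for
  planted ±1).
* **Toy H-bond frames**: donor/hydrogen/acceptor groups placed at exact
  (d_DA, angle, d_HA) combinations in well-separated clusters, with the
  truth set computed from the placement numbers, never from the
  detector. A 27-point grid straddles each criterion boundary.

None of these generators are physically realistic water or protein
models: they carry no excluded volume, no force field, no temperature
dependence and no cross-talk between stages. Passing tests therefore
demonstrate the correctness of the estimators and detectors, not the
reproduction of any measured protein spectrum; real-trajectory behaviour
enters only through the file readers and the study-condition defaults
(100 bonds × 10⁵ frames at dt = 0.01 ps for kinetics, 4096 frames at
dt = 0.01 ps for spectra — sizes chosen so sampling error sits well
below the tested tolerances).

## Collective motion

Global rotation/translation is removed before cross-correlation and PCA
by default (flag preserved): each frame is rigid-body least-squares
fitted (Kabsch, via scipy's rotation alignment) onto the mean structure,
iterated once (fit to frame 0 → mean → refit). Without this step rigid
tumbling dominates every C_ij.

C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^(1/2) uses full 3-vector dot
products on Cα displacements. Zero-variance residues get zeroed
rows/columns (diagonal 1) with a warning instead of NaNs, keeping the
matrix usable downstream. Networks threshold |C_ij| (sign kept as an
edge attribute) with node amplitudes ⟨|Δr_i|²⟩; the default threshold is
0.35 with 0.25 equally supported — both appear in the field and the
package privileges neither. Edge sets are nested across thresholds by
construction.

PCA diagonalises the 3N×3N covariance (ddof = 1) of superposed Cα
coordinates, unweighted (mass weighting is a non-default option since
Cα masses are equal anyway). Per-residue square fluctuations of mode k
are the eigenvalue times the squared mode components summed per residue;
summed over all modes they reproduce the per-residue variance exactly,
and each projection's variance equals its eigenvalue — both identities
are tested at 1e-6 relative.

## Pipelines

Three runners (protein modes, hydration kinetics, collective motion)
compose the stages, accept dict/YAML configs with units in the key names
(`shell_cutoff_angstrom`, `dt_ps`), and write TSV/GraphML outputs plus a
JSON report echoing the full config, seed and package version — a report
is exactly reproducible from its own metadata, and reruns are
byte-identical. Stage outputs on disk plus the config echo are
sufficient to resume downstream analyses; no content-addressed cache
layer is maintained beyond that. Errors are annotated with the stage
name. The `thzdyn` CLI wraps the same functions for shell use.

## Known limitations

* Geometric H-bond criteria only; no energetic definitions.
* The detector's donor topology is taken from frame 0; reactive
  trajectories (proton transfer) are out of scope.
* Boxes are orthorhombic; triclinic minimum-image is not implemented.
* Dipole autocorrelation / IR intensities are deliberately not computed;
  the VACF spectrum approximates a density of states, not an absorption
  coefficient, so simulated and measured intensities are not directly
  comparable.
* The exponential lifetime fit assumes single-exponential decay above
  the window floor; stretched or multi-exponential kinetics will show up
  in the reported fit residual rather than being modelled.
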