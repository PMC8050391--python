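# Methods

This note documents the models implemented in `fenoscore`, the defaults
and why they were chosen, the numerical choices, what the synthetic-data
generators emulate, and the known limitations.

## Structure geometry

Coordinates are read through gemmi (PDB, mmCIF) or a small XYZ reader.
Alternate locations resolve to the highest-occupancy conformer, ties to
the first encountered; hydrogens are kept when present and never
synthesized; residue numbering is taken verbatim from the file.

The metal-site report collects all non-hydrogen atoms within a cutoff
(default 3.0 Å — covers every first-shell bond of a six-coordinate
nonheme iron site, all ≤ 2.6 Å, with margin) of the unique metal atom of
the requested chain. Histidines coordinate through Nε2, the ring
nitrogen left available by δ-protonation, which is the protonation state
appropriate for 3-His ferrous sites. Carboxylate oxygens are recognised
by bonding topology (an O whose carbon carries a second oxygen within
1.6 Å); the substrate/inhibitor hydroxyl or thiol donor is the remaining
O/S ligand. Missing ligands are absent from the report, never reported
as zero. Chain-pair RMSD pairs atoms 1:1 by (residue number, atom name)
and uses the closed-form Kabsch superposition (SVD with a determinant
correction); at least three paired atoms are required.

## Hyperfine model

Each selected proton gets a purely dipolar, axial, traceless coupling
tensor (−T, −T, 2T) with T from the point-dipole formula evaluated at
its distances to the Fe and to the N and O of the nitrosyl, combined
with the {FeNO}⁷ spin-projection coefficients +7/5 (Fe) and −1/5 (each
NO atom). Constants are frozen CODATA 2018; the prefactor is the vacuum
permeability over 4π (the only dimensionally consistent reading of the
formula); distances enter in metres and outputs are MHz. Distances below
0.5 Å are rejected as unphysical. An optional ±r jitter (default use
case 0.1 Å, the typical coordinate precision of a ~2.2 Å crystal
structure) brackets each coupling by re-evaluating at r ± jitter, which
is exact because T is monotone in r.

The molecular ("magnetic") frame has its origin at Fe and z along
Fe→N(NO), the direction of the zero-field-splitting principal axis in
these centres. The x axis is fixed by placing the NO oxygen in the
positive-x half of the x–z plane. This convention is arbitrary — only
geometry relative to the frame matters, and the simulated spectra are
insensitive to the azimuthal reference — but it is applied consistently
and round-trips exactly through the toy-site generator. A proton's
orientation is (θ, φ): θ the angle of Fe→H to z, φ the elevation out of
the x–z plane (arcsin of the y component). The equivalent z-y′-z″ Euler
set is (azimuth, θ, 0); the third angle is irrelevant for an axial
tensor and is fixed to 0 rather than silently assumed.

## S = 3/2 spin model

The electron Hamiltonian is D[Sz² − S(S+1)/3] + E(Sx² − Sy²) + βB·g·S,
kept in cm⁻¹ internally with fields in mT and frequencies in GHz at the
interfaces. D defaults to 10 cm⁻¹ and E/D to 0.008, the CW-EPR values
for the nitrosyl complex this package models; intrinsic g defaults to
(2.0023, 2.0023, 2.01) — free-electron-like perpendicular values, the
standard choice for {FeNO}⁷, with the parallel value set so the
ground-doublet parallel feature lands at the observed effective 2.01.
All are overridable.

Effective g-values are computed numerically: for each principal
direction the intra-doublet resonance field at the working microwave
frequency is located by bisection and converted via g = hν/βB. The
numeric values agree with the first-order formulas
g_eff⊥ = 2g(1 ± (3/2)(E/D)), g_eff∥ = g to better than 0.5% for the
perpendicular pair; the parallel value carries a second-order field
correction of order (hν/2D)² relative scale (≈ 0.7% at X-band with
D = 10 cm⁻¹), so the test tolerance for it is 1%. Rhombicity inversion
offers both the first-order closed form and a numeric refinement that
solves the effective-g model for the E/D reproducing the observed
perpendicular splitting.

Orientation selection uses a deterministic golden-spiral grid (no seed,
bit-for-bit reproducible). Each direction is weighted by a Gaussian in
(B_res(n) − B₀) with a configurable linewidth (default 5 mT) and
normalised; an empty selection falls back to uniform with a warning.
Directions are trimmed to the smallest subset carrying 99.9% of the
weight before spectrum simulation.

## HYSCORE simulation

Within the ground doublet the electron is treated as an effective
spin-1/2. The nuclear precession vectors in the two manifolds are

    ω_{α/β} = −ν_L n ± a/2,   a_k = Σ_i (g_eff,i² / g_i) n_i A_ik / g_eff(n)

which combines (i) the mapping of true-spin onto effective-spin
operators (factor g_eff,i/g_i per axis) and (ii) the electron
quantization along the g_eff-weighted field direction. Nuclear
frequencies are the norms; the modulation depth is
k = |ω_α × ω_β|²/(ν_α ν_β)², the standard I = 1/2 ESEEM depth. This
effective-spin route is cross-validated against dense diagonalization of
the full S = 3/2 ⊗ I = 1/2 Hamiltonian (8×8, ZFS + electron and nuclear
Zeeman + S·A·I with the coupled-representation tensor): agreement is
≤ 0.5% for couplings of a few MHz and degrades to a few per cent only
for |T| ≳ 5 MHz, where second-order hyperfine corrections relative to
the intra-doublet splitting become visible.

Cross-peak prediction emits, per orientation and coupling, the mirror
pair (ν_α, ν_β)/(ν_β, ν_α) with amplitude weight × k, aggregated into
footprint grids by Gaussian-kernel accumulation (σ = 1 frequency bin).
Footprints are compared by location, not height — peak intensities
depend on measurement conditions in ways the model does not try to
capture.

The time-domain simulator propagates the electron ⊗ nucleus density
matrix through the ideal-pulse four-pulse sequence
π/2–τ–π/2–t₁–π–t₂–π/2–τ–echo along the detected coherence pathway
p: 0 → +1 → 0 → 0 → −1. Projecting onto this single pathway is exactly
what the experimental phase cycle plus the electron resonance-offset
distribution accomplish; retaining the +1/−1 anti-echo pathway would
cancel the stored nuclear coherence for a single I = 1/2 nucleus (the
sum of an SU(2) propagator and its adjoint is proportional to the
identity), which is why pathway selection is essential. The surface for
all (t₁, t₂) at once comes from an eigenbasis coefficient expansion
(a 16×16 coefficient matrix between two phase-factor matrices), making
the per-orientation cost trivial; the result was verified against the
closed-form Mims three-pulse modulation formula during development, and
the round-trip tests check it against the frequency-domain predictions.
Multi-nucleus surfaces use the product rule (per-nucleus normalised
surfaces multiplied within each orientation), then orientation
averaging, exponential decay in t₁ and t₂, and seeded complex Gaussian
noise. Every stochastic path requires an explicit seed; there is no
hidden global RNG.

## Processing chain

Fixed order, matching experimental practice for four-pulse data:

1. **Phase**: one global phase minimising the total imaginary energy;
   the minimiser is φ = arg(Σz²)/2 (closed form), choosing the branch
   that maximises real energy.
2. **Baseline**: least-squares polynomial (default degree 2) fit and
   subtracted along each row, then each column.
3. **Apodization**: separable ("diagonal") Blackman window over the
   acquired length, before any zero-filling. The common truncated
   Blackman (a₀ = 0.42, a₁ = 0.5, a₂ = 0.08) is the default; the
   "exact" coefficient set is selectable. The window length choice
   (acquired, not padded) is the only reading under which apodization
   suppresses truncation ripple.
4. **FFT**: zero-fill both dimensions (default 1024), 2-D FFT, display
   |Re(FT)|; ν₁ carries the signed axis so the (−, +) quadrant is
   visible, ν₂ the nonnegative half. Frequency bin = 1/(zero_fill·Δt) ≈
   0.0407 MHz at 24 ns sampling. A first-order phase ramp
   exp(−2πiν(t_start + τ/2)) is applied per axis: nuclear coherence in
   each dimension effectively starts evolving at −(t_start + τ/2)
   relative to the sampled grid origin, and without the ramp the |Re|
   peak shapes split into lobes and their maxima shift off position.
   Spectra are never symmetrised, so residual asymmetry can be used to
   distinguish signal from noise.

Peak picking finds local maxima above a relative threshold with 3×3
centroid refinement (sub-bin accuracy ≈ 0.1 bin for isolated peaks).

Resolution note: the acquired window (128 × 24 ns ≈ 3.07 µs) sets a
Blackman mainlobe of ≈ 0.55 MHz, so peaks closer than that pull each
other's maxima regardless of zero-filling; and τ = 120 ns imposes blind
spots at multiples of 1/τ ≈ 8.33 MHz. The round-trip tests place their
toy protons to respect both constraints — that is a property of any
spectrometer with these settings, not of this implementation.

## Kinetics

The fully competitive model is fit globally (one shared Vmax, KM, KI
across all inhibitor series) by bounded nonlinear least squares (lmfit
over scipy's trust-region reflective solver), unit weights by default
(an optional 1/v² weighting flag exists), with default initialisation
Vmax = 1.2·max(v₀), KM = median(S), KI = median(nonzero I) and up to
five seeded, jittered restarts before declaring failure. Standard errors
come from the covariance at the optimum; Wald t-intervals provide
confidence intervals. kcat = Vmax/[E] with [E] defaulting to 5.0 µM (the
assay enzyme concentration). A dataset with a single inhibitor level is
rejected: KI is structurally unidentifiable there.

The competitive diagnostic fits per-level Lineweaver–Burk lines and
compares a shared-intercept model with per-level intercepts by an
F-test; competitive data keep a common ordinate intercept (1/Vmax),
uncompetitive-like data are flagged.

## Synthetic data: what it does and does not emulate

- **Toy {FeNO}⁷ sites**: Fe at the origin, NO along +z (Fe–N 1.7 Å,
  N–O 1.15 Å, Fe–N–O 150° — typical {FeNO}⁷ values; the published
  DFT-optimised coordinates live in supplementary material that is not
  redistributed here), protons at prescribed (r, θ, φ). Orientations
  round-trip to 1e−9 degrees; overlapping atoms (< 0.5 Å) are rejected.
- **Echo traces**: exact four-pulse modulation × exponential decay +
  seeded complex white noise. Not emulated: finite pulse bandwidth,
  nuclear-modulation interference between pathways, relaxation beyond a
  single exponential, resonator bandwidth. Passing round trips therefore
  show the simulate→process chain is self-consistent at bin resolution,
  not that real spectra are noise-free.
- **Kinetics tables**: model rates × (1 + N(0, sd)) truncated at zero,
  on the inhibitor-series design (substrate 7–1000 µM; inhibitor
  0/167/500/1500 µM; 3% noise; truth kcat 1.31 s⁻¹, KM 6.7 µM,
  KI 280 µM). Real assays add electrode drift and replicate structure
  the generator does not model, so printed standard errors of a real
  experiment are not reproducible — the Monte-Carlo coverage test
  (95% CI covering truth in ≥ 90% of 200 replicates, bias < 5%) is the
  meaningful statement.
- **Miniature multi-chain structures**: a 10-residue helical Cα template
  copied under random rigid motions with per-atom Gaussian jitter;
  expected pairwise RMSD ≈ √2·sd for small sd (the Kabsch fit absorbs
  √(1 − 6/3N) of it, ~11% for N = 10).
- **Synthetic assembly stand-in**: a 12-chain structure whose chain-B
  active site is constructed exactly to the published first-shell
  geometry of the inhibitor complex (two-sphere-intersection placement
  of the ligand carbon chain makes all target distances and angles exact
  by construction). It exists so the full geometry pipeline — parsing,
  site report, Cα RMSD across 12 chains — runs offline; agreement there
  validates the measurement chain, not the deposited coordinates, which
  are not bundled.

## Pipeline

The field-series runner reads a YAML config (units explicit in key
names), builds couplings once, and per field position simulates peaks,
optionally a synthetic "experimental" trace processed through the full
chain, and writes JSON/CSV/HDF5/PNG bundles plus a manifest with the
config hash and seeds. Reruns with the same config and seed produce
byte-identical manifests. Stage failures are recorded per field and
surface as a nonzero CLI exit.

## Problem sizes

Defaults used in the test suite: 128×128 acquisition grids zero-filled
to 1024, orientation grids of 100–400 directions, 50 random orientations
for the oracle-equivalence check, 200 Monte-Carlo replicates for the
kinetics coverage study, and 12-chain assemblies for the geometry
checks. These sizes make the whole suite run in a few seconds while
leaving every statistical criterion well-resolved.

## Known limitations

- ¹⁴N (I = 1) quadrupole simulation is out of scope; the ¹H region is
  the target. The Larmor/identity machinery supports ¹⁴N and ²H.
- The effective-spin nuclear-frequency treatment loses accuracy for
  very strong couplings (|T| ≳ 5 MHz); the full-spin diagonalization
  route is available where that matters.
- Ideal (infinitely hard) pulses; no blind-spot deconvolution beyond
  reporting, no vendor raw-file readers (import is HDF5/CSV).
- Isotropic (Fermi-contact) hyperfine contributions are deliberately
  zero: the model is purely dipolar, appropriate for protons ≥ 2.5 Å
  from the spin system.
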