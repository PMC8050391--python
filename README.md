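# fenoscore

Analysis toolkit for substrate binding at the nonheme iron site of
3-mercaptopropionic acid dioxygenase (3MDO) and related thiol
dioxygenases, built around the S = 3/2 iron-nitrosyl ({FeNO}⁷) probe of
the O₂-binding site. It links three strands of evidence into one tested
pipeline:

1. **Metal-site geometry** — parse PDB/mmCIF/XYZ coordinates, measure
   first-coordination-sphere distances and angles around the iron
   (Fe–O/S, Fe–Cl, Fe–His, chloride–tyrosine contacts), and compute
   Kabsch-superposed Cα RMSDs between the chains of an asymmetric unit.
2. **Pulsed EPR (HYSCORE)** — predict ¹H hyperfine couplings from the
   structure by the point-dipole approximation with {FeNO}⁷ spin
   projection, model the S = 3/2 centre (zero-field splitting, effective
   g-values of the ground Kramers doublet, orientation selection),
   simulate four-pulse HYSCORE cross peaks and time-domain echo
   surfaces, and process 2-D echo data into frequency spectra exactly as
   an experimentalist would (phase → polynomial baseline → Blackman
   apodization → zero-fill → 2-D FFT → |Re|).
3. **Inhibition kinetics** — globally fit initial-rate oxygen-consumption
   data to the fully competitive model and test the competitive
   signature (shared Lineweaver–Burk ordinate intercept).

## The core models

**Point-dipole hyperfine with spin projection.** A proton at distance
*r* from a point electron spin has a purely dipolar, axial coupling
tensor (−T, −T, 2T) with

    T = (μ0/4π) · ge · gn · βe · βn / (h · r³)      (79.06 MHz for ¹H at 1 Å)

For the antiferromagnetically coupled {FeNO}⁷ centre (Fe(III) S = 5/2 +
NO⁻ S = 1 → S = 3/2) the site contributions combine with spin-projection
factors:

    T_total = (7/5)·T_Fe − (1/5)·(T_N + T_O)

The tensor's unique axis is the Fe–H vector, expressed in a molecular
frame with z along the Fe–NO bond by polar angles (θ, φ).

**Effective spin-1/2 of the ground Kramers doublet.** With D ≈ 10 cm⁻¹
≫ hν at X-band, only the |mₛ = ±1/2⟩ doublet is probed; it behaves as a
fictitious spin-1/2 with g_eff ≈ (2g(1 + 3E/2D), 2g(1 − 3E/2D), g)
≈ (4.05, 3.96, 2.01). The observed splitting of the perpendicular pair
inverts to the rhombicity:

    E/D = (2/3) · (g₊ − g₋)/(g₊ + g₋)

Nuclear frequencies in the two electron manifolds use the hyperfine
tensor rescaled per molecular axis by g_eff,i/g_i; this effective-spin
route is validated in the tests against full S = 3/2 ⊗ I = 1/2 dense
diagonalization (agreement ≤ 2% for couplings on the scale of the
analysed protons).

**Competitive inhibition.**

    v0 = Vmax·[S] / (KM·(1 + [I]/KI) + [S])

fit globally across inhibitor series; kcat = Vmax/[E].

## Worked example

```python
>>> import fenoscore as f
>>> f.point_dipole_T(1.0)                 # 1H point-dipole at 1 A, MHz
79.06437399302429
>>> round(f.larmor_frequency("14N", 175.0), 3)   # 14N Larmor at 175 mT
0.539
>>> first, refined = f.rhombicity_from_geff(4.06, 3.96)
>>> round(first, 5), round(refined, 5)    # E/D from the g ~ 4 splitting
(0.00831, 0.00831)
```

The g ≈ 4 pair 4.06/3.96 inverts to E/D ≈ 0.008 — a nearly axial
S = 3/2 centre — by both the first-order formula and numeric
diagonalization of the spin Hamiltonian.

A synthetic kinetics run (inhibitor series 0/167/500/1500 µM, substrate
7–1000 µM, 3 % multiplicative noise, enzyme 5.0 µM):

```python
>>> d = f.make_kinetics_dataset(noise_sd=0.03, seed=42)
>>> fit = f.global_fit(d)
>>> round(fit.kcat, 3), round(fit.KM, 2), round(fit.KI, 1)
(1.304, 6.57, 281.8)
>>> f.competitive_diagnostic(fit, d)["competitive_consistent"]
True
```

The generating truth was kcat = 1.31 s⁻¹, K_M = 6.7 µM, K_I = 280 µM;
the fit recovers it within noise, and the shared-intercept F-test is
consistent with a classic competitive inhibitor.

The command line mirrors the library:

```bash
fenoscore spin --D 10 --EoverD 0.008 --mw 9.78 --geff 4.06 3.96
fenoscore geometry --structure complex.pdb --chain B --metal FE --report table.json
fenoscore synth kinetics --seed 3 --out rates.csv
fenoscore kinetics-fit --in rates.csv --out fit.json
fenoscore run --config run.yaml      # full field-series pipeline
```

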