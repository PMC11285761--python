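# colhier

Analysis of the hierarchical organization of type I collagen across
mineralization states, combining two modalities:

* **Fiber diffraction (XRD):** each 2D scatter pattern of a scanning-SAXS
  map is reduced to five structural metrics — collagen D-period,
  intermolecular spacing, fibril and molecular azimuthal dispersions, and
  relative supramolecular twist.
* **Polarization-resolved SHG (pSHG):** each 512 × 512 × 12 stack of
  second-harmonic images under rotated linear polarization is fitted
  per pixel with a circular-harmonic model, yielding maps of the
  organization parameter I₂ and dominant orientation φ₂.

The package targets the turkey leg tendon model, whose non-mineralizing
(NM), early-mineralizing (EM) and late-mineralizing (LM) zones provide a
natural gradient of mineral content.  It is written for scientists who want
a tested, reproducible pipeline for either modality — or for the combined
question of how mineralization changes collagen order at fibrillar and
molecular scales.  Raw beamline/microscope data are not required: a
synthetic-data module generates scatter patterns and pSHG stacks from known
ground truth, so the whole pipeline is verifiable as a round trip.

## Models in brief

With the convention Q = 2π/d, a detector pixel at in-plane radius r maps to
Q = (4π/λ)·sin(½·arctan(r/L)).  Patterns are resampled to polar
(azimuth × Q) coordinates (720 segments of 0.5°); around each diffraction
feature a Porod background (I ∼ Q⁻⁴) is removed by a linear fit to
(ln Q, ln I) over flank windows.  The D-period comes from the
intensity-weighted centroid of the third meridional order in
0.24–0.32 nm⁻¹ (d = 3·2π/Q̄); the intermolecular spacing from a Gaussian
fit in 1.9–3.5 nm⁻¹; the dispersions from the FWHM of the per-segment net
peak signal folded to 180°; and the relative twist from the quadrature
deconvolution σ_twist = √(σ²_mol − σ²_fib), normalized to the NM mean.

Per pSHG pixel, I(α) = a₀ + A₂ cos 2(α−φ₂) + A₄ cos 4(α−φ₄) is fitted by
linear least squares on {1, cos 2α, sin 2α, cos 4α, sin 4α}; I₂ = A₂/a₀
measures organization around φ₂.  Regions are compared with one-way ANOVA
plus the Tukey–Kramer studentized-range test (per scan pattern for XRD,
per acquisition mean for pSHG).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run the full synthetic study
(rasters go to `scratch/`, tables to `results/`):

```sh
python analysis/01_simulate_xrd_scan.py    # 20 x 20 NM/EM/LM snake scan
python analysis/02_reduce_xrd_scan.py      # five metrics per pattern
python analysis/03_simulate_pshg.py        # 4 samples x (6+4+4) stacks
python analysis/04_fit_pshg.py             # per-pixel harmonic fits
python analysis/05_compare_regions.py      # ANOVA + Tukey-Kramer
```

Step 02 prints recovery against the generating ground truth (one run):

```
NM: d 66.90 (true 66.92)  spacing 2.370 (true 2.370)  fibril FWHM 30.32 (true 31.19)  molecular FWHM 37.38 (true 37.43)  twist 9.11 (true 8.79)
EM: d 67.45 (true 67.46)  spacing 2.160 (true 2.160)  fibril FWHM 15.40 (true 15.31)  molecular FWHM 24.51 (true 24.55)  twist 8.06 (true 8.15)
LM: d 67.16 (true 67.21)  spacing 2.131 (true 2.130)  fibril FWHM 20.14 (true 19.88)  molecular FWHM 24.92 (true 24.96)  twist 6.12 (true 6.41)
```

i.e. region-mean D-periods within 0.05 nm, spacings within 0.001 nm and
dispersion FWHMs within 0.9° of truth, with the expected orderings (spacing
NM > EM > LM; dispersions and twist largest in NM).  Step 04 recovers the
region organization parameters:

```
region  mean_i2   std_i2  n_acquisitions
    NM 0.210782 0.000034              24
    EM 0.290573 0.000033              16
    LM 0.330493 0.000031              16
```

and step 05 reports, per metric, e.g.

```
intermolecular_spacing_nm: F = 9.2498e+06, p = 0, pairs: NM-EM ****, NM-LM ****, EM-LM ****
mean_i2: F = 6.8892e+07, p = 1.01e-170, pairs: NM-EM ****, NM-LM ****, EM-LM ****
```

(stars follow the 0.05/0.01/0.001/0.0001 tiers).  A self-contained
end-to-end demo is also available as a CLI:

```sh
colhier run-demo --out results/demo --rows 2 --cols 6
```

Other subcommands (`colhier --help`): `simulate-xrd`, `simulate-pshg`,
`reduce-xrd`, `fit-pshg`, `compare-regions` — each takes YAML scenes or
configs, emits CSV/TIFF/JSON outputs and writes a JSON manifest recording
the seed and configuration of the run.

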