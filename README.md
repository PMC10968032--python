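# brainbeam

Voxel Monte Carlo simulation of near-infrared light propagation through a
layered human head model, built to answer a practical design question for
optical brain interfaces (fNIRS, photoacoustic imaging, optogenetics):
**which type of optical source delivers the most light to a given depth,
and how wide is its illumination field once it gets there?**

The package simulates sixteen source emission models — point sources
(pencil, isotropic, cone, arcsine), line sources (diffuse line, slit) and
surface sources (collimated / angular / hyperboloid Gaussian, planar,
disk, ring, pencil array, and three spatial-frequency / Fourier
patterns) — launched at the scalp surface of a four-layer head phantom
(scalp 3 mm, skull 5 mm, cerebrospinal fluid 2 mm, gray matter 4 mm;
a 14³ mm³ cube of 140³ voxels at 0.1 mm), with tissue optical properties
at 800 nm. It then quantifies the resulting light distribution.

## Model

Photon packets undergo the standard hop–drop–spin random walk on the
voxel grid: exponential free paths against the scattering coefficient
μs, Henyey–Greenstein deflections with anisotropy g, continuous
absorption weighting exp(−μa·l) along each track segment, unpolarized
Fresnel reflection/refraction at every voxel face where the refractive
index changes, and Russian-roulette termination of low-weight packets.
Fluence F (mm⁻², per unit launched energy) is scored per voxel with the
track-length estimator, and the absorbed energy density follows as

    A = μa · F

Quantification mirrors the study design:

* **Layer energy percentages** — FP and AP, the share of the in-tissue
  fluence / absorption deposited in each of the four layers,
  `P_i = E_i / Σ_i E_i × 100`.
* **Maximum propagation depth** — the axial profile through the source
  axis (x = y = 7 mm) is min–max normalized and scanned for the deepest
  voxel still at 1%, 0.1% or 0.01% of the column maximum.
* **Optical field width** — FWHM of lateral cuts through the beam axis
  at each depth, located by linear interpolation.

## Worked example

```python
import brainbeam as bb

volume = bb.build_layered_volume()          # 140^3 labeled head phantom
props  = bb.default_property_table()        # tissue optics at 800 nm
source = bb.SourceSpec(type_tag="pencil")   # at (7, 7, 0) mm, aimed +z

E = bb.run_simulation(volume, props, source,
                      bb.SimConfig(n_photons=200_000, rng_seed=3))
fp = bb.layer_percentages(E, volume, kind="fluence")
print(fp.percentages.round(3).tolist())
print(round(E.escaped_energy, 4), round(E.absorbed_energy, 4))
```

prints

```
[66.386, 29.248, 2.486, 1.879]
0.7023 0.2977
```

i.e. about 66.4% of the in-tissue fluence stays in the scalp, 29.2%
reaches the skull, 2.5% the CSF and 1.9% the gray matter, while 70% of
the launched energy escapes back out of the head — the central
quantitative fact of transcranial illumination.

The same pipeline for all sixteen sources, with depth and field-width
tables written to CSV/JSON:

```bash
brainbeam study --preset desk --seed 0 --out results/study
```

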