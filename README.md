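# centrofish

Quantification of centrosome-proximal mRNA localization, local
translation, and translation-dependent protein recruitment from 3D
single-molecule FISH / immunofluorescence image stacks — with a
ground-truthed synthetic microscopy generator so every stage of the
analysis is testable at desk scale.

## Who this is for

Cell biologists quantifying where an mRNA sits relative to an organelle
in 3D confocal stacks, and whether it is being translated there. The
motivating system is pericentrin (*PCNT*) at the mitotic centrosome:
the PCM must incorporate large amounts of a 3336-aa scaffold protein
within ~30 min of mitotic onset, while one full-length PCNT chain takes
~10–20 min to elongate at 3–10 aa/s. Co-translational targeting solves
this: polysomes — a 10 knt transcript can hold ⌊10,000/260⌋ = 38
ribosomes at typical inter-ribosome spacing — are moved to the
centrosome and finish synthesis on site.

## What it computes

Given multi-channel 3D stacks (mRNA smFISH; protein N-terminus IF;
protein C-terminus IF; PCM reference marker), per-cell masks and voxel
sizes:

- **Spots** — sub-voxel 3D smFISH detections (Laplacian-of-Gaussian,
  robust MAD thresholds, weighted-centroid refinement), with
  background-subtracted integrated intensities used in lieu of mRNA
  units.
- **Centrosomes** — segmented PCM bodies with intensity-weighted center
  of mass, equivalent spherical radius, and summed original-image
  intensity.
- **Radial profiles** — per cell, the intensity-weighted fraction of
  mRNA vs distance to the nearest centrosome in half-open 0.5 µm bins,
  averaged across cells with Student-t 95% CIs.
- **Translation sites** — the epitope logic N⁺/C⁻/smFISH⁺ identifies
  polysomes with nascent chains; the shell statistic is the fraction of
  mRNA 1–3 µm from the centrosome center bearing N-terminus signal.
- **Condition comparisons** — fold change, percent change and two-sided
  unpaired t-tests (Welch by default, classic Student's by flag) of
  centrosomal intensity, mRNA count, proximal fraction and shell
  translation fraction.
- **Synthetic data** — `generate_cell` / `generate_population` render
  PSF-accurate, Poisson-noised stacks from named condition presets
  (`G1`, `late_G2`, `early_M_control`, `early_M_puromycin`,
  `early_M_emetine`, `early_M_harringtonine`) that encode the biology's
  effect sizes: twofold PCM growth late G2 → early M, ~30% PCM loss
  under acute puromycin, fourfold mRNA rise G1 → late G2, mRNA
  dispersal under puromycin/harringtonine but not emetine.

See `docs/methods.md` for the model, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from centrofish import (generate_population, detect_spots, segment_reference,
                        assign_spots, proximal_fraction, centrosomal_intensity,
                        compare_conditions)

def per_cell_stats(preset_name, seed):
    proximal, intensity = [], []
    for image, truth in generate_population(preset_name, 12, seed=seed):
        spots = detect_spots(image, "mrna")
        cents = segment_reference(image, "reference")
        d = np.array([a.distance for a in assign_spots(spots, cents)])
        w = np.array([s.integrated_intensity for s in spots])
        proximal.append(proximal_fraction(d, w, radius=3.0))
        intensity.append(centrosomal_intensity(cents))
    return proximal, intensity

prox_c, int_c = per_cell_stats("early_M_control", seed=1)
prox_p, int_p = per_cell_stats("early_M_puromycin", seed=2)

disp = compare_conditions(prox_c, prox_p, "control", "puromycin")
print(f"proximal mRNA fraction: {disp.mean_a:.2f} vs {disp.mean_b:.2f} "
      f"(p = {disp.p:.2g})")
pcm = compare_conditions(int_p, int_c, "puromycin", "control")
print(f"centrosomal intensity change under puromycin: "
      f"{pcm.percent_change:+.1f}% (p = {pcm.p:.2g})")
```

Output:

```
proximal mRNA fraction: 0.49 vs 0.27 (p = 2.5e-06)
centrosomal intensity change under puromycin: -26.6% (p = 2.5e-05)
```

A brief (2 min) puromycin pulse dissociates ribosomes: the mRNA loses
its centrosomal enrichment (0.49 → 0.27 of mRNA within 3 µm of a pole)
and the centrosomes end up with roughly 30% less protein — translation
near the centrosome was feeding the PCM.

The same analyses run from the shell:

```sh
centrofish simulate --preset early_M_control --n-cells 6 --seed 1 --outdir sim/
centrofish detect --in sim/ --out out/
centrofish profile --spots out/spots.csv --centrosomes out/centrosomes.csv --out out/
centrofish kinetics --transcript-length-nt 10000 --spacing-nt 260
centrofish run --config config.yaml   # full pipeline from YAML
```

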