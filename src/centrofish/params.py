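"""Generator parameters and named condition presets.

The presets encode the study conditions the analysis is meant to
discriminate: cell-cycle stages (G1, late G2, early M) and acute
translation-inhibitor treatments of early-mitotic cells (puromycin,
harringtonine, emetine).  Relative to the early-M control:

* puromycin and harringtonine disperse the mRNA (proximal fraction drops
  to background), abolish nascent-chain signal, and reduce centrosomal
  protein by 30%;
* emetine freezes elongation but preserves polysomes, so it matches the
  control;
* late G2 has half the early-M centrosomal protein (mitotic maturation
  roughly doubles it) and the same mRNA count;
* G1 has a quarter of the late-G2 mRNA count (expression rises ~4x from
  G1 to late G2) and a single unseparated centrosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml


@dataclass(frozen=True)
class NoiseParams:
    """Camera model: Poisson shot noise on photon counts, then additive
    Gaussian read noise.  ``photon_gain=None`` disables shot noise."""

    photon_gain: float | None = 1.0   # photons per intensity unit
    read_noise_sd: float = 2.0        # a.u., additive Gaussian

    def __post_init__(self) -> None:
        if self.photon_gain is not None and self.photon_gain <= 0:
            raise ValueError("photon_gain must be positive or None")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    @property
    def enabled(self) -> bool:
        return self.photon_gain is not None or self.read_noise_sd > 0


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of one synthetic cell.

    Lengths in µm, axis order (z, y, x), intensities in arbitrary units
    calibrated so that 1 a.u. = 1 expected photon at the default gain.
    """

    image_shape: tuple[int, int, int] = (32, 128, 128)
    voxel_size: tuple[float, float, float] = (0.30, 0.12, 0.12)
    n_centrosomes: int = 2
    centrosome_centers: tuple[tuple[float, float, float], ...] | None = None
    centrosome_radius: float = 1.0          # nominal PCM radius; blob SD = radius/2
    centrosome_amplitude: float = 5.0e5     # total flux per centrosome
    n_spots: int = 40
    spot_amplitude: float = 1.2e4           # mean integrated flux per mRNA spot
    spot_amplitude_cv: float = 0.15         # lognormal spread of per-spot flux
    proximal_fraction: float = 0.65         # spots drawn from the decaying component
    proximal_decay_length: float = 1.5      # µm, exponential decay of distance
    proximal_max_radius: float = 5.0        # µm, truncation of the proximal law
    translating_fraction: float = 0.5       # spots with a nascent-chain source
    nterm_spot_amplitude: float = 8.0e3     # flux of the N-term source per polysome
    nterm_background: float = 20.0          # a.u. per voxel
    cterm_background: float = 50.0          # a.u. per voxel (diffuse mature protein)
    mrna_background: float = 20.0           # a.u. per voxel
    reference_background: float = 10.0      # a.u. per voxel
    psf_sigma: tuple[float, float, float] = (0.6, 0.25, 0.25)
    noise: NoiseParams = field(default_factory=NoiseParams)
    cell_axes_fraction: tuple[float, float, float] = (0.42, 0.45, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("proximal_fraction", "translating_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("centrosome_radius", "centrosome_amplitude",
                     "spot_amplitude", "proximal_decay_length",
                     "proximal_max_radius", "nterm_spot_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(s <= 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be positive")
        if self.n_centrosomes not in (1, 2):
            raise ValueError("n_centrosomes must be 1 or 2")
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        extent = np.asarray(self.image_shape) * np.asarray(self.voxel_size)
        for c in self.resolved_centers():
            if np.any(np.asarray(c) < 0) or np.any(np.asarray(c) >= extent):
                raise ValueError(f"centrosome center {c} outside image bounds")

    def resolved_centers(self) -> tuple[tuple[float, float, float], ...]:
        """Centrosome centers in µm; defaults put 1–2 poles near mid-stack,
        separated by 3 µm along y when there are two."""
        if self.centrosome_centers is not None:
            return tuple(tuple(float(x) for x in c)
                         for c in self.centrosome_centers[: self.n_centrosomes])
        extent = np.asarray(self.image_shape) * np.asarray(self.voxel_size)
        mid = extent / 2.0
        if self.n_centrosomes == 1:
            return (tuple(mid),)
        off = np.array([0.0, 1.5, 0.0])
        return (tuple(mid - off), tuple(mid + off))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        return d

    def to_yaml(self) -> str:
        def _clean(v):
            if isinstance(v, tuple):
                return [_clean(x) for x in v]
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        return yaml.safe_dump(_clean(self.to_dict()), sort_keys=False)


#: names of supported condition presets
PRESET_NAMES = (
    "G1",
    "late_G2",
    "early_M_control",
    "early_M_puromycin",
    "early_M_emetine",
    "early_M_harringtonine",
)

_CONTROL = GeneratorParams()

_PRESETS: dict[str, GeneratorParams] = {
    "early_M_control": _CONTROL,
    # elongation freeze: polysomes and localization intact
    "early_M_emetine": _CONTROL,
    # ribosome release: mRNA disperses, nascent chains lost, PCM -30%
    "early_M_puromycin": replace(
        _CONTROL,
        proximal_fraction=0.05,
        translating_fraction=0.0,
        centrosome_amplitude=_CONTROL.centrosome_amplitude * 0.7,
    ),
    # initiation block / run-off: same dispersal phenotype
    "early_M_harringtonine": replace(
        _CONTROL,
        proximal_fraction=0.05,
        translating_fraction=0.0,
        centrosome_amplitude=_CONTROL.centrosome_amplitude * 0.7,
    ),
    # pre-mitotic: half the centrosomal protein, same mRNA count
    "late_G2": replace(
        _CONTROL,
        centrosome_amplitude=_CONTROL.centrosome_amplitude * 0.5,
    ),
    # early interphase: quarter of late-G2 mRNA, one centrosome
    "G1": replace(
        _CONTROL,
        n_spots=_CONTROL.n_spots // 4,
        n_centrosomes=1,
        centrosome_amplitude=_CONTROL.centrosome_amplitude * 0.25,
        proximal_fraction=0.2,
        translating_fraction=0.2,
    ),
}


def preset(name: str, **overrides) -> GeneratorParams:
    """Return the generator parameters for a named condition.

    ``overrides`` replace individual fields (e.g. ``seed=7``).
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        ) from None
    return replace(base, **overrides) if overrides else base
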