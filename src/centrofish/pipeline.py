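"""End-to-end pipeline: simulate/load -> detect -> profile -> translation
-> intensity -> compare, with CSV outputs and a provenance record.

Condition labels are user-supplied metadata (or the preset names in
simulate mode); they are never inferred from the images.  Cells excluded
at any stage (no centrosome, no spots, no shell spots) are logged with
the reason.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import (DetectionConfig, SegmentationConfig, attach_channel_signals,
                     detect_spots, segment_reference)
from .image import VoxelImage
from .params import PRESET_NAMES
from .quant import centrosomal_intensity, mrna_count
from .radial import aggregate_profiles, assign_spots, proximal_fraction, radial_profile
from .simulate import generate_population
from .stats import compare_conditions
from .translation import ShellConfig, call_translation, cell_shell_fraction

log = logging.getLogger("centrofish")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    outdir: str = "run"
    seed: int = 0
    # simulate mode: list of {label, preset, n_cells}; labels default to
    # the preset names
    conditions: list = field(default_factory=lambda: [
        {"label": "early_M_control", "preset": "early_M_control", "n_cells": 6},
        {"label": "early_M_puromycin", "preset": "early_M_puromycin", "n_cells": 6},
    ])
    # detect mode: directory of saved stacks plus a conditions.csv
    # (columns: image, condition) overrides simulate mode
    input_dir: str | None = None
    jitter_sd: float = 0.15
    save_images: bool = False
    # analysis parameters
    spot_sigma_um: tuple = (0.6, 0.25, 0.25)
    detection_threshold_k: float = 5.0
    segmentation: dict = field(default_factory=dict)
    shell: dict = field(default_factory=dict)
    bin_width: float = 0.5
    max_distance: float = 15.0
    proximal_radius: float = 3.0
    classic_t: bool = False
    weighting: str = "intensity"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(spot_sigma_um=tuple(self.spot_sigma_um),
                               threshold_k=self.detection_threshold_k)

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self.segmentation)

    def shell_config(self) -> ShellConfig:
        return ShellConfig(**self.shell)


def _load_cells(config: RunConfig):
    """Yield (condition_label, VoxelImage) pairs for the run."""
    if config.input_dir is not None:
        indir = Path(config.input_dir)
        table = pd.read_csv(indir / "conditions.csv")
        for _, row in table.iterrows():
            img = VoxelImage.load(indir / row["image"])
            yield str(row["condition"]), img
        return
    rng = np.random.default_rng(config.seed)
    for cond in config.conditions:
        label = cond.get("label", cond["preset"])
        if cond["preset"] not in PRESET_NAMES:
            raise ValueError(f"unknown preset {cond['preset']!r}")
        pop_seed = int(rng.integers(0, 2**31 - 1))
        cells = generate_population(cond["preset"], int(cond["n_cells"]),
                                    seed=pop_seed, jitter_sd=config.jitter_sd)
        for image, _truth in cells:
            yield label, image


def analyze_cell(image: VoxelImage, config: RunConfig) -> dict:
    """Run detection, assignment and translation calling on one cell."""
    det = config.detection_config()
    shell = config.shell_config()
    spots = detect_spots(image, "mrna", det)
    centrosomes = segment_reference(image, "reference",
                                    config.segmentation_config())
    result = {"spots": spots, "centrosomes": centrosomes,
              "assignments": None, "calls": None}
    if spots and centrosomes:
        attach_channel_signals(image, spots, ("nterm", "cterm"),
                               shell.probe_radius)
        assignments = assign_spots(spots, centrosomes)
        calls = [call_translation(s, shell, distance=a.distance)
                 for s, a in zip(spots, assignments)]
        result["assignments"] = assignments
        result["calls"] = calls
    return result


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write CSV outputs, a log, and provenance.

    Returns the run directory.  Raises on zero analyzable cells.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)

    shell = config.shell_config()
    n_bins = int(np.ceil(config.max_distance / config.bin_width))
    bin_cols = [f"bin_{i * config.bin_width:.1f}" for i in range(n_bins)] + ["overflow"]

    spot_rows, cent_rows, call_rows = [], [], []
    profile_rows, shellfrac_rows, intensity_rows, count_rows = [], [], [], []
    per_condition_profiles: dict[str, list] = {}
    per_condition: dict[str, dict[str, list]] = {}

    n_cells = 0
    for label, image in _load_cells(config):
        n_cells += 1
        res = analyze_cell(image, config)
        cid = image.cell_id
        stats = per_condition.setdefault(
            label, {"proximal": [], "intensity": [], "count": [], "shell": []}
        )
        for rec in res["centrosomes"]:
            cent_rows.append({
                "cell_id": cid, "condition": label, "rank": rec.rank,
                "z_um": rec.center_of_mass[0], "y_um": rec.center_of_mass[1],
                "x_um": rec.center_of_mass[2],
                "radius_um": rec.equivalent_radius,
                "sum_intensity": rec.sum_intensity,
            })
        count_rows.append({"cell_id": cid, "condition": label,
                           "mrna_count": mrna_count(res["spots"])})
        stats["count"].append(mrna_count(res["spots"]))
        if res["centrosomes"]:
            val = centrosomal_intensity(res["centrosomes"])
            intensity_rows.append({"cell_id": cid, "condition": label,
                                   "centrosomal_intensity": val})
            stats["intensity"].append(val)
        else:
            log.warning("cell %s excluded from intensity: no centrosome", cid)
        if res["assignments"] is None:
            log.warning("cell %s excluded from profiling: no spots or "
                        "no centrosome", cid)
            if config.save_images:
                image.save(outdir / f"{cid}.tif")
            continue

        for spot, a, call in zip(res["spots"], res["assignments"], res["calls"]):
            spot_rows.append({
                "cell_id": cid, "condition": label,
                "z_um": spot.position[0], "y_um": spot.position[1],
                "x_um": spot.position[2],
                "intensity": spot.integrated_intensity,
                "quality": spot.quality,
                "nterm_signal": spot.channel_signals["nterm"].signal,
                "cterm_signal": spot.channel_signals["cterm"].signal,
                "distance_um": a.distance,
                "assigned_rank": a.centrosome_rank,
            })
            call_rows.append({
                "cell_id": cid, "condition": label,
                "z_um": spot.position[0], "y_um": spot.position[1],
                "x_um": spot.position[2],
                "nterm_positive": call.nterm_positive,
                "cterm_positive": call.cterm_positive,
                "label": call.label,
                "shell_member": call.shell_member,
                "distance_um": call.distance,
            })

        d = np.array([a.distance for a in res["assignments"]])
        w = np.array([s.integrated_intensity for s in res["spots"]])
        prof = radial_profile(d, w, config.bin_width, config.max_distance)
        profile_rows.append({"cell_id": cid, "condition": label,
                             **dict(zip(bin_cols, prof))})
        per_condition_profiles.setdefault(label, []).append(prof)
        stats["proximal"].append(
            proximal_fraction(d, w, config.proximal_radius))
        frac = cell_shell_fraction(res["calls"], weighting=config.weighting)
        if frac is None:
            log.warning("cell %s excluded from shell fraction: no shell "
                        "spots", cid)
        else:
            shellfrac_rows.append({"cell_id": cid, "condition": label,
                                   "shell_fraction": frac})
            stats["shell"].append(frac)
        if config.save_images:
            image.save(outdir / f"{cid}.tif")

    if n_cells == 0:
        raise RuntimeError("zero analyzable cells")

    pd.DataFrame(spot_rows).to_csv(outdir / "spots.csv", index=False)
    pd.DataFrame(cent_rows).to_csv(outdir / "centrosomes.csv", index=False)
    pd.DataFrame(profile_rows).to_csv(outdir / "profiles.csv", index=False)
    pd.DataFrame(call_rows).to_csv(outdir / "translation_calls.csv", index=False)
    pd.DataFrame(shellfrac_rows).to_csv(outdir / "shell_fractions.csv", index=False)
    pd.DataFrame(intensity_rows).to_csv(outdir / "per_cell_intensity.csv", index=False)
    pd.DataFrame(count_rows).to_csv(outdir / "per_cell_counts.csv", index=False)

    summary_rows = []
    for label, profs in per_condition_profiles.items():
        agg = aggregate_profiles(np.array(profs), config.bin_width,
                                 config.max_distance)
        frame = agg.to_frame()
        frame.insert(0, "condition", label)
        summary_rows.append(frame)
    if summary_rows:
        pd.concat(summary_rows).to_csv(outdir / "profile_summary.csv",
                                       index=False)

    comp_rows = []
    labels = list(per_condition)
    ref = labels[0] if labels else None
    for other in labels[1:]:
        for metric in ("proximal", "intensity", "count", "shell"):
            a = per_condition[ref][metric]
            b = per_condition[other][metric]
            if len(a) < 2 or len(b) < 2:
                log.warning("skipping %s comparison %s vs %s: too few cells",
                            metric, ref, other)
                continue
            cmp_ = compare_conditions(a, b, ref, other,
                                      classic=config.classic_t)
            comp_rows.append({
                "metric": metric, "condition_a": ref, "condition_b": other,
                "n_a": cmp_.n_a, "n_b": cmp_.n_b,
                "mean_a": cmp_.mean_a, "mean_b": cmp_.mean_b,
                "fold_change": cmp_.fold_change,
                "percent_change": cmp_.percent_change,
                "t": cmp_.t, "p": cmp_.p,
                "ci_lo": cmp_.ci_low, "ci_hi": cmp_.ci_high,
                "degenerate": cmp_.degenerate,
            })
    pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)

    cfg_dict = asdict(config)
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    provenance = {
        "package": "centrofish",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "config": cfg_dict,
        "n_cells": n_cells,
    }
    (outdir / "provenance.yaml").write_text(yaml.safe_dump(provenance,
                                                           sort_keys=False))
    log.removeHandler(handler)
    handler.close()
    return outdir
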