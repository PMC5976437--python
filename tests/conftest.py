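"""Shared fixtures: analyzed synthetic populations, cached per
(preset, master seed) so expensive image analysis runs once per session."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest
from scipy.spatial import cKDTree

from centrofish import (detect_spots, generate_population, proximal_fraction,
                        segment_reference)


@dataclass
class AnalyzedCell:
    truth: object
    spots: list
    centrosomes: list

    @property
    def count(self) -> int:
        return len(self.spots)

    @property
    def intensity(self) -> float:
        return sum(r.sum_intensity for r in self.centrosomes)

    @property
    def radii(self) -> list[float]:
        return [r.equivalent_radius for r in self.centrosomes]

    def distances_weights(self):
        """Nearest-centrosome distance and intensity per detected spot."""
        from centrofish import assign_spots
        assignments = assign_spots(self.spots, self.centrosomes)
        d = np.array([a.distance for a in assignments])
        w = np.array([s.integrated_intensity for s in self.spots])
        return d, w

    def proximal(self, radius: float = 3.0) -> float:
        d, w = self.distances_weights()
        return proximal_fraction(d, w, radius)


_CACHE: dict = {}


@pytest.fixture(scope="session")
def analyzed_population():
    """Factory: analyzed 30-cell population for (preset, seed)."""

    def get(preset_name: str, seed: int, n_cells: int = 30):
        key = (preset_name, seed, n_cells)
        if key not in _CACHE:
            cells = []
            for image, truth in generate_population(preset_name, n_cells,
                                                    seed=seed):
                cells.append(AnalyzedCell(
                    truth=truth,
                    spots=detect_spots(image, "mrna"),
                    centrosomes=segment_reference(image, "reference"),
                ))
            _CACHE[key] = cells
        return _CACHE[key]

    return get


def match_spots(true_positions: np.ndarray, detected_positions: np.ndarray,
                radius: float = 0.5):
    """One-to-one greedy matching of detections to true spots.

    Returns (recall, precision, pairs) where pairs maps detected index
    to true index for matches within ``radius`` µm.
    """
    if len(detected_positions) == 0:
        return 0.0, 0.0, {}
    d = np.linalg.norm(
        detected_positions[:, None, :] - true_positions[None, :, :], axis=2
    )
    pairs = {}
    used_true = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for det_i, true_j in order:
        if d[det_i, true_j] > radius:
            break
        if det_i in pairs or true_j in used_true:
            continue
        pairs[int(det_i)] = int(true_j)
        used_true.add(int(true_j))
    recall = len(pairs) / len(true_positions)
    precision = len(pairs) / len(detected_positions)
    return recall, precision, pairs
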