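"""Per-cell centrosomal protein levels and mRNA counts.

Centrosomal protein per cell is the sum of the summed original-image
intensities over the cell's segmented PCM bodies (both spindle poles).
The mRNA count is the number of detected smFISH spots; an optional
intensity-deconvolved count divides the total spot intensity by the
median single-spot intensity, for samples where spots may contain more
than one molecule.
"""

from __future__ import annotations

import numpy as np

from .detect import CentrosomeRecord, Spot
from .stats import ConditionComparison, compare_conditions  # noqa: F401


def centrosomal_intensity(centrosomes: list[CentrosomeRecord]) -> float:
    """Summed centrosomal intensity of one cell (all poles)."""
    if not centrosomes:
        raise ValueError("cell has no centrosome records; exclude it upstream")
    return float(sum(r.sum_intensity for r in centrosomes))


def mrna_count(spots: list[Spot], intensity_deconvolved: bool = False) -> int:
    """Number of mRNA molecules in one cell.

    Default: the spot count.  With ``intensity_deconvolved=True``:
    ``round(total intensity / median single-spot intensity)``, which
    resolves multi-molecule spots under the assumption that the median
    spot holds a single molecule.
    """
    if not spots:
        return 0
    if not intensity_deconvolved:
        return len(spots)
    intensities = np.array([s.integrated_intensity for s in spots])
    return int(round(intensities.sum() / np.median(intensities)))
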