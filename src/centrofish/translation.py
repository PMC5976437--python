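"""Nascent-translation-site calling and translational kinetics.

The epitope logic: an mRNA spot decorated by nascent chains shows
N-terminus immunofluorescence but no C-terminus signal (the C-terminus is
not yet synthesized), whereas a spot coincident with full-length protein
is positive for both termini.  Per cell, the fraction of mRNA within a
1–3 µm shell around the centrosome center that carries nascent-chain
signal is the shell translation fraction.

The kinetics calculators are exact arithmetic: the ribosome capacity of a
transcript is ``floor(transcript length / inter-ribosome spacing)``, and
the synthesis time of a protein is ``CDS length / elongation rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Spot
from .stats import ConditionComparison, compare_conditions, t_confidence_interval

LABELS = ("translating", "mrna_only", "ambiguous")


@dataclass(frozen=True)
class ShellConfig:
    """Geometry and positivity thresholds of the shell statistic."""

    r_inner: float = 1.0        # µm; excludes mRNA inside the PCM body
    r_outer: float = 3.0        # µm
    probe_radius: float = 0.3   # µm ball for local channel measurement
    positivity_k: float = 3.0   # cutoff in annulus-MAD units

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_inner < self.r_outer:
            raise ValueError("need 0 <= r_inner < r_outer")


@dataclass
class TranslationCall:
    spot: Spot
    nterm_positive: bool
    cterm_positive: bool
    label: str                 # one of LABELS
    shell_member: bool = False
    distance: float = np.nan   # µm to nearest centrosome, if known


@dataclass(frozen=True)
class KineticsParams:
    """Transcript and elongation parameters of the kinetics calculators."""

    transcript_length_nt: int = 10_000
    cds_length_aa: int = 3336
    inter_ribosome_spacing_nt: int = 260
    elongation_rate_aa_per_s: float = 3.0

    def __post_init__(self) -> None:
        if self.transcript_length_nt <= 0:
            raise ValueError("transcript_length_nt must be positive")
        if self.inter_ribosome_spacing_nt <= 0:
            raise ValueError("inter_ribosome_spacing_nt must be positive")
        if self.cds_length_aa < 0:
            raise ValueError("cds_length_aa must be non-negative")
        if self.elongation_rate_aa_per_s <= 0:
            raise ValueError("elongation_rate_aa_per_s must be positive")


def call_translation(spot: Spot, shell: ShellConfig = ShellConfig(),
                     distance: float = np.nan) -> TranslationCall:
    """Classify one spot from its local N-/C-terminus signals.

    Positivity per channel: local signal > ``positivity_k`` x annulus MAD.
    Labels are exhaustive and exclusive: ``translating`` = N+ and C-,
    ``ambiguous`` = N+ and C+ (full-length protein coincident with mRNA),
    ``mrna_only`` otherwise.
    """
    try:
        n_sig = spot.channel_signals["nterm"]
        c_sig = spot.channel_signals["cterm"]
    except KeyError as exc:
        raise ValueError(
            "spot lacks nterm/cterm local signals; run "
            "attach_channel_signals first"
        ) from exc
    n_pos = n_sig.signal > shell.positivity_k * n_sig.noise_mad
    c_pos = c_sig.signal > shell.positivity_k * c_sig.noise_mad
    if n_pos and not c_pos:
        label = "translating"
    elif n_pos and c_pos:
        label = "ambiguous"
    else:
        label = "mrna_only"
    member = bool(shell.r_inner <= distance < shell.r_outer) \
        if np.isfinite(distance) else False
    return TranslationCall(spot=spot, nterm_positive=bool(n_pos),
                           cterm_positive=bool(c_pos), label=label,
                           shell_member=member, distance=distance)


def cell_shell_fraction(calls: list[TranslationCall],
                        weighting: str = "intensity",
                        include_ambiguous: bool = True) -> float | None:
    """Fraction of shell-member mRNA that carries N-terminus signal.

    Intensity-weighted by default (spot intensity stands in for mRNA
    amount); ``weighting="count"`` weights spots equally.  Spots labeled
    ambiguous (N+/C+) stay in the denominator unless excluded.  Returns
    ``None`` for a cell with no shell spots (excluded upstream).
    """
    members = [c for c in calls if c.shell_member]
    if not include_ambiguous:
        members = [c for c in members if c.label != "ambiguous"]
    if not members:
        return None
    if weighting == "intensity":
        w = np.array([c.spot.integrated_intensity for c in members])
    elif weighting == "count":
        w = np.ones(len(members))
    else:
        raise ValueError("weighting must be 'intensity' or 'count'")
    pos = np.array([c.nterm_positive for c in members])
    return float(w[pos].sum() / w.sum())


def shell_translation_fraction(cells: list[list[TranslationCall]],
                               shell: ShellConfig = ShellConfig(),
                               weighting: str = "intensity"):
    """Per-cell shell translation fractions plus a cross-cell summary.

    Cells without shell spots are excluded and counted.  Returns
    ``(fractions, summary)`` where summary holds the mean, the Student-t
    95% CI, and the number of excluded cells.
    """
    fractions = []
    excluded = 0
    for calls in cells:
        f = cell_shell_fraction(calls, weighting=weighting)
        if f is None:
            excluded += 1
        else:
            fractions.append(f)
    fractions = np.asarray(fractions)
    if fractions.size:
        mean, lo, hi = t_confidence_interval(fractions)
    else:
        mean = lo = hi = np.nan
    summary = {"mean": mean, "ci_lo": lo, "ci_hi": hi,
               "n_cells": int(fractions.size), "n_excluded": excluded}
    return fractions, summary


def compare_shell_fractions(fractions_a, fractions_b, label_a: str = "A",
                            label_b: str = "B",
                            classic: bool = False) -> ConditionComparison:
    """Two-sided unpaired t-test between per-cell shell fractions."""
    return compare_conditions(fractions_a, fractions_b, label_a, label_b,
                              classic=classic)


def ribosome_capacity(params: KineticsParams = KineticsParams()) -> int:
    """Maximum simultaneous ribosome occupancy of one transcript."""
    return params.transcript_length_nt // params.inter_ribosome_spacing_nt


def synthesis_time(params: KineticsParams = KineticsParams()) -> float:
    """Seconds to synthesize one full-length protein after initiation."""
    return params.cds_length_aa / params.elongation_rate_aa_per_s
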