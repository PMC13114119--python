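"""In-silico arithmetic for invertible-promoter orientation assays.

Phase-variable promoters flanked by inverted repeats are assayed by
orientation-specific PCR (one product size per orientation) and by a
quantitative PCR-digestion strategy: a single amplicon spanning the
invertible region is cut asymmetrically by a restriction enzyme, so
the fragment-size pattern reports the orientation, and band
intensities report the fraction of the population in each state.

This module works on coordinates and intensities; an optional helper
scans a sequence for an enzyme recognition site (exact string match,
e.g. CCGG for HpaII).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmpliconDesign",
    "amplicon_size",
    "digest_fragments",
    "orientation_fractions",
    "find_cut_sites",
]


@dataclass(frozen=True)
class AmpliconDesign:
    """A convergent primer pair on a template, with internal cut sites.

    ``forward_start`` is the 5′ coordinate of the forward primer and
    ``reverse_end`` the coordinate one past the reverse primer's 3′ end
    (half-open), both 0-based on the template.  ``cut_offsets`` are bp
    from the amplicon start, strictly inside the amplicon.
    """

    name: str
    template_length: int
    forward_start: int
    reverse_end: int
    cut_offsets: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 <= self.forward_start < self.template_length):
            raise ValueError(f"{self.name}: forward primer outside template")
        if not (0 < self.reverse_end <= self.template_length):
            raise ValueError(f"{self.name}: reverse primer outside template")


def amplicon_size(design: AmpliconDesign) -> int:
    """Amplicon length for a convergent primer pair (half-open span)."""
    size = design.reverse_end - design.forward_start
    if size <= 0:
        raise ValueError(
            f"{design.name}: primers are divergent "
            f"(forward at {design.forward_start}, reverse 3' end at {design.reverse_end})"
        )
    return size


def digest_fragments(
    amplicon_length: int, cut_offsets: Sequence[int]
) -> list[int]:
    """Restriction fragment sizes for cuts at the given offsets.

    Fragments are consecutive differences of {0, offsets…, length},
    returned sorted descending; they sum to the amplicon length.
    """
    for off in cut_offsets:
        if not (0 < off < amplicon_length):
            raise ValueError(
                f"cut offset {off} outside amplicon of length {amplicon_length}"
            )
    bounds = sorted({0, amplicon_length, *cut_offsets})
    frags = [b - a for a, b in zip(bounds[:-1], bounds[1:])]
    return sorted(frags, reverse=True)


def orientation_fractions(
    intensities: pd.DataFrame,
    on_pattern: Sequence[int],
    off_pattern: Sequence[int],
    tolerance_bp: int = 5,
) -> tuple[float, float]:
    """Fraction of a population in each promoter orientation.

    ``intensities`` has columns ``fragment_bp, intensity`` (band sizes
    and densitometry readings).  Each band is matched (± tolerance) to
    the expected ON or OFF fragment pattern; matched intensities are
    summed and ``f_ON = I_ON / (I_ON + I_OFF)``, ``f_OFF = 1 − f_ON``.
    The two patterns must be distinguishable: a diagnostic size within
    tolerance of both patterns raises.
    """
    on = np.asarray(on_pattern)
    off = np.asarray(off_pattern)
    for a in on:
        if np.any(np.abs(off - a) <= 2 * tolerance_bp):
            raise ValueError(
                f"fragment {a} bp is ambiguous between the ON and OFF patterns "
                f"at ±{tolerance_bp} bp"
            )
    i_on = i_off = 0.0
    for row in intensities.itertuples(index=False):
        size = float(row.fragment_bp)
        val = float(row.intensity)
        m_on = bool(np.any(np.abs(on - size) <= tolerance_bp))
        m_off = bool(np.any(np.abs(off - size) <= tolerance_bp))
        if m_on and m_off:  # unreachable given the pattern check, kept defensive
            raise ValueError(f"fragment of {size} bp matches both patterns")
        if m_on:
            i_on += val
        elif m_off:
            i_off += val
    total = i_on + i_off
    if total <= 0:
        raise ValueError("no band intensity matched either orientation pattern")
    f_on = i_on / total
    return f_on, 1.0 - f_on


def find_cut_sites(sequence: str, recognition_site: str = "CCGG") -> list[int]:
    """0-based offsets of every exact recognition-site match."""
    seq = sequence.upper()
    site = recognition_site.upper()
    out = []
    start = 0
    while True:
        i = seq.find(site, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1
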