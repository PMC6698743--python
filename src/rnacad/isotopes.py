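"""Aggregated (unit-mass-binned) isotope distributions from compositions.

Patterns are computed by iterated convolution of per-element isotope
distributions: each element's per-atom distribution over nominal mass
offsets (0, +1, +2 neutrons) is raised to its atom count by repeated
squaring, and element patterns are convolved together.  This is the
standard aggregate treatment -- adequate for simulating and reading the
isotope clusters of kDa-scale RNA ions from centroided data; isotopic fine
structure is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .rna_chem import PROTON, Composition

__all__ = [
    "IsotopePattern",
    "NEUTRON_SPACING",
    "cluster_mz_grid",
    "isotope_pattern",
]

#: m/z spacing of adjacent isotopologue peaks for a singly charged ion,
#: i.e. the 13C-12C mass difference (Da).
NEUTRON_SPACING = 1.0033548

#: Per-element isotope abundances over nominal offsets 0, +1, +2 (IUPAC).
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
}


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances at nominal offsets k = 0, 1, 2, ... above the
    monoisotopic mass; abundances sum to 1 after truncation."""

    abundances: tuple[float, ...]
    monoisotopic_mass: float

    def __post_init__(self):
        if not self.abundances or self.abundances[0] <= 0:
            raise ValueError("offset 0 must be present with positive abundance")
        total = sum(self.abundances)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")

    def __len__(self) -> int:
        return len(self.abundances)


def _power_pattern(base: np.ndarray, count: int) -> np.ndarray:
    """``base`` convolved with itself ``count`` times (binary exponentiation)."""
    result = np.array([1.0])
    factor = base
    while count:
        if count & 1:
            result = np.convolve(result, factor)
        count >>= 1
        if count:
            factor = np.convolve(factor, factor)
    return result


@lru_cache(maxsize=4096)
def _pattern_cached(comp_items: tuple, truncation_threshold: float) -> tuple[float, ...]:
    dist = np.array([1.0])
    for element, count in comp_items:
        try:
            base = np.asarray(ISOTOPE_ABUNDANCES[element], dtype=float)
        except KeyError:
            raise ValueError(f"no isotope data for element {element!r}") from None
        dist = np.convolve(dist, _power_pattern(base, count))
    cumulative = np.cumsum(dist)
    keep = int(np.searchsorted(cumulative, 1.0 - truncation_threshold)) + 1
    dist = dist[:keep]
    dist = dist / dist.sum()
    return tuple(dist.tolist())


def isotope_pattern(
    comp: Composition, truncation_threshold: float = 1e-4
) -> IsotopePattern:
    """Aggregated isotope distribution of ``comp``.

    The distribution is truncated at the smallest offset K whose cumulative
    abundance reaches ``1 - truncation_threshold`` and renormalized to sum
    to 1.
    """
    if not 0.0 < truncation_threshold < 1.0:
        raise ValueError(
            f"truncation_threshold must be in (0, 1), got {truncation_threshold}"
        )
    if len(comp) == 0:
        raise ValueError("composition is empty")
    abundances = _pattern_cached(
        tuple(sorted(comp.items())), float(truncation_threshold)
    )
    return IsotopePattern(abundances, comp.monoisotopic_mass)


def cluster_mz_grid(
    pattern: IsotopePattern, neutral_mass: float, charge: int
) -> list[tuple[float, float]]:
    """Centroid (m/z, relative abundance) positions of an isotope cluster.

    Peak k sits at ``(neutral_mass + k * 1.0033548 + charge * m_H+) /
    charge``, so adjacent peaks are spaced by 1.0033548/charge -- the
    spacing used to read charge states off measured clusters.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return [
        ((neutral_mass + k * NEUTRON_SPACING + charge * PROTON) / charge, abundance)
        for k, abundance in enumerate(pattern.abundances)
    ]
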