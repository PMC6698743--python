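"""Coulombic charge partitioning on an extended RNA chain.

At elevated internal energy a multiply protonated RNA ion is modeled as a
fully extended chain of L residues at unit spacing carrying n unit-charge
protons on residue positions 1..L.  Intramolecular proton transfer is
assumed to relax the placement to the minimum of the dimensionless Coulomb
energy  E = sum_{i<j} 1 / |p_i - p_j|.  The minimum-energy placements then
predict how the precursor charge divides between complementary c/y
fragments: a c_i fragment keeps the protons at positions <= i, the
complementary y_{L-i} fragment keeps the rest, so predicted charges at
complementary indices always sum to n.

The model is deliberately minimal (discrete residue positions, vacuum 1/r,
no dielectric screening, equal weighting of degenerate minima); predictions
are model-dependent trends, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ChargeConfiguration",
    "charge_profile",
    "coulomb_energy",
    "hill_climb_charge_sites",
    "optimal_charge_sites",
    "predicted_fragment_charge",
]


@dataclass(frozen=True)
class ChargeConfiguration:
    """Proton positions (strictly increasing, 1-based) and their Coulomb
    energy in units of charge^2/spacing."""

    positions: tuple[int, ...]
    energy: float

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")


def coulomb_energy(positions) -> float:
    """Sum of 1/|p_i - p_j| over all proton pairs (0 for a single proton)."""
    positions = sorted(positions)
    return sum(
        1.0 / (b - a) for a, b in combinations(positions, 2)
    )


@lru_cache(maxsize=256)
def _optimal_cached(L: int, n: int, tie_tolerance: float) -> tuple[ChargeConfiguration, ...]:
    if n == 1:
        # Any single position has zero energy; all L placements are degenerate.
        return tuple(ChargeConfiguration((p,), 0.0) for p in range(1, L + 1))
    configs = np.array(list(combinations(range(1, L + 1), n)), dtype=float)
    diffs = configs[:, :, None] - configs[:, None, :]
    iu = np.triu_indices(n, k=1)
    energies = (1.0 / np.abs(diffs[:, iu[0], iu[1]])).sum(axis=1)
    best = energies.min()
    winners = np.flatnonzero(energies <= best + tie_tolerance)
    return tuple(
        ChargeConfiguration(tuple(int(p) for p in configs[w]), float(energies[w]))
        for w in winners
    )


def optimal_charge_sites(
    L: int, n: int, tie_tolerance: float = 1e-9
) -> list[ChargeConfiguration]:
    """All minimum-energy placements of n protons on L chain positions.

    Exhaustive search over all C(L, n) placements (intended for L <= 30);
    degenerate minima within ``tie_tolerance`` of the optimum are all
    returned, sorted by position tuple.
    """
    if n < 1:
        raise ValueError(f"proton count must be >= 1, got {n}")
    if L < 1:
        raise ValueError(f"chain length must be >= 1, got {L}")
    if n > L:
        raise ValueError(f"cannot place {n} protons on {L} positions")
    return sorted(_optimal_cached(L, n, tie_tolerance), key=lambda c: c.positions)


def predicted_fragment_charge(configs, series: str, index: int, L: int) -> float:
    """Expected fragment charge under equal weighting of degenerate minima.

    For c at index i: mean count of protons at positions <= i.  For y at
    index j: mean count at positions > L - j.  Complementary predictions
    (c_i and y_{L-i}) sum to the precursor proton count by construction.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("no charge configurations given")
    if series == "c":
        if not 1 <= index <= L - 1:
            raise ValueError(f"c index must be in 1..{L - 1}, got {index}")
        cut = index
        counts = [sum(1 for p in c.positions if p <= cut) for c in configs]
    elif series == "y":
        if not 1 <= index <= L - 1:
            raise ValueError(f"y index must be in 1..{L - 1}, got {index}")
        cut = L - index
        counts = [sum(1 for p in c.positions if p > cut) for c in configs]
    else:
        raise ValueError(f"series must be 'c' or 'y', got {series!r}")
    return float(np.mean(counts))


def charge_profile(L: int, n: int) -> pd.DataFrame:
    """Predicted c/y fragment charges across all cleavage sites.

    Columns: site (1..L-1), c_charge (fragment c_site), y_charge (fragment
    y_{L-site}); each row's charges sum to n.
    """
    configs = optimal_charge_sites(L, n)
    rows = [
        {
            "site": site,
            "c_charge": predicted_fragment_charge(configs, "c", site, L),
            "y_charge": predicted_fragment_charge(configs, "y", L - site, L),
        }
        for site in range(1, L)
    ]
    return pd.DataFrame(rows)


def hill_climb_charge_sites(
    L: int, n: int, restarts: int = 20, seed: int = 0
) -> ChargeConfiguration:
    """Heuristic fast path: repeated single-proton moves until no move
    lowers the energy, best over random restarts.

    Agrees with the exhaustive optimum for the chain lengths used here; it
    exists for larger problems and as an independent check on the search.
    """
    if not 1 <= n <= L:
        raise ValueError(f"need 1 <= n <= L, got n={n}, L={L}")
    rng = np.random.default_rng(seed)
    best_positions: tuple[int, ...] | None = None
    best_energy = np.inf
    for _ in range(max(1, restarts)):
        positions = set(rng.choice(np.arange(1, L + 1), size=n, replace=False).tolist())
        energy = coulomb_energy(positions)
        improved = True
        while improved:
            improved = False
            for p in sorted(positions):
                for q in range(1, L + 1):
                    if q in positions:
                        continue
                    trial = (positions - {p}) | {q}
                    trial_energy = coulomb_energy(trial)
                    if trial_energy < energy - 1e-12:
                        positions, energy = trial, trial_energy
                        improved = True
        if energy < best_energy:
            best_positions, best_energy = tuple(sorted(positions)), energy
    return ChargeConfiguration(best_positions, best_energy)
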