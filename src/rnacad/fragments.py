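"""Theoretical backbone fragment ions of RNA under low-energy CAD.

Low-energy collisional activation of protonated RNA cleaves the
phosphodiester backbone into complementary 5'-side and 3'-side products.
Following the standard nucleic-acid fragment nomenclature, the 5'-side
series are a/b/c/d and the 3'-side series are w/x/y/z; the dominant CAD
channel yields ``c`` ions carrying a 2',3'-cyclic phosphate and ``y`` ions
carrying a 5'-OH, so that neutral(c_i) + neutral(y_{L-i}) equals the
precursor neutral mass M exactly.

Cleavage-site convention: site ``i`` (1..L-1) is the phosphodiester linkage
between residues ``i`` and ``i+1``; ``c_i`` contains the first ``i``
residues and pairs with ``y_{L-i}``.

Neutral losses of water and of a neutral nucleobase BH are tracked at the
composition level ("which base was lost", never "from which position",
since a mass spectrum cannot localize the loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .rna_chem import (
    HPO3,
    PROTON,
    WATER,
    Composition,
    ModifiedRNASequence,
    mz as _mz,
)

__all__ = [
    "FragmentSpecies",
    "MechanisticPlausibilityWarning",
    "enumerate_fragments",
    "fragment_composition",
    "fragment_neutral_mass",
    "make_fragment",
    "precursor_species",
    "write_fragment_table",
]

SERIES_5PRIME = ("a", "b", "c", "d")
SERIES_3PRIME = ("w", "x", "y", "z")
ALL_SERIES = SERIES_5PRIME + SERIES_3PRIME


class MechanisticPlausibilityWarning(UserWarning):
    """A c fragment was requested at a site whose 5'-flanking residue lacks
    the 2'-OH nucleophile; annotation remains possible but the species is
    not expected from the 2'-OH attack mechanism."""


@dataclass(frozen=True, order=True)
class FragmentSpecies:
    """One theoretical ion: series, cleavage site, neutral losses, charge.

    ``losses`` is a sorted tuple of tokens: ``'H2O'``, ``'base:<code>'``
    (neutral nucleobase BH of residue ``<code>``) or ``'baseH:<code>'``
    (protonated nucleobase, removes one charge).  ``site`` is None for
    precursor species.
    """

    series: str
    site: int | None
    losses: tuple[str, ...]
    charge: int
    neutral_mass: float
    mz: float
    composition: Composition = None

    def key(self) -> tuple:
        return (self.series, self.site, self.losses, self.charge)

    @property
    def loss_label(self) -> str:
        return "+".join(self.losses) if self.losses else "-"


def _check_site(seq: ModifiedRNASequence, site: int) -> None:
    if not 1 <= site <= len(seq) - 1:
        raise ValueError(f"site must be in 1..{len(seq) - 1}, got {site}")


def fragment_composition(
    seq: ModifiedRNASequence,
    series: str,
    site: int,
    cyclic_c: bool = True,
) -> Composition:
    """Elemental composition of the neutral backbone fragment.

    With ``cyclic_c`` (default) the c ion is the 2',3'-cyclic phosphate
    product and complementary pairs sum exactly to the precursor
    composition (a+w = b+x = c+y = d+z = M).  ``cyclic_c=False`` selects
    the linear 3'-phosphate convention used by some tools, for which
    c + y = M + H2O.
    """
    _check_site(seq, site)
    if series in SERIES_5PRIME:
        if series == "c" and not seq.definition(site).has_2prime_OH:
            warnings.warn(
                f"c{site}: residue {seq.residues[site - 1]!r} at position "
                f"{site} lacks a 2'-OH, cleavage on its 3'-side is not "
                "expected mechanistically",
                MechanisticPlausibilityWarning,
                stacklevel=2,
            )
        prefix = seq.subsequence(0, site, five_prime=seq.five_prime).composition()
        if series == "a":
            return prefix - WATER
        if series == "b":
            return prefix
        if series == "c":
            comp = prefix + HPO3
            return comp - WATER if cyclic_c else comp
        return prefix + HPO3  # d
    if series in SERIES_3PRIME:
        j = site  # fragment length index for 3'-side series
        suffix = seq.subsequence(
            len(seq) - j, len(seq), three_prime=seq.three_prime
        ).composition()
        if series == "y":
            return suffix
        if series == "z":
            return suffix - WATER
        if series == "w":
            return suffix + HPO3
        return suffix + HPO3 - WATER  # x
    raise ValueError(f"unknown fragment series {series!r}")


def fragment_neutral_mass(
    seq: ModifiedRNASequence, series: str, site: int, cyclic_c: bool = True
) -> float:
    """Neutral monoisotopic mass (Da) of the backbone fragment."""
    return fragment_composition(seq, series, site, cyclic_c=cyclic_c).monoisotopic_mass


def _loss_composition(
    seq: ModifiedRNASequence, losses: tuple[str, ...]
) -> tuple[Composition, int]:
    """Total composition removed by ``losses`` and the charge decrement."""
    removed = Composition()
    charge_drop = 0
    for token in losses:
        if token == "H2O":
            removed = removed + WATER
        elif token.startswith("base:") or token.startswith("baseH:"):
            prefix, code = token.split(":", 1)
            removed = removed + seq.registry[code].base
            if prefix == "baseH":
                charge_drop += 1
        else:
            raise ValueError(f"unknown loss token {token!r}")
    return removed, charge_drop


def make_fragment(
    seq: ModifiedRNASequence,
    series: str,
    site: int | None,
    losses: tuple[str, ...] = (),
    charge: int = 1,
    cyclic_c: bool = True,
) -> FragmentSpecies:
    """Build a :class:`FragmentSpecies` with exact composition arithmetic."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    losses = tuple(sorted(losses))
    if series == "precursor":
        comp = seq.composition()
    else:
        if site is None:
            raise ValueError(f"series {series!r} requires a cleavage site")
        comp = fragment_composition(seq, series, site, cyclic_c=cyclic_c)
    removed, charge_drop = _loss_composition(seq, losses)
    if charge_drop:
        raise ValueError(
            "protonated-base losses are precursor channels; use precursor_species"
        )
    comp = comp - removed
    neutral = comp.monoisotopic_mass
    return FragmentSpecies(
        series=series,
        site=site,
        losses=losses,
        charge=charge,
        neutral_mass=neutral,
        mz=_mz(neutral, charge),
        composition=comp,
    )


def precursor_species(
    seq: ModifiedRNASequence,
    n: int,
    losses: tuple[str, ...] = (),
) -> FragmentSpecies:
    """Precursor-derived species of the (M+nH)^n+ ion.

    Supports neutral water/base losses (charge kept) and protonated-base
    losses ``'baseH:<code>'`` (one charge leaves with the base, so the
    product of a 4+ precursor losing protonated guanine is labeled
    (M+3H-guanine)3+ and its m/z is (M - m_BH + 3 m_H+)/3).
    """
    if n < 1:
        raise ValueError(f"charge must be >= 1, got {n}")
    losses = tuple(sorted(losses))
    removed, charge_drop = _loss_composition(seq, losses)
    charge = n - charge_drop
    if charge < 1:
        raise ValueError(
            f"losses remove {charge_drop} charge(s) from a {n}+ precursor"
        )
    comp = seq.composition() - removed
    neutral = comp.monoisotopic_mass
    return FragmentSpecies(
        series="precursor",
        site=None,
        losses=losses,
        charge=charge,
        neutral_mass=neutral,
        mz=_mz(neutral, charge),
        composition=comp,
    )


def _fragment_residues(seq: ModifiedRNASequence, series: str, site: int) -> tuple[str, ...]:
    if series in SERIES_5PRIME:
        return seq.residues[:site]
    return seq.residues[len(seq) - site :]


def enumerate_fragments(
    seq: ModifiedRNASequence,
    series_set=("c", "y"),
    max_h2o_losses: int = 1,
    allow_base_loss: bool = True,
    charge_range=(1, 2, 3),
    cyclic_c: bool = True,
) -> list[FragmentSpecies]:
    """Enumerate every (series, site, loss-combination, charge) once.

    Base losses are composition-level: one variant per *distinct* residue
    code contained in the fragment.  When ``'precursor'`` is in
    ``series_set``, intact, water-loss and neutral base-loss precursor
    species are emitted at each requested charge as well.

    The output is duplicate-free and sorted by (series, site, losses,
    charge) for stable diffs.
    """
    series_set = tuple(series_set)
    if not series_set:
        raise ValueError("series_set must not be empty")
    charges = sorted(set(int(z) for z in charge_range))
    if any(z < 1 for z in charges):
        raise ValueError("charges must be >= 1")

    species: list[FragmentSpecies] = []
    for series in series_set:
        if series == "precursor":
            continue
        if series not in ALL_SERIES:
            raise ValueError(f"unknown fragment series {series!r}")
        for site in range(1, len(seq)):
            loss_sets: list[tuple[str, ...]] = []
            contained = sorted(set(_fragment_residues(seq, series, site)))
            for n_h2o in range(max_h2o_losses + 1):
                h2o = ("H2O",) * n_h2o
                loss_sets.append(h2o)
                if allow_base_loss:
                    loss_sets.extend(h2o + (f"base:{code}",) for code in contained)
            for losses in loss_sets:
                for charge in charges:
                    species.append(
                        make_fragment(
                            seq, series, site, losses, charge, cyclic_c=cyclic_c
                        )
                    )
    if "precursor" in series_set:
        contained = sorted(set(seq.residues))
        loss_sets = [(), ("H2O",)]
        if allow_base_loss:
            loss_sets.extend((f"base:{code}",) for code in contained)
        for losses in loss_sets:
            for charge in charges:
                species.append(precursor_species(seq, charge, losses))

    keys = [sp.key() for sp in species]
    if len(keys) != len(set(keys)):
        raise AssertionError("duplicate fragment keys in enumeration")
    return sorted(species, key=lambda sp: (sp.series, sp.site or 0, sp.losses, sp.charge))


def write_fragment_table(species, path) -> None:
    """Write a TSV fragment table with a stable column order."""
    with open(path, "w") as handle:
        handle.write("series\tsite\tlosses\tcharge\tneutral_mass\tmz\n")
        for sp in species:
            site = "" if sp.site is None else sp.site
            handle.write(
                f"{sp.series}\t{site}\t{sp.loss_label}\t{sp.charge}\t"
                f"{sp.neutral_mass:.3f}\t{sp.mz:.4f}\n"
            )
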