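"""Elemental compositions, residue registry and exact masses for modified RNA.

This module is the mass engine for the rest of the package.  It represents
oligoribonucleotides as ordered lists of registered residue codes (the four
standard ribonucleosides plus modified analogs such as the deaza-adenosines
c1A/c3A/c7A/c13A and 2'-deoxyadenosine dA), derives exact elemental
compositions, and computes monoisotopic neutral masses and m/z values for
multiply protonated ions.

Conventions
-----------
* A sequence of length L with 5'-OH and 3'-OH termini has composition
  ``sum(nucleosides) + (L-1)*HPO3 - (L-1)*H2O`` (one phosphodiester bridge
  per internal linkage).  Phosphate termini add one HPO3 each.
* Monoisotopic atomic masses are hard-coded IUPAC/CODATA values with at
  least six decimals so that 15-mer masses are reliable to the third
  decimal place.
* Positive-ion m/z follows ``(M + n * m_proton) / n``.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field

__all__ = [
    "Composition",
    "CompositionError",
    "ModifiedRNASequence",
    "ResidueDefinition",
    "ResidueRegistry",
    "SequenceParseError",
    "UnknownResidueError",
    "default_registry",
    "monoisotopic_mass",
    "mz",
    "neutral_mass_from_mz",
    "parse_sequence",
    "read_sequences",
    "residue_mass_delta",
]

#: Monoisotopic atomic masses (Da).
MONOISOTOPIC = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Isotope-abundance-weighted (average) atomic masses, convenience only.
AVERAGE = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
}

#: Mass of the proton (Da), used for (M+nH)^n+ m/z arithmetic.
PROTON = 1.00727646


class CompositionError(ValueError):
    """Raised when composition arithmetic would produce a negative count."""


class UnknownResidueError(KeyError):
    """Raised when a residue code is not present in the registry."""


class SequenceParseError(ValueError):
    """Raised when sequence notation cannot be parsed."""


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class Composition(Mapping):
    """Immutable map of chemical element symbol to non-negative count.

    Supports element-wise ``+`` and ``-`` (subtraction raises
    :class:`CompositionError` on underflow) and scalar multiplication.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}, kwargs):
            for element, count in source.items():
                count = int(count)
                if count < 0:
                    raise CompositionError(
                        f"negative count {count} for element {element!r}"
                    )
                if count:
                    merged[element] = merged.get(element, 0) + count
        self._counts = merged

    @classmethod
    def from_formula(cls, formula: str) -> "Composition":
        """Parse a molecular formula such as ``'C10H13N5O4'``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise CompositionError(
                    f"cannot parse formula {formula!r} at offset {pos}"
                )
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula) or not counts:
            raise CompositionError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element) -> bool:
        return element in self._counts

    def __add__(self, other: "Composition") -> "Composition":
        if not isinstance(other, Composition):
            return NotImplemented
        counts = dict(self._counts)
        for element, count in other._counts.items():
            counts[element] = counts.get(element, 0) + count
        return Composition(counts)

    def __sub__(self, other: "Composition") -> "Composition":
        if not isinstance(other, Composition):
            return NotImplemented
        counts = dict(self._counts)
        for element, count in other._counts.items():
            remaining = counts.get(element, 0) - count
            if remaining < 0:
                raise CompositionError(
                    f"subtraction underflow for element {element!r}: "
                    f"{counts.get(element, 0)} - {count}"
                )
            counts[element] = remaining
        return Composition(counts)

    def __mul__(self, factor: int) -> "Composition":
        if not isinstance(factor, int):
            return NotImplemented
        if factor < 0:
            raise CompositionError("cannot multiply composition by a negative factor")
        return Composition({el: c * factor for el, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if isinstance(other, Composition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def contains(self, other: "Composition") -> bool:
        """True if ``other`` is an element-wise sub-composition of self."""
        return all(self[el] >= count for el, count in other.items())

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC[el] * c for el, c in sorted(self._counts.items()))

    @property
    def average_mass(self) -> float:
        return sum(AVERAGE[el] * c for el, c in sorted(self._counts.items()))

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(self._counts, key=lambda el: (el != "C", el != "H", el))
        return "".join(
            f"{el}{self._counts[el]}" if self._counts[el] != 1 else el for el in order
        )

    def __repr__(self) -> str:
        return f"Composition({self.formula()!r})"


WATER = Composition.from_formula("H2O")
HPO3 = Composition.from_formula("HPO3")


@dataclass(frozen=True)
class ResidueDefinition:
    """One registered residue.

    Parameters
    ----------
    code:
        Short unique key used in sequence notation (e.g. ``'A'``, ``'c3A'``).
    nucleoside:
        Elemental composition of the free nucleoside (base + sugar).
    base:
        Composition of the neutral nucleobase BH released in base-loss
        fragmentation channels.
    has_2prime_OH:
        False for 2'-deoxy residues, which cannot supply the 2'-OH
        nucleophile required for backbone cleavage on their 3'-side.
    basic_n3:
        True for adenine-type residues whose ring nitrogen N3 is available
        for protonation (A, c1A, c7A, dA).  Protonated N3 can hydrogen-bond
        to the 5'-flanking phosphodiester group and promote its cleavage;
        the 3-deaza analogs (c3A, c13A) lack the site.  Cytidine's N3 is
        excluded because its protonated conformers do not engage the
        backbone this way.
    """

    code: str
    nucleoside: Composition
    base: Composition
    has_2prime_OH: bool = True
    basic_n3: bool = False

    def __post_init__(self):
        if not self.nucleoside.contains(self.base):
            raise CompositionError(
                f"base composition of {self.code!r} is not a sub-composition "
                "of its nucleoside"
            )


class ResidueRegistry:
    """Mutable collection of :class:`ResidueDefinition`, keyed by code."""

    def __init__(self):
        self._residues: dict[str, ResidueDefinition] = {}
        self._aliases: dict[str, str] = {}

    def register(
        self,
        code: str,
        nucleoside: str | Composition,
        base: str | Composition,
        *,
        has_2prime_OH: bool = True,
        basic_n3: bool = False,
    ) -> ResidueDefinition:
        if code in self._residues or code in self._aliases:
            raise ValueError(f"residue code {code!r} already registered")
        if isinstance(nucleoside, str):
            nucleoside = Composition.from_formula(nucleoside)
        if isinstance(base, str):
            base = Composition.from_formula(base)
        definition = ResidueDefinition(
            code, nucleoside, base, has_2prime_OH=has_2prime_OH, basic_n3=basic_n3
        )
        self._residues[code] = definition
        return definition

    def alias(self, alias: str, target: str) -> None:
        if alias in self._residues or alias in self._aliases:
            raise ValueError(f"residue code {alias!r} already registered")
        self.resolve(target)
        self._aliases[alias] = target

    def resolve(self, code: str) -> str:
        if code in self._residues:
            return code
        if code in self._aliases:
            return self._aliases[code]
        raise UnknownResidueError(code)

    def __getitem__(self, code: str) -> ResidueDefinition:
        return self._residues[self.resolve(code)]

    def __contains__(self, code: str) -> bool:
        return code in self._residues or code in self._aliases

    def __iter__(self):
        return iter(self._residues)

    def __len__(self) -> int:
        return len(self._residues)

    def copy(self) -> "ResidueRegistry":
        new = ResidueRegistry()
        new._residues = dict(self._residues)
        new._aliases = dict(self._aliases)
        return new

    def update_from_config(self, config: Mapping) -> None:
        """Register residues from a config mapping.

        Expected shape::

            {"residues": [{"code": "m6A", "nucleoside": "C11H15N5O4",
                           "base": "C6H7N5", "has_2prime_OH": true,
                           "basic_n3": true}, ...]}
        """
        for entry in config.get("residues", []):
            self.register(
                entry["code"],
                entry["nucleoside"],
                entry["base"],
                has_2prime_OH=bool(entry.get("has_2prime_OH", True)),
                basic_n3=bool(entry.get("basic_n3", False)),
            )


def default_registry() -> ResidueRegistry:
    """Registry with A, C, G, U, the deaza-adenosines and dA.

    Deaza compositions are N-to-CH substitutions of adenosine (each shifts
    the monoisotopic mass by -0.995249 Da); dA is adenosine minus one
    oxygen.
    """
    reg = ResidueRegistry()
    reg.register("A", "C10H13N5O4", "C5H5N5", basic_n3=True)
    reg.register("C", "C9H13N3O5", "C4H5N3O")
    reg.register("G", "C10H13N5O5", "C5H5N5O")
    reg.register("U", "C9H12N2O6", "C4H4N2O2")
    # 1-deaza / 7-deaza keep N3; 3-deaza and 1,3-dideaza remove it.
    reg.register("c1A", "C11H14N4O4", "C6H6N4", basic_n3=True)
    reg.register("c3A", "C11H14N4O4", "C6H6N4", basic_n3=False)
    reg.register("c7A", "C11H14N4O4", "C6H6N4", basic_n3=True)
    reg.register("c13A", "C12H15N3O4", "C7H7N3", basic_n3=False)
    reg.alias("c1,3A", "c13A")
    reg.register("dA", "C10H13N5O3", "C5H5N5", has_2prime_OH=False, basic_n3=True)
    return reg


DEFAULT_REGISTRY = default_registry()

_TERMINI = ("OH", "phosphate")


@dataclass(frozen=True)
class ModifiedRNASequence:
    """Ordered residue codes with terminus chemistry.

    ``five_prime`` / ``three_prime`` are ``'OH'`` or ``'phosphate'``; the
    study sequences are all synthesized 5'-OH to 3'-OH.
    """

    residues: tuple[str, ...]
    five_prime: str = "OH"
    three_prime: str = "OH"
    registry: ResidueRegistry = field(
        default=None, compare=False, repr=False, hash=False
    )

    def __post_init__(self):
        if self.registry is None:
            object.__setattr__(self, "registry", DEFAULT_REGISTRY)
        if not self.residues:
            raise ValueError("sequence must contain at least one residue")
        if self.five_prime not in _TERMINI or self.three_prime not in _TERMINI:
            raise ValueError(f"termini must be one of {_TERMINI}")
        resolved = tuple(self.registry.resolve(code) for code in self.residues)
        object.__setattr__(self, "residues", resolved)

    def __len__(self) -> int:
        return len(self.residues)

    def definition(self, position: int) -> ResidueDefinition:
        """Residue definition at 1-based ``position``."""
        return self.registry[self.residues[position - 1]]

    def composition(self) -> Composition:
        total = Composition()
        for code in self.residues:
            total = total + self.registry[code].nucleoside
        n_bridges = len(self.residues) - 1
        total = total + HPO3 * n_bridges
        if self.five_prime == "phosphate":
            total = total + HPO3
        if self.three_prime == "phosphate":
            total = total + HPO3
        return total - WATER * n_bridges

    def monoisotopic_mass(self) -> float:
        return self.composition().monoisotopic_mass

    def average_mass(self) -> float:
        return self.composition().average_mass

    def subsequence(
        self,
        start: int,
        stop: int,
        five_prime: str = "OH",
        three_prime: str = "OH",
    ) -> "ModifiedRNASequence":
        """Residues ``start:stop`` (0-based slice) as a new sequence."""
        return ModifiedRNASequence(
            self.residues[start:stop],
            five_prime=five_prime,
            three_prime=three_prime,
            registry=self.registry,
        )

    def notation(self) -> str:
        """Round-trippable sequence notation (brackets for long codes)."""
        return "".join(
            code if len(code) == 1 else f"[{code}]" for code in self.residues
        )


def parse_sequence(
    text: str,
    five_prime: str = "OH",
    three_prime: str = "OH",
    registry: ResidueRegistry | None = None,
) -> ModifiedRNASequence:
    """Parse sequence notation into a :class:`ModifiedRNASequence`.

    One residue per one-letter code or per ``[bracketed]`` multi-character
    token; whitespace is ignored (study sequences are printed in groups of
    five); codes are case-sensitive.

    Raises
    ------
    SequenceParseError
        Naming the offending token and its 1-based residue position.
    """
    registry = registry or DEFAULT_REGISTRY
    codes: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise SequenceParseError(
                    f"unterminated '[' at residue position {len(codes) + 1}"
                )
            token = text[i + 1 : end]
            i = end + 1
        else:
            token = ch
            i += 1
        position = len(codes) + 1
        try:
            codes.append(registry.resolve(token))
        except UnknownResidueError:
            raise SequenceParseError(
                f"unknown residue code {token!r} at position {position}"
            ) from None
    if not codes:
        raise SequenceParseError("empty sequence")
    return ModifiedRNASequence(
        tuple(codes), five_prime=five_prime, three_prime=three_prime, registry=registry
    )


def read_sequences(
    path, registry: ResidueRegistry | None = None
) -> dict[str, ModifiedRNASequence]:
    """Read a plain-text sequence file.

    One sequence per line, either bare notation or ``name<TAB>notation``;
    blank lines and ``#`` comments are skipped.  Unnamed sequences are
    keyed ``seq1``, ``seq2``, ...
    """
    sequences: dict[str, ModifiedRNASequence] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, notation = line.split("\t", 1)
                name = name.strip()
            else:
                name, notation = f"seq{len(sequences) + 1}", line
            try:
                sequences[name] = parse_sequence(notation, registry=registry)
            except SequenceParseError as exc:
                raise SequenceParseError(f"line {lineno}: {exc}") from None
    return sequences


def monoisotopic_mass(obj) -> float:
    """Monoisotopic mass of a composition or sequence, in Da."""
    if isinstance(obj, Composition):
        return obj.monoisotopic_mass
    if isinstance(obj, ModifiedRNASequence):
        return obj.monoisotopic_mass()
    raise TypeError(f"cannot compute mass of {type(obj).__name__}")


def residue_mass_delta(
    code_a: str, code_b: str, registry: ResidueRegistry | None = None
) -> float:
    """Signed monoisotopic nucleoside mass difference a - b (Da)."""
    registry = registry or DEFAULT_REGISTRY
    return (
        registry[code_a].nucleoside.monoisotopic_mass
        - registry[code_b].nucleoside.monoisotopic_mass
    )


def mz(neutral_mass: float, n: int) -> float:
    """m/z of the (M+nH)^n+ ion of a neutral of mass ``neutral_mass``."""
    if n < 1:
        raise ValueError(f"charge must be >= 1, got {n}")
    return (neutral_mass + n * PROTON) / n


def neutral_mass_from_mz(mz_value: float, n: int) -> float:
    """Inverse of :func:`mz`."""
    if n < 1:
        raise ValueError(f"charge must be >= 1, got {n}")
    return mz_value * n - n * PROTON
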