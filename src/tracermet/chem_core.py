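"""Elemental formulas, isotope abundance tables and isotopologue distributions.

This module is the chemical foundation of natural-abundance correction for
GC-MS stable-isotope tracing.  A measured fragment of a derivatized
metabolite (MOX/TBDMS chemistry adds C, H, N, O and Si atoms to the analyte)
has a nominal-mass isotopologue distribution determined entirely by its
elemental composition and the terrestrial isotope abundances of those
elements.  :func:`natural_distribution` computes that distribution exactly by
per-element multinomial expansion combined by discrete convolution, at unit
(nominal) mass resolution — fine isotope structure is collapsed, matching
quadrupole GC-MS data.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections.abc import Mapping
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "FragmentSpec",
    "IsotopeTable",
    "natural_distribution",
    "parse_formula",
    "read_fragment_library",
    "example_fragment_library",
]

#: Element symbols accepted in formulas (main-group and common hetero atoms;
#: covers everything occurring in derivatized metabolite fragments).
KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Cr Mn Fe Co Ni Cu Zn "
    "As Se Br Mo I W".split()
)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or chemically invalid elemental formula."""


@dataclasses.dataclass(frozen=True)
class ElementalFormula:
    """Element → atom-count map for a measured (derivatized) fragment.

    Counts are non-negative integers; unknown element symbols are rejected
    at construction.  Addition sums counts element-wise.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.counts.items():
            if element not in KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise FormulaError(
                    f"atom count for {element} must be a non-negative integer, got {count!r}"
                )
            if count > 0:
                clean[element] = int(count)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalFormula(merged)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def remove(self, element: str, count: int) -> "ElementalFormula":
        """Return a copy with ``count`` atoms of ``element`` removed."""
        have = self[element]
        if count > have:
            raise FormulaError(
                f"cannot remove {count} {element} atoms from a formula with {have}"
            )
        out = dict(self.counts)
        out[element] = have - count
        return ElementalFormula(out)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        # Hill order: C first, H second, remaining elements alphabetical.
        parts = []
        for element in ("C", "H"):
            if self[element]:
                parts.append(element + (str(self[element]) if self[element] > 1 else ""))
        for element in sorted(set(self.counts) - {"C", "H"}):
            parts.append(element + (str(self[element]) if self[element] > 1 else ""))
        return "".join(parts)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C11H26NO2Si"``.

    Counts default to 1 (``"CO2"`` → C:1, O:2).  Repeated element symbols
    accumulate.  Raises :class:`FormulaError` naming the offending span for
    malformed input or unknown symbols.
    """
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos:
            raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
        element, digits = match.groups()
        if element not in KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return ElementalFormula(counts)


@dataclasses.dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope abundances at unit mass resolution.

    For each element a sorted tuple of ``(mass_shift, abundance)`` pairs,
    mass shifts in integer Da relative to the lightest isotope.  Abundances
    must sum to 1 within 1e-9 and shifts must increase strictly from 0.
    """

    isotopes: Mapping[str, tuple[tuple[int, float], ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[tuple[int, float], ...]] = {}
        for element, pairs in self.isotopes.items():
            pairs = tuple((int(s), float(a)) for s, a in pairs)
            shifts = [s for s, _ in pairs]
            if not shifts or shifts[0] != 0 or any(
                b <= a for a, b in zip(shifts, shifts[1:])
            ):
                raise ValueError(
                    f"{element}: mass shifts must increase strictly from 0, got {shifts}"
                )
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{element}: abundances sum to {total!r}, expected 1")
            if any(a < 0 for _, a in pairs):
                raise ValueError(f"{element}: negative abundance")
            clean[element] = pairs
        object.__setattr__(self, "isotopes", clean)

    def atom_vector(self, element: str) -> np.ndarray:
        """Dense single-atom shift distribution for ``element``."""
        if element not in self.isotopes:
            raise KeyError(
                f"element {element!r} has no isotope data in this table"
            )
        pairs = self.isotopes[element]
        vec = np.zeros(pairs[-1][0] + 1)
        for shift, abundance in pairs:
            vec[shift] = abundance
        return vec

    @classmethod
    def from_tsv(cls, path) -> "IsotopeTable":
        """Load from a TSV with columns ``element, mass_shift, abundance``."""
        df = pd.read_csv(path, sep="\t")
        grouped: dict[str, list[tuple[int, float]]] = {}
        for row in df.itertuples(index=False):
            grouped.setdefault(str(row.element), []).append(
                (int(row.mass_shift), float(row.abundance))
            )
        return cls({e: tuple(sorted(v)) for e, v in grouped.items()})

    @classmethod
    def default(cls) -> "IsotopeTable":
        """Standard terrestrial abundances for C, H, N, O, Si and S."""
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            with resources.as_file(
                resources.files("tracermet.data") / "isotopes.tsv"
            ) as path:
                _DEFAULT_TABLE = cls.from_tsv(path)
        return _DEFAULT_TABLE


_DEFAULT_TABLE: IsotopeTable | None = None


def _full_distribution(formula: ElementalFormula, isotopes: IsotopeTable) -> np.ndarray:
    """Untruncated isotopologue distribution of ``formula`` (sums to 1)."""
    dist = np.ones(1)
    for element, count in formula.counts.items():
        atom = isotopes.atom_vector(element)
        # multinomial expansion of one element = count-fold self-convolution
        for _ in range(count):
            dist = np.convolve(dist, atom)
    return dist


def natural_distribution(
    formula: ElementalFormula,
    isotopes: IsotopeTable | None = None,
    max_shift: int | None = None,
) -> np.ndarray:
    """Probability of nominal mass shifts 0..``max_shift`` for ``formula``.

    Computed by per-element multinomial expansion combined by discrete
    convolution; entry 0 equals the product over atoms of the
    lightest-isotope abundance.  The distribution is truncated to
    ``max_shift + 1`` entries; truncated tail mass above 1e-6 is logged.

    Parameters
    ----------
    formula:
        Elemental composition of the full (derivatized) fragment.
    isotopes:
        Abundance table; defaults to standard terrestrial values.
    max_shift:
        Highest mass shift retained.  Defaults to the full support of the
        distribution (no truncation).
    """
    if isotopes is None:
        isotopes = IsotopeTable.default()
    full = _full_distribution(formula, isotopes)
    if max_shift is None:
        return full
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    out = np.zeros(max_shift + 1)
    upto = min(len(full), max_shift + 1)
    out[:upto] = full[:upto]
    tail = float(full[upto:].sum())
    if tail > 1e-6:
        logger.warning(
            "truncation of %s at shift %d discards %.3g probability mass",
            formula, max_shift, tail,
        )
    return out


@dataclasses.dataclass(frozen=True)
class FragmentSpec:
    """A measured GC-MS fragment of a metabolite.

    ``n_carbons`` is the number of carbons of the *parent metabolite*
    contained in the fragment — the carbons a ¹³C tracer can label, and the
    ``n`` of the total-contribution formula.  ``fragment_formula`` is the
    full derivatized composition including MOX/TBDMS groups.
    """

    metabolite: str
    fragment_formula: ElementalFormula
    n_carbons: int
    base_mz: int = 0

    def __post_init__(self) -> None:
        total_c = self.fragment_formula["C"]
        if not 1 <= self.n_carbons <= total_c:
            raise ValueError(
                f"{self.metabolite}: n_carbons={self.n_carbons} outside "
                f"[1, {total_c}] for formula {self.fragment_formula}"
            )


def read_fragment_library(path) -> dict[str, FragmentSpec]:
    """Read a fragment library TSV (metabolite, fragment_formula, n_carbons, base_mz)."""
    df = pd.read_csv(path, sep="\t")
    library: dict[str, FragmentSpec] = {}
    for row in df.itertuples(index=False):
        spec = FragmentSpec(
            metabolite=str(row.metabolite),
            fragment_formula=parse_formula(str(row.fragment_formula)),
            n_carbons=int(row.n_carbons),
            base_mz=int(getattr(row, "base_mz", 0)),
        )
        library[spec.metabolite] = spec
    return library


def example_fragment_library() -> dict[str, FragmentSpec]:
    """The packaged example set of MOX/TBDMS fragments (user-editable TSV)."""
    with resources.as_file(
        resources.files("tracermet.data") / "fragments_example.tsv"
    ) as path:
        return read_fragment_library(path)
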