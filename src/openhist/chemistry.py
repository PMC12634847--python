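"""Elemental-composition arithmetic, the modification registry, and
isobaric delta-mass decomposition.

Histone sample preparation (propionylation of lysines, phenyl-isocyanate
capping of peptide N-termini) and the breadth of biological acylations /
glycation adducts mean that a single precursor delta mass frequently admits
several chemically distinct explanations: a malonyl group (+86.0004 Da) is
exactly isobaric with propionyl (+56.0262) plus a quinone adduct (+29.9742),
and lactylation (+72.0211) with propionyl plus oxidation.  Everything in
this module exists to make those identities explicit and enumerable.

Monoisotopic atomic masses are taken from :mod:`pyteomics.mass` (NIST
values).  Heavy isotopes used by derivatization chemistry (d3-acetyl) and
AQUA-style labels are first-class element symbols: ``2H``, ``13C``, ``15N``.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from pyteomics import mass as _pmass

__all__ = [
    "Composition",
    "Modification",
    "Registry",
    "monoisotopic_mass",
    "mod_mass_sum",
    "decompose_delta",
    "default_registry",
    "BIOLOGICAL",
    "CHEMICAL_ARTIFACT",
    "DERIVATIZATION",
]

# modification categories; these drive FDR-group assignment downstream
BIOLOGICAL = "biological"
CHEMICAL_ARTIFACT = "chemical_artifact"
DERIVATIZATION = "derivatization"
CATEGORIES = frozenset({BIOLOGICAL, CHEMICAL_ARTIFACT, DERIVATIZATION})

# special target tokens usable alongside single residue letters
N_TERM = "N-term"
C_TERM = "C-term"
PROTEIN_N_TERM = "protein-N-term"
_TARGET_TOKENS = frozenset({N_TERM, C_TERM, PROTEIN_N_TERM})


def _nist(element: str, isotope: int = 0) -> float:
    return _pmass.nist_mass[element][isotope][0]


#: monoisotopic mass per supported element symbol
ELEMENT_MASS: dict[str, float] = {
    "C": _nist("C"),
    "H": _nist("H"),
    "N": _nist("N"),
    "O": _nist("O"),
    "S": _nist("S"),
    "P": _nist("P"),
    "13C": _nist("C", 13),
    "2H": _nist("H", 2),
    "15N": _nist("N", 15),
}

_FORMULA_TOKEN = re.compile(r"(13C|15N|2H|[A-Z][a-z]?)(-?\d*)")


class UnknownElementError(ValueError):
    """Raised when a composition references an element symbol outside the
    supported set."""


@dataclass(frozen=True)
class Composition:
    """A signed elemental composition, e.g. ``C3H4O`` or ``O − H2``.

    Counts may be negative, which is how loss-type deltas (quinone = +O2
    −H2) are expressed.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for symbol, n in self.counts.items():
            if symbol not in ELEMENT_MASS:
                raise UnknownElementError(f"unknown element symbol: {symbol!r}")
            if n:
                clean[symbol] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, formula: str) -> "Composition":
        """Parse a compact formula string such as ``C3H4O`` or ``O-H2``
        (minus signs attach to the following count).  Heavy-isotope tokens
        must start a whitespace-separated chunk, e.g. d3-acetyl is
        ``C2 H-1 2H3 O``."""
        counts: dict[str, int] = {}
        for chunk in formula.split():
            pos = 0
            while pos < len(chunk):
                m = _FORMULA_TOKEN.match(chunk, pos)
                if not m:
                    raise UnknownElementError(
                        f"cannot parse formula {formula!r} at {chunk[pos:]!r}"
                    )
                symbol, count = m.group(1), m.group(2)
                if symbol not in ELEMENT_MASS:
                    raise UnknownElementError(f"unknown element symbol: {symbol!r}")
                counts[symbol] = counts.get(symbol, 0) + (int(count) if count else 1)
                pos = m.end()
        return cls(counts)

    def mass(self) -> float:
        return sum(ELEMENT_MASS[el] * n for el, n in self.counts.items())

    def __add__(self, other: "Composition") -> "Composition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Composition(merged)

    def __sub__(self, other: "Composition") -> "Composition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
        return Composition(merged)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def formula(self) -> str:
        light = ["C", "H", "N", "O", "S", "P"]
        heavy = ["13C", "2H", "15N"]
        parts = [
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in light
            if self.counts.get(el)
        ]
        compact = "".join(parts)
        # heavy-isotope tokens must start their own chunk to re-parse
        tail = [
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in heavy
            if self.counts.get(el)
        ]
        return " ".join(x for x in [compact] + tail if x)


def monoisotopic_mass(c: Composition | str) -> float:
    """Monoisotopic mass of a composition (Da).  Accepts a
    :class:`Composition` or a formula string."""
    if isinstance(c, str):
        c = Composition.parse(c)
    return c.mass()


@dataclass(frozen=True)
class Modification:
    """A named mass delta with residue targets and a category.

    ``category`` places the modification into one of three classes —
    biological, chemical artifact, or sample-preparation derivatization —
    which later determines the FDR group of any peptide carrying it.
    ``blocks_lysine_derivatization`` records whether the modification
    occupies the lysine epsilon-amine so that propionylation (or d3
    acetylation) can no longer occur there: all acylations and glycation
    adducts block; mono-methylation does not.
    """

    name: str
    targets: frozenset[str]
    category: str
    composition: Composition | None = None
    explicit_mass: float | None = None
    diagnostic_neutral_losses: tuple[Composition, ...] = ()
    blocks_lysine_derivatization: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no targets")
        for t in self.targets:
            if t not in _TARGET_TOKENS and not (len(t) == 1 and t.isupper()):
                raise ValueError(f"bad target {t!r} for {self.name!r}")
        if self.composition is None and self.explicit_mass is None:
            raise ValueError(f"modification {self.name!r} has neither composition nor mass")
        if not math.isfinite(self.mass):
            raise ValueError(f"modification {self.name!r} has non-finite mass")

    @property
    def mass(self) -> float:
        if self.explicit_mass is not None:
            return self.explicit_mass
        return self.composition.mass()

    def applies_to(self, residue_or_token: str) -> bool:
        return residue_or_token in self.targets

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.name}({self.mass:+.4f})"


def mod_mass_sum(mods: Sequence[Modification]) -> float:
    """Arithmetic sum of modification masses (Da)."""
    if not mods:
        raise ValueError("mod_mass_sum requires a non-empty list")
    return sum(m.mass for m in mods)


class Registry:
    """An ordered collection of modifications with lookup by name and by
    mass within a tolerance."""

    def __init__(self, mods: Iterable[Modification] = ()) -> None:
        self._mods: list[Modification] = []
        self._by_name: dict[str, Modification] = {}
        for m in mods:
            self.add(m)

    def add(self, mod: Modification) -> None:
        if mod.name in self._by_name:
            raise ValueError(f"duplicate modification name {mod.name!r}")
        self._mods.append(mod)
        self._by_name[mod.name] = mod

    def __iter__(self):
        return iter(self._mods)

    def __len__(self) -> int:
        return len(self._mods)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Modification:
        return self._by_name[name]

    def get(self, name: str, default=None):
        return self._by_name.get(name, default)

    def by_category(self, category: str) -> list[Modification]:
        return [m for m in self._mods if m.category == category]

    def by_mass(self, mass: float, tol: float) -> list[Modification]:
        """All modifications within ``tol`` Da of ``mass``, sorted by
        absolute mass error (ties: registry order)."""
        hits = [(abs(m.mass - mass), i, m) for i, m in enumerate(self._mods)
                if abs(m.mass - mass) <= tol]
        hits.sort(key=lambda t: (t[0], t[1]))
        return [m for _, _, m in hits]

    def subset(self, names: Iterable[str]) -> "Registry":
        return Registry(self._by_name[n] for n in names)

    # --- serialization -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Registry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Registry":
        reg = cls()
        for entry in doc.get("modifications", []):
            comp = None
            explicit = None
            if "composition" in entry:
                comp = Composition.parse(str(entry["composition"]))
            if "mass" in entry:
                explicit = float(entry["mass"])
            nls = tuple(
                Composition.parse(str(f)) for f in entry.get("neutral_losses", [])
            )
            reg.add(
                Modification(
                    name=str(entry["name"]),
                    targets=frozenset(str(t) for t in entry["targets"]),
                    category=str(entry["category"]),
                    composition=comp,
                    explicit_mass=explicit,
                    diagnostic_neutral_losses=nls,
                    blocks_lysine_derivatization=bool(
                        entry.get("blocks_lysine_derivatization", True)
                    ),
                )
            )
        return reg

    def to_dict(self) -> dict:
        out = []
        for m in self._mods:
            entry: dict = {
                "name": m.name,
                "targets": sorted(m.targets),
                "category": m.category,
            }
            if m.explicit_mass is not None:
                entry["mass"] = m.explicit_mass
            else:
                entry["composition"] = m.composition.formula()
            if m.diagnostic_neutral_losses:
                entry["neutral_losses"] = [
                    c.formula() for c in m.diagnostic_neutral_losses
                ]
            if not m.blocks_lysine_derivatization:
                entry["blocks_lysine_derivatization"] = False
            out.append(entry)
        return {"modifications": out}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def decompose_delta(
    delta: float,
    registry: Registry,
    max_terms: int = 2,
    tol: float = 0.001,
) -> list[tuple[tuple[Modification, ...], float]]:
    """Enumerate all multisets of at most ``max_terms`` registry
    modifications whose summed mass lies within ``tol`` Da of ``delta``.

    Returns ``[(combination, mass_error), ...]`` sorted by |mass error|,
    then fewest terms, then lexicographic modification names, so output is
    deterministic for a fixed registry.  An open-search delta of +86.0004
    on a derivatized histone peptide, for example, decomposes both to
    {malonyl} and to {propionyl, quinone}.
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    mods = list(registry)
    results = []
    for k in range(1, max_terms + 1):
        for combo in itertools.combinations_with_replacement(mods, k):
            err = sum(m.mass for m in combo) - delta
            if abs(err) <= tol:
                ordered = tuple(sorted(combo, key=lambda m: m.name))
                results.append((ordered, err))
    results.sort(key=lambda t: (abs(t[1]), len(t[0]), tuple(m.name for m in t[0])))
    return results


_DATA_DIR = Path(__file__).parent / "data"


def default_registry() -> Registry:
    """The bundled static registry covering the modifications handled by
    the workflow: classical marks, short-chain acylations, glycation
    adducts (AGEs), derivatization chemistry and common preparation
    artifacts.  Extend by editing a copy of the YAML file or with
    :meth:`Registry.add`."""
    return Registry.from_yaml(_DATA_DIR / "default_registry.yaml")
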