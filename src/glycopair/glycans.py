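"""Glycan composition arithmetic, database parsing and combinatorics.

O-glycans are treated as *compositions* (multisets of monosaccharide
residues), not structures: collisional and electron-based fragmentation of
glycopeptides does not normally resolve topology, and the search only needs
residue masses.  A peptide may carry several database glycans at once; the
multiset of glycans carried by one peptide is a :class:`GlycanBox`, the unit
that a peptide-first search deconvolutes after identification.

The combinatorial helpers quantify why peptide-first searching scales:
a conventional search must enumerate every placement of every glycan
combination on every candidate site, whereas a peptide-first search only
needs the distinct *summed* glycan masses.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chem import PROTON, WATER, formula_mass, parse_formula

__all__ = [
    "Monosaccharide",
    "MonosaccharideRegistry",
    "DEFAULT_REGISTRY",
    "GlycanComposition",
    "GlycanDatabase",
    "GlycanBox",
    "parse_glycan_database",
    "builtin_oglycan_database",
    "oxonium_mz",
    "count_configurations",
    "enumerate_boxes",
    "count_unique_combined_masses",
]


@dataclass(frozen=True)
class Monosaccharide:
    """A monosaccharide residue: the mass it adds to a peptide."""

    name: str
    formula: tuple[tuple[str, int], ...]

    @property
    def residue_mass(self) -> float:
        return formula_mass(dict(self.formula))

    @classmethod
    def from_formula(cls, name: str, formula_text: str) -> "Monosaccharide":
        return cls(name, tuple(sorted(parse_formula(formula_text).items())))


class MonosaccharideRegistry:
    """Ordered registry of known monosaccharides.

    Registry order fixes the canonical text form of a composition
    (``HexNAc(2)Hex(1)`` etc.).  User-defined residues can be appended from
    a two-column TSV of ``name<TAB>formula``.
    """

    def __init__(self, residues: Iterable[Monosaccharide] = ()):
        self._order: list[str] = []
        self._by_name: dict[str, Monosaccharide] = {}
        for r in residues:
            self.add(r)

    def add(self, residue: Monosaccharide) -> None:
        if residue.name in self._by_name:
            raise ValueError(f"duplicate monosaccharide name {residue.name!r}")
        self._order.append(residue.name)
        self._by_name[residue.name] = residue

    def load_tsv(self, path: str | Path) -> None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>formula'")
            self.add(Monosaccharide.from_formula(parts[0].strip(), parts[1].strip()))

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Monosaccharide:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown monosaccharide {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._order)

    def index(self, name: str) -> int:
        return self._order.index(name)


def _default_registry() -> MonosaccharideRegistry:
    reg = MonosaccharideRegistry()
    for name, formula in [
        ("HexNAc", "C8H13NO5"),
        ("Hex", "C6H10O5"),
        ("Fuc", "C6H10O4"),
        ("NeuAc", "C11H17NO8"),
        ("NeuGc", "C11H17NO9"),
        ("Phospho", "HPO3"),
        ("Sulfo", "SO3"),
    ]:
        reg.add(Monosaccharide.from_formula(name, formula))
    return reg


#: Built-in residues in canonical order.
DEFAULT_REGISTRY = _default_registry()

_COMP_SEGMENT_RE = re.compile(r"([A-Za-z][A-Za-z0-9]*)\((\d+)\)")


@dataclass(frozen=True)
class GlycanComposition:
    """Multiset of monosaccharide residues with its exact monoisotopic mass."""

    counts: tuple[tuple[str, int], ...]
    registry: MonosaccharideRegistry = field(
        default=DEFAULT_REGISTRY, compare=False, repr=False
    )

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
    ) -> "GlycanComposition":
        for name, n in counts.items():
            if name not in registry:
                raise ValueError(f"unknown monosaccharide {name}")
            if n < 0:
                raise ValueError(f"negative count for {name}")
        ordered = tuple(
            (name, counts[name])
            for name in registry.names
            if counts.get(name, 0) > 0
        )
        extra = set(counts) - set(registry.names)
        if extra:
            raise ValueError(f"unknown monosaccharide {sorted(extra)[0]}")
        return cls(ordered, registry)

    @classmethod
    def parse(
        cls, text: str, registry: MonosaccharideRegistry = DEFAULT_REGISTRY
    ) -> "GlycanComposition":
        """Parse Byonic-style composition text like ``HexNAc(2)Hex(1)``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for m in _COMP_SEGMENT_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"malformed glycan composition: {text!r}")
            pos = m.end()
            name, n = m.group(1), int(m.group(2))
            if name not in registry:
                raise ValueError(f"unknown monosaccharide {name}")
            counts[name] = counts.get(name, 0) + n
        if pos != len(text):
            raise ValueError(f"malformed glycan composition: {text!r}")
        return cls.from_counts(counts, registry)

    @property
    def mass(self) -> float:
        return sum(self.registry[name].residue_mass * n for name, n in self.counts)

    @property
    def total_residues(self) -> int:
        return sum(n for _, n in self.counts)

    def count(self, name: str) -> int:
        return dict(self.counts).get(name, 0)

    def contains(self, other: "GlycanComposition") -> bool:
        """True when this composition has at least ``other``'s residue counts."""
        mine = dict(self.counts)
        return all(mine.get(name, 0) >= n for name, n in other.counts)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        counts = dict(self.counts)
        for name, n in other.counts:
            counts[name] = counts.get(name, 0) + n
        return GlycanComposition.from_counts(counts, self.registry)

    def __str__(self) -> str:
        return "".join(f"{name}({n})" for name, n in self.counts)


@dataclass(frozen=True)
class GlycanDatabase:
    """Ordered, duplicate-free list of glycan compositions, sorted by mass."""

    entries: tuple[GlycanComposition, ...]
    source_path: str = "<memory>"

    @classmethod
    def from_compositions(
        cls, comps: Sequence[GlycanComposition], source_path: str = "<memory>"
    ) -> "GlycanDatabase":
        seen = set()
        for c in comps:
            if c.counts in seen:
                raise ValueError(f"duplicate glycan composition {c}")
            if c.total_residues == 0:
                raise ValueError("empty glycan composition in database")
            seen.add(c.counts)
        ordered = tuple(sorted(comps, key=lambda c: (c.mass, str(c))))
        return cls(ordered, source_path)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> GlycanComposition:
        return self.entries[i]

    def __iter__(self):
        return iter(self.entries)


def parse_glycan_database(
    path: str | Path, registry: MonosaccharideRegistry = DEFAULT_REGISTRY
) -> GlycanDatabase:
    """Read a glycan database: one composition per line.

    Dialect: ``#`` starts a comment; an optional `` % <mass>`` annotation
    after the composition is checked against the computed mass (0.01 Da).
    """
    path = Path(path)
    comps: list[GlycanComposition] = []
    seen: set[tuple] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        comp_text, _, mass_text = line.partition("%")
        try:
            comp = GlycanComposition.parse(comp_text.strip(), registry)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if comp.total_residues == 0:
            raise ValueError(f"{path}:{lineno}: empty glycan composition")
        if mass_text.strip():
            annotated = float(mass_text.strip())
            if abs(annotated - comp.mass) > 0.01:
                raise ValueError(
                    f"{path}:{lineno}: annotated mass {annotated} disagrees "
                    f"with computed mass {comp.mass:.4f} for {comp}"
                )
        if comp.counts in seen:
            raise ValueError(f"{path}:{lineno}: duplicate composition {comp}")
        seen.add(comp.counts)
        comps.append(comp)
    return GlycanDatabase.from_compositions(comps, str(path))


# A small human O-glycan composition set (core-1/core-2 type, with common
# sialylated and fucosylated forms), used as the package default.
_BUILTIN_OGLYCANS = [
    "HexNAc(1)",
    "HexNAc(1)Hex(1)",
    "HexNAc(1)NeuAc(1)",
    "HexNAc(1)Hex(1)NeuAc(1)",
    "HexNAc(1)Hex(1)NeuAc(2)",
    "HexNAc(1)Hex(1)Fuc(1)",
    "HexNAc(2)",
    "HexNAc(2)Hex(1)",
    "HexNAc(2)Hex(2)",
    "HexNAc(2)Hex(1)NeuAc(1)",
    "HexNAc(2)Hex(2)NeuAc(1)",
    "HexNAc(2)Hex(2)NeuAc(2)",
]


def builtin_oglycan_database() -> GlycanDatabase:
    """The default 12-composition human O-glycan database."""
    return GlycanDatabase.from_compositions(
        [GlycanComposition.parse(t) for t in _BUILTIN_OGLYCANS], "<builtin>"
    )


def oxonium_mz(composition: GlycanComposition, water_loss: bool = False) -> float:
    """m/z of the singly protonated oxonium ion of a glycan composition.

    Diagnostic low-mass ions in collisional spectra: the protonated residue
    (e.g. Hex -> 163.0601) or its water-loss form (Hex -> 145.0495).
    """
    if composition.total_residues == 0:
        raise ValueError("empty glycan composition has no oxonium ion")
    m = composition.mass + PROTON
    if water_loss:
        m -= WATER
    return m


def count_configurations(n_glycans_in_db: int, n_sites: int, max_glycans: int) -> int:
    """Number of glycan multisets of size 1..min(n_sites, max_glycans).

    This is the search space a conventional (glycan-first) engine faces for
    a single peptide: every multiset of database glycans that could occupy
    its candidate sites.  Closed form C(n + k, k) - 1 with
    k = min(n_sites, max_glycans).
    """
    if n_glycans_in_db < 1 or n_sites < 1 or max_glycans < 1:
        raise ValueError("all arguments must be >= 1")
    k = min(n_sites, max_glycans)
    return math.comb(n_glycans_in_db + k, k) - 1


def enumerate_boxes(
    db: GlycanDatabase,
    max_glycans: int,
    target_mass: float | None = None,
    tolerance_ppm: float = 10.0,
) -> list["GlycanBox"]:
    """All glycan boxes (multisets of database entries) of size 1..max_glycans.

    With ``target_mass`` given, only boxes whose total mass lies within
    ``tolerance_ppm`` of it (relative to the target) are returned.  Boxes
    are sorted by total mass.
    """
    if max_glycans < 1:
        raise ValueError("max_glycans must be >= 1")
    boxes: list[GlycanBox] = []
    lo = hi = None
    if target_mass is not None:
        half = abs(target_mass) * tolerance_ppm * 1e-6
        lo, hi = target_mass - half, target_mass + half
    for size in range(1, max_glycans + 1):
        for combo in combinations_with_replacement(range(len(db)), size):
            box = GlycanBox.from_indices(db, combo)
            if target_mass is not None and not (lo <= box.total_mass <= hi):
                continue
            boxes.append(box)
    boxes.sort(key=lambda b: (b.total_mass, b.key))
    return boxes


def count_unique_combined_masses(
    db: GlycanDatabase, max_glycans: int, mass_decimals: int = 4
) -> int:
    """Distinct summed box masses, rounded to ``mass_decimals`` decimals.

    This is the search space of a peptide-first engine: the total glycan
    mass is a precursor mass offset, so only unique summed masses matter.
    """
    masses = {
        round(b.total_mass, mass_decimals) for b in enumerate_boxes(db, max_glycans)
    }
    return len(masses)


@dataclass(frozen=True)
class GlycanBox:
    """Multiset of glycan-database entries carried by one peptide."""

    db: GlycanDatabase = field(compare=False, repr=False)
    glycan_counts: tuple[tuple[int, int], ...]  # (entry index, count), index-sorted

    @classmethod
    def from_indices(cls, db: GlycanDatabase, indices: Iterable[int]) -> "GlycanBox":
        counts: dict[int, int] = {}
        for i in indices:
            counts[i] = counts.get(i, 0) + 1
        if not counts:
            raise ValueError("a glycan box must contain at least one glycan")
        return cls(db, tuple(sorted(counts.items())))

    @property
    def key(self) -> tuple[tuple[int, int], ...]:
        return self.glycan_counts

    @property
    def n_glycans(self) -> int:
        return sum(n for _, n in self.glycan_counts)

    @property
    def total_mass(self) -> float:
        return sum(self.db[i].mass * n for i, n in self.glycan_counts)

    @property
    def entries(self) -> list[GlycanComposition]:
        """The box's glycans, one element per instance (with repeats)."""
        out: list[GlycanComposition] = []
        for i, n in self.glycan_counts:
            out.extend([self.db[i]] * n)
        return out

    @property
    def summed_composition(self) -> GlycanComposition:
        total: dict[str, int] = {}
        for i, n in self.glycan_counts:
            for name, c in self.db[i].counts:
                total[name] = total.get(name, 0) + c * n
        return GlycanComposition.from_counts(total, self.db[0].registry)

    def __str__(self) -> str:
        return ",".join(str(self.db[i]) for i, n in self.glycan_counts for _ in range(n))
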