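"""Peptide-first glycopeptide search on the identification scan.

The engine matches the *naked* peptide backbone (b/y ions, glycans assumed
lost during collisional activation) and explains the precursor mass excess
as a total glycan mass: for each MS2 pair, candidate peptides are those
whose mass equals the observed neutral precursor mass minus either zero or
one of the precomputed combined glycan-box masses, within the precursor
tolerance.  Candidates are ranked by an X!Tandem-style hyperscore.

Diagnostic oxonium ions gate which glycan compositions may be assigned: a
rule ties a residue requirement (e.g. contains Hex) to one or more low-mass
ions that must be present in the identification scan with sufficient summed
base-peak-relative intensity.  Rules are evaluated against the first scan
of the pair only — the collisional scan is where oxonium ions are produced.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import NH3, PROTON, WATER, AA_RESIDUE_MASS, neutral_mass, ppm_window
from .digestion import PeptideCandidate
from .glycans import (
    GlycanBox,
    GlycanComposition,
    GlycanDatabase,
    enumerate_boxes,
)
from .spectra import Spectrum, SpectrumPair

log = logging.getLogger(__name__)

__all__ = [
    "OxoniumRule",
    "default_oxonium_rules",
    "parse_oxonium_rules",
    "oxonium_filter",
    "OffsetIndex",
    "precompute_offset_index",
    "PeptideIndex",
    "hyperscore",
    "GlycoPSM",
    "search_pair",
    "SearchParams",
]


# ---------------------------------------------------------------------------
# Oxonium rules

@dataclass(frozen=True)
class OxoniumRule:
    """Residue requirement -> diagnostic ions with a minimum summed intensity."""

    residues: GlycanComposition
    ion_mzs: tuple[float, ...]
    min_summed_relative_intensity: float

    def __post_init__(self):
        if not self.ion_mzs:
            raise ValueError("an oxonium rule needs at least one ion m/z")
        if not 0.0 <= self.min_summed_relative_intensity <= 1.0:
            raise ValueError("rule threshold must lie in [0, 1]")


# The standard rule set: each residue class with its printed diagnostic ions
# (protonated residue and, where informative, the water-loss form), at a 5%
# minimum summed relative abundance.
_DEFAULT_RULES = [
    ("HexNAc(1)Hex(1)", (366.1395,)),
    ("Hex(1)", (163.0601, 145.0495)),
    ("NeuAc(1)", (274.0921, 292.1027)),
    ("NeuGc(1)", (290.0870, 308.0976)),
]


def default_oxonium_rules(min_intensity: float = 0.05) -> list[OxoniumRule]:
    return [
        OxoniumRule(GlycanComposition.parse(res), ions, min_intensity)
        for res, ions in _DEFAULT_RULES
    ]


def parse_oxonium_rules(path: str | Path) -> list[OxoniumRule]:
    """Read a rule file: ``residues<TAB>mz1,mz2,...<TAB>min_rel_intensity``."""
    rules = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 'residues<TAB>ions<TAB>threshold'"
            )
        rules.append(
            OxoniumRule(
                GlycanComposition.parse(parts[0].strip()),
                tuple(float(x) for x in parts[1].split(",")),
                float(parts[2]),
            )
        )
    return rules


def oxonium_filter(
    first_scan: Spectrum,
    box: GlycanBox,
    rules: Sequence[OxoniumRule],
    tol_ppm: float = 10.0,
) -> bool:
    """True when every rule applicable to the box passes on the first scan."""
    if first_scan.n_peaks == 0:
        raise ValueError("cannot evaluate oxonium rules on an empty spectrum")
    applicable = [
        r for r in rules if box.summed_composition.contains(r.residues)
    ]
    if not applicable:
        return True
    base = float(first_scan.intensity.max())
    mz = first_scan.mz
    inten = first_scan.intensity
    for rule in applicable:
        summed = 0.0
        for ion in rule.ion_mzs:
            half = ppm_window(ion, tol_ppm)
            i = np.searchsorted(mz, ion - half)
            j = np.searchsorted(mz, ion + half, side="right")
            summed += float(inten[i:j].sum())
        if summed / base < rule.min_summed_relative_intensity:
            return False
    return True


# ---------------------------------------------------------------------------
# Offset index

@dataclass
class OffsetIndex:
    """Glycan boxes grouped by combined mass, binary-searchable by window."""

    masses: list[float]
    groups: list[list[GlycanBox]]
    db: GlycanDatabase
    max_glycans: int

    def lookup(self, lo: float, hi: float) -> list[GlycanBox]:
        i = bisect.bisect_left(self.masses, lo)
        j = bisect.bisect_right(self.masses, hi)
        out: list[GlycanBox] = []
        for k in range(i, j):
            out.extend(self.groups[k])
        return out

    def offset_masses(self) -> list[float]:
        return self.masses


def precompute_offset_index(
    db: GlycanDatabase, max_glycans: int, mass_decimals: int = 4
) -> OffsetIndex:
    """Group all glycan boxes by combined mass rounded to ``mass_decimals``."""
    grouped: dict[float, list[GlycanBox]] = {}
    for box in enumerate_boxes(db, max_glycans):
        grouped.setdefault(round(box.total_mass, mass_decimals), []).append(box)
    masses = sorted(grouped)
    return OffsetIndex(masses, [grouped[m] for m in masses], db, max_glycans)


# ---------------------------------------------------------------------------
# Fragment arithmetic and scoring

def _residue_prefix_masses(peptide: PeptideCandidate) -> np.ndarray:
    mods = dict(peptide.mod_state)
    deltas = np.array(
        [AA_RESIDUE_MASS[a] + mods.get(i, 0.0) for i, a in enumerate(peptide.sequence, 1)]
    )
    prefix = np.cumsum(deltas)
    return prefix + mods.get(0, 0.0)  # N-terminal mod rides on every prefix


def by_fragment_mzs(
    peptide: PeptideCandidate, max_charge: int = 2
) -> tuple[list[float], list[float]]:
    """Theoretical b and y ion m/z values (charges 1..max_charge)."""
    prefix = _residue_prefix_masses(peptide)
    total = prefix[-1]
    b_neutral = prefix[:-1]
    y_neutral = total - prefix[:-1] + WATER
    b = [m / q + PROTON for q in range(1, max_charge + 1) for m in b_neutral]
    y = [m / q + PROTON for q in range(1, max_charge + 1) for m in y_neutral]
    return b, y


def hyperscore(
    spectrum: Spectrum,
    peptide: PeptideCandidate,
    charge: int,
    product_tol_ppm: float = 10.0,
) -> tuple[float, int, int]:
    """X!Tandem-style hyperscore of the naked peptide against a spectrum.

    score = ln(n_b!) + ln(n_y!) + ln(sum_b_int * sum_y_int), counting
    matched b/y ions at product charges 1+/2+, factorials capped at 10.
    A series with zero matched intensity zeroes the score.
    """
    if spectrum.n_peaks == 0:
        return 0.0, 0, 0
    b_ions, y_ions = by_fragment_mzs(peptide)
    mz = spectrum.mz
    inten = spectrum.intensity

    def series(ions: list[float]) -> tuple[int, float]:
        n = 0
        total = 0.0
        for ion in ions:
            half = ppm_window(ion, product_tol_ppm)
            i = np.searchsorted(mz, ion - half)
            j = np.searchsorted(mz, ion + half, side="right")
            if j > i:
                n += 1
                total += float(inten[i:j].max())
        return n, total

    n_b, int_b = series(b_ions)
    n_y, int_y = series(y_ions)
    if int_b <= 0.0 or int_y <= 0.0:
        return 0.0, n_b, n_y
    score = (
        math.lgamma(min(n_b, 10) + 1)
        + math.lgamma(min(n_y, 10) + 1)
        + math.log(int_b * int_y)
    )
    return score, n_b, n_y


# ---------------------------------------------------------------------------
# Search

@dataclass
class SearchParams:
    precursor_tol_ppm: float = 30.0
    product_tol_ppm: float = 10.0
    max_glycans: int = 5
    min_hyperscore: float = 0.0


class PeptideIndex:
    """Peptide candidates sorted by neutral sequence mass."""

    def __init__(self, candidates: Sequence[PeptideCandidate]):
        decorated = sorted(
            ((c.sequence_mass, c) for c in candidates), key=lambda t: t[0]
        )
        self._masses = np.array([m for m, _ in decorated])
        self._candidates = [c for _, c in decorated]

    def __len__(self) -> int:
        return len(self._candidates)

    def in_window(self, lo: float, hi: float) -> list[PeptideCandidate]:
        i = int(np.searchsorted(self._masses, lo))
        j = int(np.searchsorted(self._masses, hi, side="right"))
        return self._candidates[i:j]

    @property
    def mass_range(self) -> tuple[float, float]:
        if len(self._candidates) == 0:
            return (0.0, 0.0)
        return float(self._masses[0]), float(self._masses[-1])


@dataclass
class GlycoPSM:
    """One identified pair: peptide, total glycan mass, candidate boxes."""

    pair: SpectrumPair
    peptide: PeptideCandidate
    charge: int
    observed_neutral_mass: float
    delta_mass: float
    hyperscore: float
    candidate_boxes: list[GlycanBox] = field(default_factory=list)
    q_value: float = float("nan")
    localization: "object | None" = None  # LocalizationResult, set later
    selected_box: GlycanBox | None = None  # box chosen during localization

    @property
    def is_glyco(self) -> bool:
        return bool(self.candidate_boxes)


def search_pair(
    pair: SpectrumPair,
    peptides: PeptideIndex,
    offsets: OffsetIndex,
    params: SearchParams = SearchParams(),
) -> GlycoPSM | None:
    """Identify the first scan of a pair against peptide + glycan-offset space.

    For every candidate whose mass matches the observed neutral precursor
    mass minus zero or one combined glycan mass, score the naked backbone;
    return the top-hyperscore candidate.  Glycan offsets apply only to
    peptides with at least one S/T site and boxes no larger than the site
    count.  Ties break toward fewer glycans, then the lexicographically
    smaller peptide.
    """
    scan = pair.first_scan
    if scan.precursor_charge is None:
        log.debug("scan %d has unknown charge; skipped", scan.scan_id)
        return None
    charge = scan.precursor_charge
    obs_mass = neutral_mass(scan.precursor_mz, charge)
    tol = ppm_window(obs_mass, params.precursor_tol_ppm)

    pep_lo, pep_hi = peptides.mass_range
    hits: dict[tuple[str, tuple, bool], tuple[PeptideCandidate, float]] = {}
    score_cache: dict[tuple[str, tuple], tuple[float, int, int]] = {}

    def consider(candidate: PeptideCandidate, offset: float) -> None:
        if offset > 0.0 and candidate.n_candidate_sites < 1:
            return
        key = (candidate.sequence, candidate.mod_state, candidate.is_decoy)
        if key not in hits:
            hits[key] = (candidate, offset)

    # non-glycosylated explanation
    for cand in peptides.in_window(obs_mass - tol, obs_mass + tol):
        consider(cand, 0.0)
    # glycan-offset explanations
    for off in offsets.offset_masses():
        target = obs_mass - off
        if target < pep_lo - tol or target > pep_hi + tol:
            continue
        for cand in peptides.in_window(target - tol, target + tol):
            consider(cand, off)

    best: tuple | None = None
    for candidate, _ in hits.values():
        cache_key = (candidate.sequence, candidate.mod_state)
        if cache_key not in score_cache:
            score_cache[cache_key] = hyperscore(
                scan, candidate, charge, params.product_tol_ppm
            )
        score, n_b, n_y = score_cache[cache_key]
        if score <= params.min_hyperscore:
            continue
        delta = obs_mass - candidate.sequence_mass
        if abs(delta) <= tol:
            boxes: list[GlycanBox] = []
        else:
            boxes = [
                b
                for b in offsets.lookup(delta - tol, delta + tol)
                if b.n_glycans <= candidate.n_candidate_sites
                and b.n_glycans <= params.max_glycans
                and abs(delta - b.total_mass) <= tol
            ]
            if not boxes:
                continue
        min_box = min((b.n_glycans for b in boxes), default=0)
        rank = (-score, min_box, candidate.sequence, candidate.is_decoy)
        if best is None or rank < best[0]:
            best = (rank, candidate, delta, score, boxes)

    if best is None:
        return None
    _, candidate, delta, score, boxes = best
    return GlycoPSM(
        pair=pair,
        peptide=candidate,
        charge=charge,
        observed_neutral_mass=obs_mass,
        delta_mass=delta,
        hyperscore=score,
        candidate_boxes=sorted(boxes, key=lambda b: (b.n_glycans, str(b))),
    )
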