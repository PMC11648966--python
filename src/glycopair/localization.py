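"""Glycan-box deconvolution and site localization on the electron scan.

Given a peptide, a glycan box (the multiset of glycans whose summed mass
explains the precursor delta mass), and the electron-activation scan, the
localization graph has nodes (i, c): after residue i, the sub-multiset c of
the box sits on candidate sites at or before i.  Edges keep c unchanged
between residues and, at a candidate S/T site, may add one remaining glycan.
Every root-to-sink path is exactly one full assignment of the box to sites.

A node (i, c) is scored by counting matched electron-scan ions among the
c-ion of length i carrying glycan mass(c) and the z•-ion of length L-i
carrying glycan mass(box - c), each at product charges 1+ and 2+.  A path's
score is the sum of its node scores; paths are weighted softmax-style as
base**score (base 10 by default, so one extra site-determining ion moves a
two-way site probability to 10/11 ≈ 0.91).  Site probabilities come from
exact forward-backward accumulation over the graph — no path enumeration —
and, when the base is an integer, the arithmetic is exact (Python integers),
so probabilities carry no floating-point accumulation error.

Confidence levels: 1 = every glycan instance localized (some site with
probability above the threshold) with spectral evidence; 1b = localized by
process of elimination (a single feasible configuration, or no matched
site-determining ion); 2 = at least one but not all localized; 3 = none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations
from typing import Sequence

import numpy as np

from .chem import H_ATOM, NH3, PROTON, WATER, AA_RESIDUE_MASS, ppm_window
from .digestion import PeptideCandidate
from .glycans import GlycanBox
from .search import GlycoPSM, OxoniumRule, SearchParams, oxonium_filter
from .spectra import Spectrum, SpectrumPair

log = logging.getLogger(__name__)

__all__ = [
    "LocalizationGraph",
    "LocalizationResult",
    "build_graph",
    "localize",
    "brute_force_localize",
    "select_best_box",
]


@dataclass(frozen=True)
class LocalizationResult:
    """Best assignment, per-site glycan probabilities and a confidence level."""

    best_assignment: tuple[tuple[int, str], ...]  # (site, glycan text)
    best_path_score: int
    site_probabilities: tuple[tuple[int, str, float], ...]  # site, glycan, P
    level: str  # "1" | "1b" | "2" | "3"
    n_configurations: int
    opair_score: float

    @property
    def assignment_string(self) -> str:
        if not self.best_assignment:
            return ""
        return ";".join(f"{site}:{g}" for site, g in self.best_assignment)

    def probability_string(self) -> str:
        return ";".join(
            f"{site}:{g}:{p:.4f}" for site, g, p in self.site_probabilities
        )

    def probability(self, site: int, glycan: str) -> float:
        for s, g, p in self.site_probabilities:
            if s == site and g == glycan:
                return p
        return 0.0


UNLOCALIZED = LocalizationResult((), 0, (), "3", 0, 0.0)


class LocalizationGraph:
    """The layered DAG of partial glycan placements along the peptide."""

    def __init__(
        self,
        peptide: PeptideCandidate,
        box: GlycanBox,
        scan: Spectrum | None,
        product_tol_ppm: float = 10.0,
    ):
        if box.n_glycans > peptide.n_candidate_sites:
            raise ValueError(
                f"infeasible box: {box.n_glycans} glycans on "
                f"{peptide.n_candidate_sites} candidate sites of {peptide.sequence}"
            )
        self.peptide = peptide
        self.box = box
        self.scan = scan
        self.product_tol_ppm = product_tol_ppm
        self.length = len(peptide.sequence)
        self.candidate_sites = peptide.candidate_sites
        # distinct glycans with multiplicities; child boxes are count vectors
        self.glycans = [box.db[i] for i, _ in box.glycan_counts]
        self.multiplicities = tuple(n for _, n in box.glycan_counts)
        self.glycan_masses = [g.mass for g in self.glycans]
        self._site_set = set(self.candidate_sites)
        self._prefix = self._residue_prefix()
        self._layers = self._build_layers()
        self._score_cache: dict[tuple[int, tuple[int, ...]], int] = {}

    # -- structure -----------------------------------------------------

    def _residue_prefix(self) -> np.ndarray:
        mods = dict(self.peptide.mod_state)
        deltas = [
            AA_RESIDUE_MASS[a] + mods.get(i, 0.0)
            for i, a in enumerate(self.peptide.sequence, 1)
        ]
        prefix = np.concatenate([[0.0], np.cumsum(deltas)])
        return prefix + mods.get(0, 0.0)

    def _build_layers(self) -> list[list[tuple[int, ...]]]:
        n_total = self.box.n_glycans
        sites_le = np.zeros(self.length + 1, dtype=int)
        for i in range(1, self.length + 1):
            sites_le[i] = sites_le[i - 1] + (1 if i in self._site_set else 0)
        total_sites = int(sites_le[-1])
        layers: list[list[tuple[int, ...]]] = [[(0,) * len(self.glycans)]]
        for i in range(1, self.length + 1):
            prev = layers[i - 1]
            here: set[tuple[int, ...]] = set()
            is_site = i in self._site_set
            for c in prev:
                here.add(c)
                if is_site:
                    for g in range(len(self.glycans)):
                        if c[g] < self.multiplicities[g]:
                            grown = list(c)
                            grown[g] += 1
                            here.add(tuple(grown))
            feasible = []
            for c in here:
                size = sum(c)
                if size > sites_le[i]:
                    continue
                if n_total - size > total_sites - sites_le[i]:
                    continue
                feasible.append(c)
            layers.append(sorted(feasible))
        return layers

    @property
    def layers(self) -> list[list[tuple[int, ...]]]:
        return self._layers

    def predecessors(self, i: int, c: tuple[int, ...]):
        """Yield (c_prev, glycan index or None) for edges into (i, c)."""
        prev = set(self._layers[i - 1])
        if c in prev:
            yield c, None
        if i in self._site_set:
            for g in range(len(self.glycans)):
                if c[g] > 0:
                    shrunk = list(c)
                    shrunk[g] -= 1
                    shrunk = tuple(shrunk)
                    if shrunk in prev:
                        yield shrunk, g

    # -- scoring -------------------------------------------------------

    def _glycan_mass(self, c: tuple[int, ...]) -> float:
        return sum(m * n for m, n in zip(self.glycan_masses, c))

    def node_ion_mzs(self, i: int, c: tuple[int, ...]) -> list[float]:
        """Theoretical c/z• ions read out at node (i, c), charges 1+/2+."""
        if i <= 0 or i >= self.length:
            return []
        gm = self._glycan_mass(c)
        c_neutral = self._prefix[i] + NH3 + gm
        z_neutral = (
            (self._prefix[self.length] - self._prefix[i])
            + WATER
            - NH3
            + H_ATOM
            + (self.box.total_mass - gm)
        )
        return [
            m / q + PROTON for m in (c_neutral, z_neutral) for q in (1, 2)
        ]

    def node_score(self, i: int, c: tuple[int, ...]) -> int:
        """Matched-ion count at node (i, c); identical for equal glycan mass."""
        key = (i, c)
        if key in self._score_cache:
            return self._score_cache[key]
        if self.scan is None or self.scan.n_peaks == 0:
            score = 0
        else:
            score = sum(
                1
                for ion in self.node_ion_mzs(i, c)
                if self.scan.has_peak(ion, self.product_tol_ppm)
            )
        self._score_cache[key] = score
        return score

    def variable_layers(self) -> set[int]:
        """Positions i where the attached glycan mass differs between
        feasible nodes — matched ions there are site-determining."""
        out = set()
        for i in range(1, self.length):
            masses = {round(self._glycan_mass(c), 6) for c in self._layers[i]}
            if len(masses) > 1:
                out.add(i)
        return out

    def n_configurations(self) -> int:
        count: dict[tuple[int, ...], int] = {self._layers[0][0]: 1}
        for i in range(1, self.length + 1):
            nxt: dict[tuple[int, ...], int] = {}
            for c in self._layers[i]:
                nxt[c] = sum(
                    count.get(cp, 0) for cp, _ in self.predecessors(i, c)
                )
            count = nxt
        return count.get(tuple(self.multiplicities), 0)


def build_graph(
    peptide: PeptideCandidate,
    box: GlycanBox,
    scan: Spectrum | None,
    product_tol_ppm: float = 10.0,
) -> LocalizationGraph:
    """Construct the localization graph for one peptide/box/scan triple."""
    return LocalizationGraph(peptide, box, scan, product_tol_ppm)


def _as_weight(base: float, score: int):
    if float(base).is_integer():
        return int(base) ** score  # exact big-int arithmetic
    return base**score


def localize(
    graph: LocalizationGraph,
    weighting_base: float = 10.0,
    prob_threshold: float = 0.75,
) -> LocalizationResult:
    """Forward-backward localization over the graph.

    Exact per-(site, glycan) probabilities, the best-scoring assignment, and
    a confidence level.  Runs in time linear in the number of graph edges.
    """
    L = graph.length
    layers = graph.layers
    full = tuple(graph.multiplicities)

    # forward pass: weight of all partial paths into each node, and the
    # best (max-sum) path with deterministic tie-breaking
    fwd: list[dict[tuple[int, ...], object]] = [{layers[0][0]: 1}]
    best: list[dict[tuple[int, ...], tuple[int, tuple]]] = [
        {layers[0][0]: (0, ())}
    ]
    for i in range(1, L + 1):
        f_here: dict[tuple[int, ...], object] = {}
        b_here: dict[tuple[int, ...], tuple[int, tuple]] = {}
        for c in layers[i]:
            score = graph.node_score(i, c)
            w = _as_weight(weighting_base, score)
            total = 0
            best_entry = None
            for cp, g in graph.predecessors(i, c):
                if cp not in fwd[i - 1]:
                    continue
                total = total + fwd[i - 1][cp] * w
                prev_score, prev_path = best[i - 1][cp]
                cand_score = prev_score + score
                step = prev_path + (((i, g),) if g is not None else ())
                entry = (cand_score, step)
                if (
                    best_entry is None
                    or entry[0] > best_entry[0]
                    or (entry[0] == best_entry[0] and entry[1] < best_entry[1])
                ):
                    best_entry = entry
            if best_entry is None:
                continue
            f_here[c] = total
            b_here[c] = best_entry
        fwd.append(f_here)
        best.append(b_here)

    if full not in fwd[L]:
        return UNLOCALIZED
    Z = fwd[L][full]
    best_score, best_steps = best[L][full]

    # backward pass: weight of all partial paths out of each node
    bwd: list[dict[tuple[int, ...], object]] = [dict() for _ in range(L + 1)]
    bwd[L][full] = 1
    for i in range(L, 0, -1):
        for c in layers[i]:
            if c not in bwd[i]:
                continue
            w = _as_weight(weighting_base, graph.node_score(i, c))
            contrib = bwd[i][c] * w
            for cp, _ in graph.predecessors(i, c):
                bwd[i - 1][cp] = bwd[i - 1].get(cp, 0) + contrib

    # per-edge posterior mass -> per-(site, glycan) probabilities
    prob_acc: dict[tuple[int, int], object] = {}
    for i in graph.candidate_sites:
        for c in layers[i]:
            if c not in bwd[i] or c not in fwd[i]:
                continue
            w = _as_weight(weighting_base, graph.node_score(i, c))
            for cp, g in graph.predecessors(i, c):
                if g is None or cp not in fwd[i - 1]:
                    continue
                mass = fwd[i - 1][cp] * w * bwd[i][c]
                prob_acc[(i, g)] = prob_acc.get((i, g), 0) + mass

    def ratio(num, den) -> float:
        if isinstance(num, int) and isinstance(den, int):
            return float(Fraction(num, den))
        return num / den

    site_probs = tuple(
        (site, str(graph.glycans[g]), ratio(mass, Z))
        for (site, g), mass in sorted(prob_acc.items())
    )

    n_conf = graph.n_configurations()
    assignment = tuple(
        sorted((site, str(graph.glycans[g])) for site, g in best_steps)
    )

    # site-determining ions matched along the best path
    variable = graph.variable_layers()
    placed: dict[int, int] = dict()
    c_now = [0] * len(graph.glycans)
    step_at = {site: g for site, g in best_steps}
    n_sd_matched = 0
    for i in range(1, L + 1):
        if i in step_at:
            c_now[step_at[i]] += 1
        if i in variable:
            n_sd_matched += graph.node_score(i, tuple(c_now))

    # localization status per glycan instance; identical glycan entries
    # share a text name, so count each name once against its total multiplicity
    seen_names = set()
    localized = 0
    for g, mult in enumerate(graph.multiplicities):
        name = str(graph.glycans[g])
        if name in seen_names:
            continue
        seen_names.add(name)
        over = sum(1 for _, n, p in site_probs if n == name and p > prob_threshold)
        total_mult = sum(
            m
            for gg, m in enumerate(graph.multiplicities)
            if str(graph.glycans[gg]) == name
        )
        localized += min(over, total_mult)

    n_total = graph.box.n_glycans
    if localized == n_total:
        if n_conf == 1 or n_sd_matched == 0:
            level = "1b"
        else:
            level = "1"
    elif localized >= 1:
        level = "2"
    else:
        level = "3"

    return LocalizationResult(
        best_assignment=assignment,
        best_path_score=best_score,
        site_probabilities=site_probs,
        level=level,
        n_configurations=n_conf,
        opair_score=float(best_score),
    )


def brute_force_localize(
    peptide: PeptideCandidate,
    box: GlycanBox,
    scan: Spectrum | None,
    product_tol_ppm: float = 10.0,
    weighting_base: float = 10.0,
    prob_threshold: float = 0.75,
    max_configurations: int = 100_000,
) -> LocalizationResult:
    """Reference localization by explicit enumeration of every assignment.

    Independent oracle for :func:`localize`: scores each full configuration
    directly and accumulates probabilities without any graph machinery.
    """
    graph = LocalizationGraph(peptide, box, scan, product_tol_ppm)
    sites = graph.candidate_sites
    instances: list[int] = []
    for g, mult in enumerate(graph.multiplicities):
        instances.extend([g] * mult)
    n = len(instances)

    configs: set[tuple[tuple[int, int], ...]] = set()
    from itertools import combinations

    for chosen in combinations(sites, n):
        for perm in set(permutations(instances)):
            configs.add(tuple(zip(chosen, perm)))
    if len(configs) > max_configurations:
        raise ValueError(f"too many configurations ({len(configs)})")
    if not configs:
        return UNLOCALIZED

    def config_score(config) -> int:
        placement = dict(config)
        c_now = [0] * len(graph.glycans)
        total = 0
        for i in range(1, graph.length + 1):
            if i in placement:
                c_now[placement[i]] += 1
            total += graph.node_score(i, tuple(c_now))
        return total

    scored = {cfg: config_score(cfg) for cfg in configs}
    exact = float(weighting_base).is_integer()
    base = int(weighting_base) if exact else weighting_base
    weights = {cfg: base**s for cfg, s in scored.items()}
    Z = sum(weights.values())

    prob_acc: dict[tuple[int, int], object] = {}
    for cfg, w in weights.items():
        for site, g in cfg:
            prob_acc[(site, g)] = prob_acc.get((site, g), 0) + w
    site_probs = tuple(
        (site, str(graph.glycans[g]), float(Fraction(m, Z)) if exact else m / Z)
        for (site, g), m in sorted(prob_acc.items())
    )

    best_score = max(scored.values())
    # tie-break consistent with localize(): smallest sorted step sequence
    best_paths = {}
    for cfg, s in scored.items():
        if s != best_score:
            continue
        steps = tuple(sorted((site, g) for site, g in cfg))
        best_paths[steps] = tuple(
            sorted((site, str(graph.glycans[g])) for site, g in cfg)
        )
    assignment = best_paths[min(best_paths)]

    variable = graph.variable_layers()
    best_cfg_steps = min(
        (tuple(sorted(cfg)) for cfg, s in scored.items() if s == best_score)
    )
    placement = dict(best_cfg_steps)
    c_now = [0] * len(graph.glycans)
    n_sd_matched = 0
    for i in range(1, graph.length + 1):
        if i in placement:
            c_now[placement[i]] += 1
        if i in variable:
            n_sd_matched += graph.node_score(i, tuple(c_now))

    localized = 0
    seen_names = set()
    for g, mult in enumerate(graph.multiplicities):
        name = str(graph.glycans[g])
        if name in seen_names:
            continue
        seen_names.add(name)
        over = sum(1 for _, nm, p in site_probs if nm == name and p > prob_threshold)
        total_mult = sum(
            m
            for gg, m in enumerate(graph.multiplicities)
            if str(graph.glycans[gg]) == name
        )
        localized += min(over, total_mult)

    n_total = box.n_glycans
    if localized == n_total:
        level = "1b" if len(configs) == 1 or n_sd_matched == 0 else "1"
    elif localized >= 1:
        level = "2"
    else:
        level = "3"

    return LocalizationResult(
        best_assignment=assignment,
        best_path_score=best_score,
        site_probabilities=site_probs,
        level=level,
        n_configurations=len(configs),
        opair_score=float(best_score),
    )


def select_best_box(
    pair: SpectrumPair,
    peptide: PeptideCandidate,
    candidate_boxes: Sequence[GlycanBox],
    rules: Sequence[OxoniumRule] = (),
    params: SearchParams = SearchParams(),
    weighting_base: float = 10.0,
    prob_threshold: float = 0.75,
) -> tuple[GlycanBox | None, LocalizationResult]:
    """Pick the glycan box best supported by the localization scan.

    Boxes first pass the oxonium filter (on the identification scan); each
    survivor is localized on the localization scan and the box with the
    highest best-path score wins (ties: fewer glycans, then canonical text).
    If every box is filtered out, the PSM keeps only its total glycan mass:
    composition unassigned, level 3.
    """
    passing = [
        b
        for b in candidate_boxes
        if oxonium_filter(pair.first_scan, b, rules, params.product_tol_ppm)
    ]
    if not passing:
        return None, UNLOCALIZED
    scan = pair.localization_scan
    ranked: list[tuple[tuple, GlycanBox, LocalizationResult]] = []
    for box in passing:
        result = localize(
            build_graph(peptide, box, scan, params.product_tol_ppm),
            weighting_base,
            prob_threshold,
        )
        ranked.append(((-result.best_path_score, box.n_glycans, str(box)), box, result))
    ranked.sort(key=lambda t: t[0])
    _, box, result = ranked[0]
    return box, result
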