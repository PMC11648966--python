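"""In-silico protein digestion with decoys and variable modifications.

Supported proteases: trypsin (C-terminal to K/R, optionally not before P),
StcE (a mucinase cleaving N-terminal to serine/threonine — since
glycosylation cannot be known in silico, every S/T is treated as a
potential cleavage site, so "missed cleavages" here count skipped S/T
positions, not true enzymatic misses), or no enzyme.  Semi-specific mode
additionally yields every peptide with exactly one non-specific terminus.

Decoys are digested from reversed protein sequences and flagged; a decoy
whose sequence collides with a target peptide is discarded so target and
decoy candidate sets stay disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator

from pyteomics import fasta as _fasta

from .chem import peptide_mass

log = logging.getLogger(__name__)

__all__ = ["DigestionSpec", "PeptideCandidate", "VariableMod", "digest"]

# deltas used for the default variable modification set
OXIDATION = 15.994915
DEAMIDATION = 0.984016
ACETYL = 42.010565


@dataclass(frozen=True)
class VariableMod:
    """A variable modification: residue letter or 'prot_nterm', delta Da."""

    target: str
    delta: float
    max_occurrences: int = 1
    name: str = ""


@dataclass(frozen=True)
class DigestionSpec:
    enzyme: str = "trypsin"  # trypsin | stce | none
    specificity: str = "full"  # full | semi
    max_missed_cleavages: int = 2
    peptide_length_range: tuple[int, int] = (5, 40)
    variable_mods: tuple[VariableMod, ...] = ()
    trypsin_not_before_proline: bool = True
    max_candidates: int = 5_000_000

    def __post_init__(self):
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.peptide_length_range[0] < 4:
            raise ValueError("minimum peptide length must be >= 4")


@dataclass(frozen=True)
class PeptideCandidate:
    """A (possibly modified) peptide sequence considered during search."""

    sequence: str
    protein_ids: tuple[str, ...]
    is_decoy: bool = False
    mod_state: tuple[tuple[int, float], ...] = ()  # (1-based position, delta)
    is_protein_nterm: bool = False

    @property
    def sequence_mass(self) -> float:
        return peptide_mass(self.sequence, sum(d for _, d in self.mod_state))

    @property
    def n_candidate_sites(self) -> int:
        return sum(1 for a in self.sequence if a in "ST")

    @property
    def candidate_sites(self) -> tuple[int, ...]:
        """1-based positions of S/T residues."""
        return tuple(i for i, a in enumerate(self.sequence, 1) if a in "ST")

    @property
    def modified_sequence(self) -> str:
        if not self.mod_state:
            return self.sequence
        mods = dict(self.mod_state)
        out = []
        if 0 in mods:  # N-terminal modification
            out.append(f"n[{mods[0]:+.4f}]")
        for i, a in enumerate(self.sequence, 1):
            out.append(a)
            if i in mods:
                out.append(f"[{mods[i]:+.4f}]")
        return "".join(out)


def _cut_positions(seq: str, enzyme: str, not_before_p: bool) -> list[int]:
    """Positions (between seq[i-1] and seq[i]) where the protease cuts."""
    n = len(seq)
    if enzyme == "none":
        return list(range(1, n))
    cuts = []
    if enzyme == "trypsin":
        for i in range(1, n):
            if seq[i - 1] in "KR" and not (not_before_p and seq[i] == "P"):
                cuts.append(i)
    elif enzyme == "stce":
        for i in range(1, n):
            if seq[i] in "ST":
                cuts.append(i)
    else:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    return cuts


def _specific_spans(
    n: int, cuts: list[int], max_missed: int
) -> Iterator[tuple[int, int]]:
    bounds = [0] + cuts + [n]
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(bounds))):
            yield bounds[a], bounds[b]


def _peptides_from_protein(
    seq: str, spec: DigestionSpec
) -> Iterator[tuple[int, int]]:
    cuts = _cut_positions(seq, spec.enzyme, spec.trypsin_not_before_proline)
    lo, hi = spec.peptide_length_range
    seen: set[tuple[int, int]] = set()
    for start, end in _specific_spans(len(seq), cuts, spec.max_missed_cleavages):
        if spec.specificity == "full":
            if lo <= end - start <= hi and (start, end) not in seen:
                seen.add((start, end))
                yield start, end
        elif spec.specificity == "semi":
            # keep the specific span plus every sub-span sharing one terminus
            for s in range(start, end):
                span = (s, end)
                if lo <= end - s <= hi and span not in seen:
                    seen.add(span)
                    yield span
            for e in range(start + 1, end + 1):
                span = (start, e)
                if lo <= e - start <= hi and span not in seen:
                    seen.add(span)
                    yield span
        else:
            raise ValueError(f"unknown specificity {spec.specificity!r}")


def _mod_states(
    sequence: str, is_protein_nterm: bool, mods: tuple[VariableMod, ...]
) -> Iterator[tuple[tuple[int, float], ...]]:
    """Enumerate modification states (position -> delta) up to per-mod maxima."""
    per_mod_choices: list[list[tuple[tuple[int, float], ...]]] = []
    for mod in mods:
        if mod.target == "prot_nterm":
            positions = [0] if is_protein_nterm else []
        else:
            positions = [
                i for i, a in enumerate(sequence, 1) if a in mod.target
            ]
        choices: list[tuple[tuple[int, float], ...]] = [()]
        for k in range(1, min(mod.max_occurrences, len(positions)) + 1):
            for combo in combinations(positions, k):
                choices.append(tuple((p, mod.delta) for p in combo))
        per_mod_choices.append(choices)

    def rec(i: int, acc: tuple[tuple[int, float], ...]):
        if i == len(per_mod_choices):
            yield tuple(sorted(acc))
            return
        for choice in per_mod_choices[i]:
            yield from rec(i + 1, acc + choice)

    yield from rec(0, ())


def digest(
    fasta: str | Path,
    spec: DigestionSpec = DigestionSpec(),
    decoy_mode: str = "reverse",
) -> list[PeptideCandidate]:
    """Digest a FASTA database into modified peptide candidates.

    Returns targets plus (for ``decoy_mode='reverse'``) decoys digested from
    reversed protein sequences.  Identical target sequences from different
    proteins are merged, accumulating protein ids.
    """
    source = fasta if hasattr(fasta, "read") else str(fasta)
    proteins = [
        (header.split()[0], seq)
        for header, seq in _fasta.read(source, use_index=False)
    ]
    if not proteins:
        raise ValueError(f"empty FASTA: {fasta}")
    if decoy_mode not in ("reverse", "none"):
        raise ValueError(f"unknown decoy_mode {decoy_mode!r}")

    def collect(protein_list, is_decoy: bool) -> dict[tuple, PeptideCandidate]:
        out: dict[tuple, PeptideCandidate] = {}
        n_states = 0
        for pid, seq in protein_list:
            seq = seq.upper().replace("*", "")
            for start, end in _peptides_from_protein(seq, spec):
                pep = seq[start:end]
                if any(a not in "ACDEFGHIKLMNPQRSTVWY" for a in pep):
                    continue
                nterm = start == 0
                for mod_state in _mod_states(pep, nterm, spec.variable_mods):
                    n_states += 1
                    if n_states > spec.max_candidates:
                        raise ValueError(
                            "candidate cap exceeded "
                            f"({spec.max_candidates}); tighten digestion "
                            "limits (missed cleavages, specificity, length "
                            "range or variable modifications)"
                        )
                    key = (pep, mod_state)
                    if key in out:
                        if pid not in out[key].protein_ids:
                            out[key] = PeptideCandidate(
                                pep,
                                out[key].protein_ids + (pid,),
                                is_decoy,
                                mod_state,
                                out[key].is_protein_nterm or nterm,
                            )
                    else:
                        out[key] = PeptideCandidate(
                            pep, (pid,), is_decoy, mod_state, nterm
                        )
        return out

    targets = collect(proteins, False)
    candidates = list(targets.values())
    if decoy_mode == "reverse":
        target_seqs = {pep for pep, _ in targets}
        decoys = collect(
            [(f"rev_{pid}", seq[::-1]) for pid, seq in proteins], True
        )
        n_dropped = 0
        for (pep, _), cand in decoys.items():
            if pep in target_seqs:
                n_dropped += 1
                continue
            candidates.append(cand)
        if n_dropped:
            log.info("dropped %d decoy peptides colliding with targets", n_dropped)
    return candidates
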