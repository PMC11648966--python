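"""Ground-truth glycopeptide run simulation.

Emulates product-dependent paired acquisition: for each simulated
glycopeptide an MS1 survey scan is followed by a collisional MS2 scan
(naked-peptide b/y ladder, oxonium ions implied by the glycan content, and
a precursor residual) and an electron-activation MS2 scan (c/z• ladder with
the glycans retained at their true sites).  Fragment detection is Bernoulli
per ion, m/z values carry Gaussian ppm jitter, intensities are log-normal
on a base-peak-relative scale, and uniform noise peaks can be mixed in.

Every source of randomness flows from ``SimulationConfig.seed``, so a fixed
configuration reproduces a byte-identical run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import NH3, PROTON, WATER, H_ATOM, AA_RESIDUE_MASS, mz as _mz
from .digestion import DigestionSpec, PeptideCandidate, digest
from .glycans import (
    GlycanBox,
    GlycanComposition,
    GlycanDatabase,
    builtin_oglycan_database,
    oxonium_mz,
)
from .spectra import Spectrum, write_mgf, write_mzml

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruthRecord",
    "SimulatedRun",
    "build_run",
    "simulate_run",
    "make_entrapment_run",
    "write_truth",
    "read_truth",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# roughly vertebrate-proteome amino-acid frequencies
_AA_FREQ = np.array(
    [7.4, 2.5, 5.9, 5.8, 4.0, 7.4, 2.9, 3.8, 7.2, 7.6,
     1.8, 4.4, 5.0, 3.7, 4.2, 8.1, 6.2, 6.8, 1.3, 3.3]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_glycopeptides: int = 100
    fasta: str | None = None  # None -> random proteome
    n_proteins: int = 20
    protein_length: int = 300
    glycan_db: GlycanDatabase | None = None  # None -> builtin 12-composition set
    max_glycans_per_peptide: int = 3
    site_occupancy: float = 0.35  # probability each S/T carries a glycan
    detection_prob_by: float = 0.9
    detection_prob_cz: float = 0.9
    ppm_jitter_sd: float = 5.0
    noise_peaks_per_scan: int = 30
    oxonium_emission: bool = True
    pairing_order: str = "hcd_first"  # hcd_first | etd_first
    charges: tuple[int, ...] = (2, 3, 4)
    charge_weights: tuple[float, ...] = (2.0, 2.0, 1.0)
    peptide_length_range: tuple[int, int] = (6, 30)
    output_format: str = "mgf"  # mgf | mzml


@dataclass(frozen=True)
class GroundTruthRecord:
    first_scan_id: int
    second_scan_id: int
    peptide: str
    proteins: str
    charge: int
    precursor_mz: float
    total_glycan_mass: float
    site_assignments: tuple[tuple[int, str], ...]  # (1-based site, glycan text)

    @property
    def n_glycans(self) -> int:
        return len(self.site_assignments)

    def assignment_string(self, seq: str | None = None) -> str:
        seq = seq or self.peptide
        return ";".join(
            f"{seq[s - 1]}{s}:{g}" for s, g in self.site_assignments
        )


@dataclass
class SimulatedRun:
    spectra: list[Spectrum]
    truth: list[GroundTruthRecord]
    fasta_path: Path | None = None
    run_path: Path | None = None
    truth_path: Path | None = None


def _random_proteome(rng: np.random.Generator, cfg: SimulationConfig) -> list[tuple[str, str]]:
    out = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(cfg.protein_length // 2, cfg.protein_length * 2))
        seq = "".join(rng.choice(list(_AA), size=length, p=_AA_FREQ))
        out.append((f"SIM{i:04d}", seq))
    return out


def _lognormal(rng: np.random.Generator, scale: float = 1.0) -> float:
    return float(scale * np.exp(rng.normal(0.0, 0.5)))


def _jitter(rng: np.random.Generator, mz: float, ppm_sd: float) -> float:
    if ppm_sd <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm_sd * 1e-6))


_OXONIUM_SINGLETONS = ["HexNAc", "Hex", "NeuAc", "NeuGc"]


def _oxonium_peaks(total: GlycanComposition) -> list[float]:
    peaks = []
    for name in _OXONIUM_SINGLETONS:
        if total.count(name) > 0:
            single = GlycanComposition.from_counts({name: 1}, total.registry)
            peaks.append(oxonium_mz(single))
            peaks.append(oxonium_mz(single, water_loss=True))
    if total.count("HexNAc") > 0 and total.count("Hex") > 0:
        pair = GlycanComposition.from_counts({"HexNAc": 1, "Hex": 1}, total.registry)
        peaks.append(oxonium_mz(pair))
    return peaks


def _backbone_prefix(peptide: str) -> np.ndarray:
    return np.concatenate(
        [[0.0], np.cumsum([AA_RESIDUE_MASS[a] for a in peptide])]
    )


def build_run(
    config: SimulationConfig, glycan_pool: Sequence[GlycanComposition] | None = None
) -> SimulatedRun:
    """Generate spectra and ground truth in memory.

    ``glycan_pool`` restricts which database glycans the truth may draw
    (used for entrapment simulations); spectra always emit only the oxonium
    ions implied by the glycans actually present.
    """
    rng = np.random.default_rng(config.seed)
    db = config.glycan_db or builtin_oglycan_database()
    pool = list(glycan_pool) if glycan_pool is not None else list(db)
    pool_indices = [i for i, c in enumerate(db) if c in pool]
    if not pool_indices:
        raise ValueError("glycan pool is empty")

    if config.fasta is not None:
        from pyteomics import fasta as _fasta

        proteins = [(h.split()[0], s) for h, s in _fasta.read(config.fasta)]
    else:
        proteins = _random_proteome(rng, config)

    spec = DigestionSpec(
        enzyme="trypsin",
        specificity="full",
        max_missed_cleavages=2,
        peptide_length_range=config.peptide_length_range,
    )
    candidates = [
        c
        for c in digest(_fasta_from(proteins), spec, "none")
        if c.n_candidate_sites >= 1
    ]
    if not candidates:
        raise ValueError("no glycosylatable peptides in the simulated proteome")

    spectra: list[Spectrum] = []
    truth: list[GroundTruthRecord] = []
    scan_id = 0
    charge_p = np.array(config.charge_weights) / sum(config.charge_weights)

    for _ in range(config.n_glycopeptides):
        pep = candidates[int(rng.integers(len(candidates)))]
        sites = pep.candidate_sites
        occupied = [s for s in sites if rng.random() < config.site_occupancy]
        n_max = min(config.max_glycans_per_peptide, len(sites))
        if len(occupied) > n_max:
            occupied = list(rng.choice(occupied, size=n_max, replace=False))
        if not occupied:
            occupied = [sites[int(rng.integers(len(sites)))]]
        occupied = sorted(int(s) for s in occupied)
        glycan_idx = [
            int(pool_indices[int(rng.integers(len(pool_indices)))])
            for _ in occupied
        ]
        assignment = tuple(
            (s, str(db[g])) for s, g in zip(occupied, glycan_idx)
        )
        box = GlycanBox.from_indices(db, glycan_idx)
        charge = int(rng.choice(config.charges, p=charge_p))
        neutral = pep.sequence_mass + box.total_mass
        precursor = _mz(neutral, charge)
        rt = 60.0 + 2.0 * len(truth)

        # MS1 boundary
        scan_id += 1
        spectra.append(
            Spectrum(
                scan_id, 1, mz=[precursor], intensity=[1e6], retention_time=rt
            )
        )

        first = _collisional_scan(
            rng, config, scan_id + 1, pep, box, charge, precursor, rt + 0.5
        )
        second = _electron_scan(
            rng, config, scan_id + 2, pep, db, assignment, box, charge,
            precursor, rt + 1.0,
        )
        scan_id += 2
        if config.pairing_order == "hcd_first":
            spectra.extend([first, second])
            first_id, second_id = first.scan_id, second.scan_id
        elif config.pairing_order == "etd_first":
            spectra.extend([second, first])
            first_id, second_id = second.scan_id, first.scan_id
        else:
            raise ValueError(f"unknown pairing_order {config.pairing_order!r}")

        truth.append(
            GroundTruthRecord(
                first_scan_id=first.scan_id,
                second_scan_id=second.scan_id,
                peptide=pep.sequence,
                proteins=",".join(pep.protein_ids),
                charge=charge,
                precursor_mz=precursor,
                total_glycan_mass=box.total_mass,
                site_assignments=assignment,
            )
        )
    return SimulatedRun(spectra, truth)


def _fasta_from(proteins):
    """Materialize an in-memory protein list as a temp FASTA-like iterable."""
    import io

    text = "".join(f">{pid}\n{seq}\n" for pid, seq in proteins)
    return io.StringIO(text)


def _noise(rng, config, peaks_mz, peaks_int, mz_hi):
    for _ in range(config.noise_peaks_per_scan):
        peaks_mz.append(float(rng.uniform(100.0, mz_hi)))
        peaks_int.append(_lognormal(rng, 0.1))


def _collisional_scan(
    rng, config, scan_id, pep, box, charge, precursor, rt
) -> Spectrum:
    prefix = _backbone_prefix(pep.sequence)
    total = prefix[-1]
    peaks_mz: list[float] = []
    peaks_int: list[float] = []
    for i in range(1, len(pep.sequence)):
        for q in (1, 2):
            b = prefix[i] / q + PROTON
            y = (total - prefix[i] + WATER) / q + PROTON
            for ion in (b, y):
                if rng.random() < config.detection_prob_by:
                    peaks_mz.append(_jitter(rng, ion, config.ppm_jitter_sd))
                    peaks_int.append(_lognormal(rng))
    if config.oxonium_emission:
        for ion in _oxonium_peaks(box.summed_composition):
            peaks_mz.append(_jitter(rng, ion, config.ppm_jitter_sd))
            peaks_int.append(_lognormal(rng, 2.0))
    # residual precursor
    peaks_mz.append(_jitter(rng, precursor, config.ppm_jitter_sd))
    peaks_int.append(_lognormal(rng, 0.5))
    _noise(rng, config, peaks_mz, peaks_int, precursor * charge)
    return Spectrum(
        scan_id, 2, "HCD",
        _jitter(rng, precursor, config.ppm_jitter_sd / 3),
        charge, rt, peaks_mz, peaks_int,
    )


def _electron_scan(
    rng, config, scan_id, pep, db, assignment, box, charge, precursor, rt
) -> Spectrum:
    prefix = _backbone_prefix(pep.sequence)
    total = prefix[-1]
    placed = {s: GlycanComposition.parse(g).mass for s, g in assignment}
    peaks_mz: list[float] = []
    peaks_int: list[float] = []
    length = len(pep.sequence)
    cumulative = 0.0
    glycan_at = np.zeros(length + 1)
    for s, m in placed.items():
        glycan_at[s] = m
    cum_glycan = np.cumsum(glycan_at)
    total_glycan = cum_glycan[-1]
    for i in range(1, length):
        c_neutral = prefix[i] + NH3 + cum_glycan[i]
        z_neutral = (total - prefix[i]) + WATER - NH3 + H_ATOM + (
            total_glycan - cum_glycan[i]
        )
        for q in (1, 2):
            for ion in (c_neutral / q + PROTON, z_neutral / q + PROTON):
                if rng.random() < config.detection_prob_cz:
                    peaks_mz.append(_jitter(rng, ion, config.ppm_jitter_sd))
                    peaks_int.append(_lognormal(rng))
    peaks_mz.append(_jitter(rng, precursor, config.ppm_jitter_sd))
    peaks_int.append(_lognormal(rng, 0.5))
    _noise(rng, config, peaks_mz, peaks_int, precursor * charge)
    return Spectrum(
        scan_id, 2, "EThcD",
        _jitter(rng, precursor, config.ppm_jitter_sd / 3),
        charge, rt, peaks_mz, peaks_int,
    )


TRUTH_COLUMNS = [
    "first_scan_id", "second_scan_id", "peptide", "proteins", "charge",
    "precursor_mz", "total_glycan_mass", "site_assignments",
]


def write_truth(truth: Sequence[GroundTruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                "\t".join(
                    [
                        str(t.first_scan_id),
                        str(t.second_scan_id),
                        t.peptide,
                        t.proteins,
                        str(t.charge),
                        f"{t.precursor_mz:.6f}",
                        f"{t.total_glycan_mass:.6f}",
                        ";".join(f"{s}:{g}" for s, g in t.site_assignments),
                    ]
                )
                + "\n"
            )


def read_truth(path: str | Path) -> list[GroundTruthRecord]:
    out = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        f = line.split("\t")
        assignment = tuple(
            (int(item.split(":")[0]), item.split(":", 1)[1])
            for item in f[7].split(";")
            if item
        )
        out.append(
            GroundTruthRecord(
                int(f[0]), int(f[1]), f[2], f[3], int(f[4]),
                float(f[5]), float(f[6]), assignment,
            )
        )
    return out


def simulate_run(config: SimulationConfig, out_dir: str | Path) -> SimulatedRun:
    """Generate a run and write FASTA, run file, and ground-truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if config.fasta is None:
        proteins = _random_proteome(rng, config)
        fasta_path = out_dir / "proteome.fasta"
        fasta_path.write_text(
            "".join(f">{pid}\n{seq}\n" for pid, seq in proteins)
        )
        config = replace(config, fasta=str(fasta_path))
    else:
        fasta_path = Path(config.fasta)
    run = build_run(config)
    suffix = "mgf" if config.output_format == "mgf" else "mzML"
    run_path = out_dir / f"run.{suffix}"
    if config.output_format == "mgf":
        write_mgf(run.spectra, run_path)
    else:
        write_mzml(run.spectra, run_path)
    truth_path = out_dir / "truth.tsv"
    write_truth(run.truth, truth_path)
    run.fasta_path = fasta_path
    run.run_path = run_path
    run.truth_path = truth_path
    return run


def make_entrapment_run(
    config: SimulationConfig, out_dir: str | Path, hexose_free: bool = True
) -> SimulatedRun:
    """Simulate a run whose true glycans (optionally) contain no hexose.

    Mirrors inhibitor-treated samples where hexose elongation is blocked:
    searched against a full database, any hexose-containing assignment is an
    entrapment, and its diagnostic hexose oxonium ions are absent from every
    collisional scan.
    """
    db = config.glycan_db or builtin_oglycan_database()
    if hexose_free:
        pool = [c for c in db if c.count("Hex") == 0]
    else:
        pool = list(db)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if config.fasta is None:
        proteins = _random_proteome(rng, config)
        fasta_path = out_dir / "proteome.fasta"
        fasta_path.write_text(
            "".join(f">{pid}\n{seq}\n" for pid, seq in proteins)
        )
        config = replace(config, fasta=str(fasta_path))
    else:
        fasta_path = Path(config.fasta)
    run = build_run(config, glycan_pool=pool)
    run_path = out_dir / ("run.mgf" if config.output_format == "mgf" else "run.mzML")
    if config.output_format == "mgf":
        write_mgf(run.spectra, run_path)
    else:
        write_mzml(run.spectra, run_path)
    truth_path = out_dir / "truth.tsv"
    write_truth(run.truth, truth_path)
    run.fasta_path = fasta_path
    run.run_path = run_path
    run.truth_path = truth_path
    return run
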