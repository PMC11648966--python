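"""Target-decoy q-values and tab-separated result tables.

The PSM table (psm.tsv) uses a fixed column schema so downstream tools can
round-trip it; a site-level summary (sites.tsv) aggregates PSMs per
(protein, site) and counts a site as confidently localized only when its
best PSM reaches level 1 or 1b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from .search import GlycoPSM

log = logging.getLogger(__name__)

__all__ = [
    "PSM_COLUMNS",
    "PsmRecord",
    "compute_qvalues",
    "psm_record",
    "write_psm_table",
    "read_psm_table",
    "summarize_sites",
]

PSM_COLUMNS = [
    "spectrum_id",
    "paired_scan_id",
    "file",
    "peptide",
    "modified_peptide",
    "protein_ids",
    "is_decoy",
    "charge",
    "precursor_mz",
    "observed_neutral_mass",
    "sequence_mass",
    "delta_mass",
    "glycan_composition",
    "n_glycans",
    "total_glycan_mass",
    "site_assignments",
    "site_probabilities",
    "n_configurations",
    "localization_level",
    "hyperscore",
    "opair_score",
    "q_value",
]


@dataclass(frozen=True)
class PsmRecord:
    """One psm.tsv row (the on-disk schema, in column order)."""

    spectrum_id: int
    paired_scan_id: int  # -1 when no localization scan
    file: str
    peptide: str
    modified_peptide: str
    protein_ids: str
    is_decoy: bool
    charge: int
    precursor_mz: float
    observed_neutral_mass: float
    sequence_mass: float
    delta_mass: float
    glycan_composition: str  # "" for non-glyco, "unassigned" if filtered out
    n_glycans: int
    total_glycan_mass: float
    site_assignments: str
    site_probabilities: str
    n_configurations: int
    localization_level: str
    hyperscore: float
    opair_score: float
    q_value: float


def compute_qvalues(psms: Sequence[GlycoPSM]) -> list[GlycoPSM]:
    """Assign target-decoy q-values in place; returns PSMs sorted by score.

    FDR(s) = #decoys with score >= s / max(1, #targets with score >= s);
    q-values are the running minimum taken from the worst score upward.
    """
    ordered = sorted(psms, key=lambda p: -p.hyperscore)
    n_decoys = sum(1 for p in ordered if p.peptide.is_decoy)
    if n_decoys == 0 and ordered:
        log.warning("no decoy PSMs present; all q-values set to 0")
        for p in ordered:
            p.q_value = 0.0
        return ordered
    n_t = n_d = 0
    fdrs = []
    for p in ordered:
        if p.peptide.is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(n_d / max(1, n_t))
    running = float("inf")
    for i in range(len(ordered) - 1, -1, -1):
        running = min(running, fdrs[i])
        ordered[i].q_value = running
    return ordered


def _site_label(peptide_seq: str, site: int) -> str:
    return f"{peptide_seq[site - 1]}{site}"


def psm_record(psm: GlycoPSM, file: str = "") -> PsmRecord:
    """Flatten a searched/localized PSM into the table schema."""
    loc = psm.localization
    seq = psm.peptide.sequence
    if psm.is_glyco:
        if loc is not None and loc.best_assignment:
            box = getattr(psm, "selected_box", None)
            composition = str(box) if box is not None else ""
            assignments = ";".join(
                f"{_site_label(seq, s)}:{g}" for s, g in loc.best_assignment
            )
            probs = ";".join(
                f"{_site_label(seq, s)}:{g}:{p:.4f}"
                for s, g, p in loc.site_probabilities
            )
            n_glycans = sum(1 for _ in loc.best_assignment)
            total_mass = box.total_mass if box is not None else psm.delta_mass
        else:
            composition = "unassigned"
            assignments = ""
            probs = ""
            n_glycans = 0
            total_mass = psm.delta_mass
    else:
        composition = ""
        assignments = ""
        probs = ""
        n_glycans = 0
        total_mass = 0.0
    return PsmRecord(
        spectrum_id=psm.pair.first_scan.scan_id,
        paired_scan_id=(
            psm.pair.second_scan.scan_id if psm.pair.second_scan is not None else -1
        ),
        file=file,
        peptide=seq,
        modified_peptide=psm.peptide.modified_sequence,
        protein_ids=",".join(psm.peptide.protein_ids),
        is_decoy=psm.peptide.is_decoy,
        charge=psm.charge,
        precursor_mz=round(psm.pair.first_scan.precursor_mz, 6),
        observed_neutral_mass=round(psm.observed_neutral_mass, 6),
        sequence_mass=round(psm.peptide.sequence_mass, 6),
        delta_mass=round(psm.delta_mass, 6),
        glycan_composition=composition,
        n_glycans=n_glycans,
        total_glycan_mass=round(total_mass, 6),
        site_assignments=assignments,
        site_probabilities=probs,
        n_configurations=loc.n_configurations if loc is not None else 0,
        localization_level=loc.level if loc is not None else "",
        hyperscore=round(psm.hyperscore, 6),
        opair_score=loc.opair_score if loc is not None else 0.0,
        q_value=psm.q_value,
    )


def write_psm_table(records: Sequence[PsmRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__")
                       else {f.name: getattr(r, f.name) for f in dc_fields(r)}
                       for r in records], columns=PSM_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column {missing[0]!r}")
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        out.append(
            PsmRecord(
                spectrum_id=int(d["spectrum_id"]),
                paired_scan_id=int(d["paired_scan_id"]),
                file=d["file"],
                peptide=d["peptide"],
                modified_peptide=d["modified_peptide"],
                protein_ids=d["protein_ids"],
                is_decoy=d["is_decoy"] in ("True", "true", "1"),
                charge=int(d["charge"]),
                precursor_mz=float(d["precursor_mz"]),
                observed_neutral_mass=float(d["observed_neutral_mass"]),
                sequence_mass=float(d["sequence_mass"]),
                delta_mass=float(d["delta_mass"]),
                glycan_composition=d["glycan_composition"],
                n_glycans=int(d["n_glycans"]),
                total_glycan_mass=float(d["total_glycan_mass"]),
                site_assignments=d["site_assignments"],
                site_probabilities=d["site_probabilities"],
                n_configurations=int(d["n_configurations"]),
                localization_level=d["localization_level"],
                hyperscore=float(d["hyperscore"]),
                opair_score=float(d["opair_score"]),
                q_value=float(d["q_value"]),
            )
        )
    return out


LEVEL_ORDER = {"1": 0, "1b": 1, "2": 2, "3": 3, "": 4}


def summarize_sites(records: Sequence[PsmRecord]) -> pd.DataFrame:
    """Aggregate localized PSMs into one row per (protein, site).

    Only levels 1 and 1b count as confident localization; a PSM contributes
    every site in its best assignment.
    """
    rows: dict[tuple[str, str], dict] = {}
    for rec in records:
        if not rec.site_assignments:
            continue
        proteins = rec.protein_ids.split(",")
        for item in rec.site_assignments.split(";"):
            site_label, _, glycan = item.partition(":")
            for protein in proteins:
                key = (protein, site_label)
                entry = rows.setdefault(
                    key,
                    {
                        "protein": protein,
                        "site": site_label,
                        "psm_count": 0,
                        "glycan_compositions": set(),
                        "best_level": "",
                    },
                )
                entry["psm_count"] += 1
                entry["glycan_compositions"].add(glycan)
                if (
                    entry["best_level"] == ""
                    or LEVEL_ORDER[rec.localization_level]
                    < LEVEL_ORDER[entry["best_level"]]
                ):
                    entry["best_level"] = rec.localization_level
    table = [
        {
            "protein": e["protein"],
            "site": e["site"],
            "psm_count": e["psm_count"],
            "glycan_compositions": ",".join(sorted(e["glycan_compositions"])),
            "best_level": e["best_level"],
            "confidently_localized": e["best_level"] in ("1", "1b"),
        }
        for e in rows.values()
    ]
    df = pd.DataFrame(
        table,
        columns=[
            "protein",
            "site",
            "psm_count",
            "glycan_compositions",
            "best_level",
            "confidently_localized",
        ],
    )
    return df.sort_values(["protein", "site"]).reset_index(drop=True)
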