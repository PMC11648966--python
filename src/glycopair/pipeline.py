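"""Workflow configuration and end-to-end orchestration.

Stage order: digest -> read runs -> pair scans -> per-pair search ->
oxonium filter -> glycan-box selection + localization -> target-decoy
q-values -> psm.tsv + sites.tsv.  Configuration lives in a key=value text
file (``#`` comments); unknown or duplicate keys are rejected so typos
cannot silently change a search.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .digestion import (
    ACETYL,
    DEAMIDATION,
    OXIDATION,
    DigestionSpec,
    VariableMod,
    digest,
)
from .glycans import GlycanDatabase, builtin_oglycan_database, parse_glycan_database
from .localization import select_best_box
from .reporting import (
    compute_qvalues,
    psm_record,
    summarize_sites,
    write_psm_table,
)
from .search import (
    PeptideIndex,
    SearchParams,
    default_oxonium_rules,
    parse_oxonium_rules,
    precompute_offset_index,
    search_pair,
)
from .spectra import pair_scans, read_run

log = logging.getLogger(__name__)

__all__ = ["WorkflowConfig", "load_workflow", "run_workflow", "default_variable_mods"]


def default_variable_mods() -> tuple[VariableMod, ...]:
    return (
        VariableMod("M", OXIDATION, 3, "oxidation"),
        VariableMod("NQ", DEAMIDATION, 1, "deamidation"),
        VariableMod("prot_nterm", ACETYL, 1, "acetyl"),
    )


@dataclass
class WorkflowConfig:
    fasta: str = ""
    run_files: tuple[str, ...] = ()
    glycan_db: str = "builtin"
    oxonium_rules: str = "default"  # default | none | <path>
    precursor_tol_ppm: float = 30.0
    product_tol_ppm: float = 10.0
    max_glycans: int = 5
    oxonium_min_intensity: float = 0.05
    prob_threshold: float = 0.75
    weighting_base: float = 10.0
    fdr: float = 0.01
    pairing_mode: str = "hcd_first"  # hcd_first | etd_first | single_scan
    require_same_charge: bool = True
    enzyme: str = "trypsin"
    specificity: str = "full"
    max_missed_cleavages: int = 2
    min_peptide_length: int = 5
    max_peptide_length: int = 40
    variable_mods: bool = False
    decoy_mode: str = "reverse"
    output_dir: str = "glycopair_out"

    def digestion_spec(self) -> DigestionSpec:
        return DigestionSpec(
            enzyme=self.enzyme,
            specificity=self.specificity,
            max_missed_cleavages=self.max_missed_cleavages,
            peptide_length_range=(self.min_peptide_length, self.max_peptide_length),
            variable_mods=default_variable_mods() if self.variable_mods else (),
        )

    def search_params(self) -> SearchParams:
        return SearchParams(
            precursor_tol_ppm=self.precursor_tol_ppm,
            product_tol_ppm=self.product_tol_ppm,
            max_glycans=self.max_glycans,
        )

    def load_glycan_db(self) -> GlycanDatabase:
        if self.glycan_db == "builtin":
            return builtin_oglycan_database()
        return parse_glycan_database(self.glycan_db)

    def load_rules(self):
        if self.oxonium_rules == "default":
            return default_oxonium_rules(self.oxonium_min_intensity)
        if self.oxonium_rules == "none":
            return []
        return parse_oxonium_rules(self.oxonium_rules)


_BOOL_KEYS = {"require_same_charge", "variable_mods"}
_INT_KEYS = {
    "max_glycans",
    "max_missed_cleavages",
    "min_peptide_length",
    "max_peptide_length",
}
_FLOAT_KEYS = {
    "precursor_tol_ppm",
    "product_tol_ppm",
    "oxonium_min_intensity",
    "prob_threshold",
    "weighting_base",
    "fdr",
}


def load_workflow(path: str | Path, **overrides) -> WorkflowConfig:
    """Load a key=value workflow file; keyword arguments override it."""
    known = {f.name for f in dataclasses.fields(WorkflowConfig)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in values:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        if key == "run_files":
            values[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        elif key in _BOOL_KEYS:
            values[key] = value.lower() in ("1", "true", "yes", "on")
        elif key in _INT_KEYS:
            values[key] = int(value)
        elif key in _FLOAT_KEYS:
            values[key] = float(value)
        else:
            values[key] = value
    values.update({k: v for k, v in overrides.items() if v is not None})
    return WorkflowConfig(**values)


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute the full paired-scan workflow; returns paths and PSMs."""
    if not config.fasta:
        raise ValueError("config error: no FASTA given")
    if not Path(config.fasta).exists():
        raise ValueError(f"config error: FASTA not found: {config.fasta}")
    if not config.run_files:
        raise ValueError("config error: no run files given")
    for rf in config.run_files:
        if not Path(rf).exists():
            raise ValueError(f"config error: run file not found: {rf}")
    if config.glycan_db != "builtin" and not Path(config.glycan_db).exists():
        raise ValueError(f"config error: glycan database not found: {config.glycan_db}")
    log.info("resolved config: %s", config)

    db = config.load_glycan_db()
    rules = config.load_rules()
    log.info("glycan database: %d compositions; %d oxonium rules", len(db), len(rules))

    candidates = digest(config.fasta, config.digestion_spec(), config.decoy_mode)
    peptides = PeptideIndex(candidates)
    log.info("digest: %d peptide candidates (targets+decoys)", len(peptides))

    offsets = precompute_offset_index(db, config.max_glycans)
    log.info("offset index: %d unique combined glycan masses", len(offsets.masses))

    params = config.search_params()
    all_psms = []
    records = []
    for run_file in config.run_files:
        run = read_run(run_file)
        pairs = pair_scans(
            run,
            config.pairing_mode,
            config.precursor_tol_ppm,
            config.require_same_charge,
        )
        log.info(
            "%s: %d scans read, %d pairs formed", run_file, len(run), len(pairs)
        )
        psms = []
        for pair in pairs:
            psm = search_pair(pair, peptides, offsets, params)
            if psm is None:
                continue
            if psm.is_glyco:
                box, result = select_best_box(
                    pair,
                    psm.peptide,
                    psm.candidate_boxes,
                    rules,
                    params,
                    config.weighting_base,
                    config.prob_threshold,
                )
                psm.selected_box = box
                psm.localization = result
            psms.append(psm)
        log.info("%s: %d PSMs", run_file, len(psms))
        all_psms.extend((run_file, p) for p in psms)

    compute_qvalues([p for _, p in all_psms])
    accepted = [
        (rf, p)
        for rf, p in all_psms
        if not p.peptide.is_decoy and p.q_value <= config.fdr
    ]
    levels = Counter(
        p.localization.level
        for _, p in accepted
        if p.localization is not None
    )
    log.info(
        "%d/%d PSMs accepted at q<=%g; level histogram: %s",
        len(accepted), len(all_psms), config.fdr, dict(sorted(levels.items())),
    )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = [psm_record(p, file=rf) for rf, p in accepted]
    psm_path = out_dir / "psm.tsv"
    write_psm_table(records, psm_path)
    sites = summarize_sites(records)
    sites_path = out_dir / "sites.tsv"
    sites.to_csv(sites_path, sep="\t", index=False)
    log.info(
        "wrote %s (%d rows) and %s (%d sites, %d confident)",
        psm_path, len(records), sites_path, len(sites),
        int(sites["confidently_localized"].sum()) if len(sites) else 0,
    )
    return {
        "psm_tsv": psm_path,
        "sites_tsv": sites_path,
        "psms": [p for _, p in accepted],
        "all_psms": [p for _, p in all_psms],
        "records": records,
        "level_histogram": dict(levels),
    }
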