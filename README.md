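# glycopair

Paired-scan O-glycopeptide identification and site localization.

## The problem

O-glycans are attached to serine and threonine with no consensus sequence
motif, so every S/T in a peptide is a potential glycosite, and a peptide may
carry several glycans at once. Under collisional activation (HCD) the
glycosidic bonds are labile: the glycans fall off, the backbone fragments as
naked b/y ions, and diagnostic low-mass oxonium ions appear. Under
electron-based activation (ETD/EThcD/EAD) the backbone fragments as c/z•
ions with the glycans still attached to their sites. Modern acquisitions
therefore pair the two: an HCD scan that identifies the peptide, and a
product-dependent EThcD scan of the same precursor that localizes the
glycans.

A conventional search that enumerates every placement of every glycan
combination on every site faces a combinatorial explosion: with a 32-glycan
database, a peptide with 8 glycosites has C(40, 8) − 1 = 76,904,684
configurations. `glycopair` instead searches *peptide-first*: the collisional
scan is matched against naked-peptide b/y ions with the **total** glycan
mass treated as a precursor mass offset (only the distinct summed masses of
glycan multisets matter — hundreds, not millions), and the glycan "box" is
deconvoluted onto sites afterwards using only the electron scan.

## The method

- **Scan pairing.** Within each block of MS2 scans bounded by MS1 survey
  scans, each collisional scan is greedily paired with the earliest
  subsequent electron-activation scan whose precursor m/z (and charge)
  matches within tolerance. ETD-first and single-scan (EThcD/EAD-only)
  modes are supported.
- **Peptide-first search.** Candidates come from in-silico digestion
  (trypsin or the mucinase StcE, full or semi-specific, reversed-protein
  decoys, variable modifications). A candidate is considered when its mass
  equals the observed neutral precursor mass minus zero or one combined
  glycan-box mass, and is ranked by an X!Tandem-style hyperscore
  ln(n_b!) + ln(n_y!) + ln(Σ I_b · Σ I_y) over matched naked b/y ions.
- **Oxonium filtering.** A rule file ties residue content to required
  diagnostic ions (e.g. hexose ⇒ 163.0601/145.0495 at ≥ 5% summed
  base-peak-relative intensity in the collisional scan); glycan boxes whose
  content violates an applicable rule are never assigned.
- **Graph DP localization.** For a peptide of length L with glycan box B,
  the localization graph has nodes (i, c), c ⊆ B the glycans placed on
  sites ≤ i. Node (i, c) scores the matched c-ion of length i carrying
  mass(c) and z•-ion of length L−i carrying mass(B∖c) (1+/2+). Each
  root-to-sink path is one configuration with weight 10^(Σ node scores);
  exact per-(site, glycan) probabilities come from forward–backward
  accumulation (integer arithmetic — no floating-point drift, no path
  enumeration). Confidence levels: **1** all glycans localized (P > 0.75)
  with fragment evidence, **1b** localized by elimination, **2** some
  localized, **3** none.
- **FDR and reporting.** Classical target-decoy q-values
  (FDR(s) = #decoys≥s / #targets≥s, monotonized), a fixed-schema `psm.tsv`,
  and a per-(protein, site) `sites.tsv` where only levels 1/1b count as
  confidently localized.
- **Simulation.** A ground-truth generator emulates the paired acquisition
  (jitter, peak dropout, noise peaks, oxonium emission) so the whole
  pipeline is testable end to end without any external data.

## Worked example

```python
import numpy as np
from glycopair import GlycanBox, builtin_oglycan_database
from glycopair.chem import NH3, PROTON, AA_RESIDUE_MASS
from glycopair.digestion import PeptideCandidate
from glycopair.localization import build_graph, localize
from glycopair.spectra import Spectrum

db = builtin_oglycan_database()
hexnac = next(i for i, c in enumerate(db) if str(c) == "HexNAc(1)")
pep = PeptideCandidate("GASTAK", ("DEMO",))
box = GlycanBox.from_indices(db, [hexnac])

def c_ion(seq, i, g=0.0):
    return sum(AA_RESIDUE_MASS[a] for a in seq[:i]) + NH3 + g + PROTON

ions = [c_ion("GASTAK", 2), c_ion("GASTAK", 3, db[hexnac].mass),
        c_ion("GASTAK", 4, db[hexnac].mass)]
scan = Spectrum(1, 2, "EThcD", 500.0, 2, 0.0, ions, np.ones(3))
res = localize(build_graph(pep, box, scan))
print(res.level, res.best_path_score, res.site_probabilities)
```

prints

```
1 3 ((3, 'HexNAc(1)', 0.9090909090909091), (4, 'HexNAc(1)', 0.09090909090909091))
```

GASTAK has two candidate sites, S3 and T4. The spectrum's glycosylated c3
ion is explained only by placement on S3 (3 matched ions vs 2), so S3 is
favored 10^3 : 10^2 — probability 10/11 ≈ 0.909 > 0.75, confidence level 1.
The scripts in `examples/` walk through combinatorics, simulation and
pairing, single-spectrum localization, and the full workflow; the
`glycopair` command exposes the same stages as subcommands
(`simulate`, `pair-scans`, `search`, `localize`, `run`, `report`).

## File formats

- **Runs**: mzML (centroided) or MGF with `ACTIVATION=` and `MSLEVEL=`
  header tags.
- **Glycan database**: one Byonic-style composition per line
  (`HexNAc(2)Hex(1)`), optional ` % mass` check, `#` comments. Built-in
  residues: HexNAc, Hex, Fuc, NeuAc, NeuGc, Phospho, Sulfo; extensible via
  a `name<TAB>formula` TSV.
- **Oxonium rules**: `residues<TAB>mz1,mz2,…<TAB>min_rel_intensity`.
- **Workflow config**: `key=value` lines, `#` comments; unknown or
  duplicate keys are rejected.
- **psm.tsv / sites.tsv**: tab-separated, fixed documented schemas
  (see `glycopair.reporting.PSM_COLUMNS`).

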