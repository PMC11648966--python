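"""Simulate a paired HCD/EThcD glycopeptide run and reconstruct the pairs.

The simulator writes an MGF with interleaved MS1 scans, a collisional scan
(naked b/y ladder + oxonium ions) and an electron-activation scan (c/z
ladder with glycans attached) per glycopeptide, plus a ground-truth table.
"""

import tempfile

from glycopair import SimulationConfig, pair_scans, read_run, simulate_run

out_dir = tempfile.mkdtemp(prefix="glycopair_demo_")
config = SimulationConfig(seed=42, n_glycopeptides=10)
run = simulate_run(config, out_dir)

print("run file:   ", run.run_path)
print("ground truth:", run.truth_path)

spectra = read_run(run.run_path)
pairs = pair_scans(spectra, "hcd_first", precursor_tol_ppm=30)
complete = [p for p in pairs if p.second_scan is not None]
print(f"{len(spectra)} scans -> {len(complete)} HCD/EThcD pairs")

t = run.truth[0]
print("first simulated glycopeptide:")
print("  peptide:", t.peptide, f"({t.charge}+ at m/z {t.precursor_mz:.4f})")
print("  true glycans:", t.assignment_string())
# Each pair shares a precursor within tolerance and sits between two MS1
# scans; the truth table links scan ids to the planted site assignments.
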