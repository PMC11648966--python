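# Methods

## Model and assumptions

`glycopair` analyzes paired tandem-MS scans of O-glycopeptides under two
assumptions grounded in glycopeptide fragmentation chemistry:

1. **Collisional activation sheds O-glycans.** The identification scan is
   modeled as the naked peptide's b/y ladder plus glycan oxonium ions and a
   precursor residual. The glycans contribute to the precursor mass but not
   to backbone fragment masses.
2. **Electron-based activation retains O-glycans.** The localization scan is
   modeled as a c/z• ladder in which each fragment carries exactly the
   glycans attached N-terminal (for c) or C-terminal (for z•) of the
   cleavage site.

Glycans are treated as compositions (multisets of monosaccharide residues);
topology is never inferred. Every S/T residue is a candidate site. The
multiset of database glycans on one peptide (the *glycan box*) is the unit
of deconvolution: search constrains only its total mass, localization
distributes its members over sites.

## Mass arithmetic

Element and amino-acid monoisotopic masses come from `pyteomics.mass`;
proton = 1.007276 Da, water = 18.010565 Da. Monosaccharide residue masses
are always derived from elemental formulas (HexNAc = C8H13NO5, Hex =
C6H10O5, Fuc = C6H10O4, NeuAc = C11H17NO8, NeuGc = C11H17NO9, Phospho =
HPO3, Sulfo = SO3), never hard-coded; the printed diagnostic-ion values
(Hex⁺ 163.0601, [Hex−H₂O]⁺ 145.0495, [HexNAc+Hex]⁺ 366.1395, NeuAc⁺
292.1027/274.0921, NeuGc⁺ 308.0976/290.0870) serve as regression checks.
Ion conventions: b = Σ residues + H⁺; y = b-complement + H₂O; c = b + NH₃;
z• = y − NH₃ + H. Product charges 1+ and 2+ are considered throughout.

## Scan pairing

MS1 scans delimit blocks. Within a block, scans of the first activation
type are paired greedily with the earliest subsequent unpaired scan of the
second type whose precursor m/z agrees within the precursor tolerance
(default 30 ppm) and, by default, whose charge agrees when both are known.
Greedy earliest-match was chosen because product-dependent acquisition
places the triggered scan immediately after its trigger; the charge
requirement is a flag because acquisition software does not always record
charge on the triggered scan. A first-type scan left unpaired is retained
with no localization scan (rather than dropped): it can still be
identified, and its localization simply has no electron-scan evidence —
this is what reproduces the empirical pattern that collisional-only data
yields level-3 localizations for multi-site peptides.

## Search

Digestion supports trypsin (C-terminal to K/R, by default not before P)
and StcE (N-terminal to every S/T, since glycosylation state is unknowable
in silico), full or semi-specific, with a configurable missed-cleavage
budget, length range (default 5–40), and variable modifications
(default set when enabled: oxidation M ×3, deamidation N/Q ×1, protein
N-terminal acetyl). Decoys are reversed proteins; decoy peptides colliding
with a target sequence are discarded to keep the sets disjoint. A candidate
cap (default 5×10⁶ modified peptides) guards the semi-specific explosion.

The offset index groups all glycan boxes of size 1..max_glycans (default 5)
by combined mass rounded to 4 decimals (≈0.1 mDa, matching the precision of
printed reference ions). For an observed neutral precursor mass M, every
candidate with mass within tolerance of M or of M − offset is scored by the
hyperscore ln(n_b!) + ln(n_y!) + ln(ΣI_b · ΣI_y) with factorials capped at
n = 10 and score 0 when either matched-intensity sum is zero. Glycan-offset
explanations require ≥ 1 candidate site and box size ≤ site count. Ties
break toward fewer glycans, then lexicographic peptide, making results
independent of candidate enumeration order.

## Oxonium filtering

A rule (residue requirement → ion list → minimum summed base-peak-relative
intensity) applies to a box when the box's summed composition contains the
required residues. All applicable rules must pass, evaluated on the
identification scan only — the collisional scan is where oxonium ions are
generated. The default rule set requires, at 5%: 366.1395 for
HexNAc+Hex-containing boxes; 163.0601/145.0495 for Hex; 274.0921/292.1027
for NeuAc; 290.0870/308.0976 for NeuGc. Filtering is a spectrum-quality
gate, not a glycan-level FDR.

## Localization

For peptide length L and box B, the graph's nodes are (i, c) with c the
sub-multiset placed on sites ≤ i; edges keep c or, at a candidate site, add
one remaining glycan; nodes that cannot be completed (too many glycans
placed, or too few sites remaining) are pruned. Node (i, c), 0 < i < L, is
scored by counting matched scan peaks among four theoretical ions: c_i and
z•_(L−i) carrying mass(c) and mass(B∖c) respectively, at 1+/2+ within the
product tolerance (default 10 ppm). A path's score is the sum of its node
scores, and its weight is base^score with base 10.

Why base 10: a single additional site-determining ion then shifts a
two-way comparison to 10:1 — probability 0.909 — comfortably above the
0.75 reporting threshold, so "one discriminating fragment ⇒ confident
site" holds by construction. The base is configurable.

Site probabilities are computed by forward–backward accumulation over the
graph. Because integer bases give integer path weights, the arithmetic
uses Python integers and exact fractions: probabilities are exact, and the
dynamic program is bit-identical to brute-force enumeration (this is
asserted over randomized instances in the tests). The best assignment is
the max-score path with deterministic lexicographic tie-breaking.

A *site-determining ion* is a matched ion at a position where the attached
glycan mass differs between feasible configurations. Confidence levels:

- **1** — every glycan instance has a site with P > 0.75 and at least one
  site-determining ion was matched on the best path;
- **1b** — every instance localized but by elimination: only one feasible
  configuration, or zero site-determining ions matched;
- **2** — at least one, but not all, instances localized;
- **3** — none localized.

The level-1b boundary (treating "some forced, some evidenced" cases as 1
when the evidenced ones have matched site-determining ions, and 1b only
when localization is entirely elimination-based) is a design choice; the
threshold and base are parameters, and the reported per-site probabilities
let users apply their own cutoffs.

When several boxes match the delta mass and pass the oxonium filter, each
is localized on the electron scan and the highest best-path score wins
(ties: fewer glycans, then canonical composition text). If all boxes are
filtered out, the PSM is kept with its total glycan mass only, composition
"unassigned", level 3.

## FDR

Classical target-decoy estimation: sort by hyperscore, FDR(s) =
#decoys≥s / max(1, #targets≥s), q-values as the running minimum from the
bottom, acceptance at q ≤ 0.01 by default. This replaces semiparametric
PSM rescoring deliberately: it is self-contained, assumption-light and
directly testable by planted-truth simulation. With no decoys present all
q-values are 0 and a warning is logged. Calibration is verified in the
tests: with false targets and decoys drawn from the same null, the mean
empirical false discovery proportion of the accepted set over 20 seeds
stays within 2×.

## Simulator

The generator emulates product-dependent paired acquisition on a random
(or user-supplied) proteome: tryptic peptides (full-specific, ≤ 2 missed
cleavages, length 6–30, ≥ 1 S/T), each S/T occupied with probability 0.35
(at least one; at most `max_glycans_per_peptide`, default 3), glycans drawn
uniformly from the database (default: a 12-composition core-1/core-2 human
O-glycan set), charge from {2, 3, 4} weighted 2:2:1 as typical for tryptic
O-glycopeptides. Defaults: fragment detection probability 0.9 per ion,
5 ppm m/z jitter, 30 uniform noise peaks per scan, log-normal (σ = 0.5)
relative intensities with oxonium ions emitted at double scale. All
randomness flows from a single seed; output is byte-reproducible.

What the simulator does *not* model — chromatographic peak shape, isotope
envelopes, co-isolation chimeras, charge-reduced ETD species, neutral
losses, intensity structure along the ladder — bounds what passing tests
show: they validate the algorithms' correctness and calibration under the
stated fragmentation model, not performance on instrument data, where
spectrum quality and co-isolation dominate.

## Problem sizes and numerical choices

The test suite exercises the pipeline at sizes chosen to make the checks
statistically meaningful while staying desk-scale: a 500-glycopeptide
noise-free run for recovery, 150 glycopeptides for entrapment, 200+
randomized instances for DP-oracle parity, 20 seeds × 1,700 PSMs for FDR
calibration. Combined-mass uniqueness uses 4-decimal rounding; peak
matching uses ppm windows via binary search on sorted peak arrays; all
tie-breaks (search ranking, best path, box selection) are deterministic and
documented above, so identical inputs yield byte-identical outputs.

## Known limitations

- Compositions only; no glycan topology, no glycan-level FDR.
- No deisotoping, charge deconvolution or mass calibration: input is
  assumed centroided and deisotoped.
- Localization uses c/z• ions only (no hybrid b/y co-scoring in
  single-scan EThcD mode).
- Semi-specific + StcE + high missed-cleavage searches can exceed the
  candidate cap on large proteomes; the cap fails fast with guidance
  rather than degrading silently.
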