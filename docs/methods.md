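# Methods

## Scope and data model

`httxl` consumes *identified* crosslinks: one row per crosslinked
peptide-spectrum match (PSM) with the xQuest-style confidence metrics
and absolute 1-based residue positions in the Q23 reference numbering
(3144 residues). Spectral matching, site localization and FDR
estimation are upstream concerns: the score cut-off (17) stands in for
the search engine's FDR control, and rows whose required fields do not
parse are reported, never silently dropped. All residue intervals in
the package are 1-based inclusive, including the BED-like partition
export (documented in its header, since standard BED is 0-based
half-open).

## Identification filters

A PSM survives iff it satisfies every criterion. Comparisons follow
the stated thresholds exactly: mass error is a strict bound
(|error| < 4 ppm), delta score a strict bound (< 0.9), the rest
inclusive (length ≥ 6, %TIC ≥ 0.1, cleavages ≥ 4, score ≥ 17).
Filtering is monotone in each threshold and idempotent; both are
property-tested. Surviving PSMs collapse to unordered residue pairs
(min, max) with a support count; self-links carry no distance
information and are returned separately.

## Contact categories and allelic comparison

Sequence separation is |j − i| in Q23 numbering with no renumbering
for other tract lengths. Categories partition all separations:
short ≤ 200 < mid ≤ 1000 < long. The thresholds are configurable to
allow sensitivity analysis; the defaults are the conventional ones for
this analysis. Allelic comparison is exact set algebra on residue
pairs — valid only because all alleles share one coordinate frame —
and the counting unit is the unique residue pair, not the PSM.
No significance test is attached to overlap counts; there is no
agreed null model for crosslink networks, and we do not invent one.

## Domain partition and UCD detection

The five-domain partition is assembled from landmarks: NTD-I ends at
the minor protease site (500), NTD-II at the hinge midpoint (the
1184–1254 interval is operationalized as its rounded midpoint, 1219,
because a partition needs a single boundary), CTD-I at the start of
the crosslink-depleted span, the UCD at its end, and CTD-II at the
chain end. The partition always covers the chain exactly once.

The UCD is detected, not assumed. The involvement profile counts, for
each residue r, contact endpoints within a centered window
[r − w, r + w] (half-width w, default 25 residues; both endpoints of a
pair are counted, so short-range pairs contribute locally twice). By
default only short- and mid-range links feed the profile, since the
depletion claim concerns local folding, and long-range contacts into
the span would otherwise mask it. Candidate regions are maximal runs
with involvement ≤ 1 (one stray endpoint within a window is not
evidence of folding), at least 300 residues long, containing at least
3 lysines. A lysine-free stretch carries no evidence in either
direction, so each reported boundary is placed at the midpoint of the
uninformative gap between the run's raw edge and the outermost lysine
inside the run; the reported interval therefore never overlaps a
residue whose involvement exceeds the threshold. When detection is
skipped (e.g. no lysine positions available), the configured default
span 1800–2300 is used.

## Envelope geometry

`envelope_volume` provides the closed forms (π/6·d³ for a sphere,
π/6·a·b·c for a full-axis ellipsoid). A *measured* envelope volume is
always accepted as a direct input and takes precedence over the
nominal shape: the Matthews coefficient V_M = V/M and cavity fraction
1 − 1.23/V_M are computed from the measurement of record, never from a
silent recomputation (the closed-form sphere volume for a 115 Å
diameter, ≈796,328 Å³, differs from the measured 861,829 Å³ envelope —
both are available, and the code never substitutes one for the other).
The protein-only value 1.23 Å³/Da is a named, overridable constant.
Reported percentages round half-up to integer percent.

## CD analysis

MRE(λ) = θ(λ)·MRW/(10·l·c) with MRW = M/(n − 1) (per-peptide-bond
convention, the standard choice when the chain length is known).
Helicity trend: least-squares slope of MRE at 222 nm against polyQ
length plus Spearman rank correlation; an "incremental effect" is
flagged when the rank correlation is perfectly monotone. With two
replicates per allele both replicate values enter the regression
rather than being averaged, since n = 2 makes a SEM weakly defined.

Melt summaries read a 25–95 °C, 5 °C-step grid at 222 nm. The onset is
the first grid temperature whose MRE deviates from the
first-temperature baseline by more than 5% of the baseline magnitude
(configurable); the grid step is the resolution of this read, so an
onset of 45 °C means "stable up to 40 °C". The denaturation span runs
from the onset to the later of the two slope-change elbows (arrival at
the denatured plateau). The irreversibility index is the mean absolute
heating–cooling MRE gap over shared grid temperatures; zero means the
cooling curve retraces heating. No secondary-structure deconvolution
is performed: there is no reference basis set of HEAT-repeat proteins
with known structures against which a deconvolution would be reliable.

## Synthetic-data generator

The generator is first-class, tested code; it supplies ground truth
for every stage.

**Bead model.** One bead per residue, ~3.8 Å contour spacing (bond
lengths kept within 2.5–4.5 Å, checked). The chain is laid on nested
spherical shells inside a 115 Å outer diameter with a hollow core
(no bead within 35 Å of the center): the NTD arm spirals down an outer
shell from near the north pole to the hinge latitude; CTD-I spirals up
and back on an inner shell; the UCD crosses a ≥30 Å buffer gap onto a
separated south-polar cap; CTD-II returns on a middle shell to a
northern band, placing the carboxyl terminus near the amino terminus
(arm ends in proximity) and the amino terminus at the particle surface
(it is antibody-accessible in the emulated system). Piece arc lengths
are tuned numerically (Brent's method on the turn count) so bead
spacing is uniform. The geometry is a plausibility construction — a
hollow solenoid with correct adjacencies — not a fold prediction; no
self-avoidance, energetics or HEAT-repeat geometry is modeled, so
passing tests demonstrate recovery of *planted* architecture, not
accuracy on real huntingtin.

**Lysines.** Without a sequence, lysines are placed uniformly at
huntingtin-like density (3%) outside the UCD. Inside the UCD they are
planted deterministically: both ends of the span are anchored and the
interior filled by farthest-point greedy selection with a mutual
spacing of cutoff + 2 Å, so the span contains several lysines but
essentially no lysine pair within DSS reach — the depletion the
detector must find. (One edge-to-edge pair can sit just under the
cutoff where the cap entry and exit rims approach each other; it is a
single mid-range link at the span boundary and does not affect
detection.) A real sequence can be supplied instead, in which case the
mask is taken verbatim.

**Observation model.** True links are lysine pairs within the cutoff
(default 30 Å Cα–Cα: the 11.4 Å DSS spacer plus two extended lysine
side chains — a standard structural-validation bound, treated as a
documented parameter). Each is detected with probability 0.7 and
supported by ~1.6 PSMs whose attributes are drawn from a passing
regime (score N(28, 5), mass error N(0, 1.5) ppm, …); decoys are drawn
uniformly from beyond-cutoff pairs at 0.15 per detected true pair with
attributes from a failing regime (score N(11, 3), delta U(0.4, 1.05),
…). Under these conditions ~98% of detected true links survive the
filters and <5% of decoys do; these rates are measured, not asserted.

**Allelic perturbation.** The tract-length effect is modeled as a
rotation of the CTD-II band toward the CTD-I latitudes (30° at full
scale) with a 6 Å radial approach, and a 10°/3 Å displacement of
NTD-I away from CTD-I, both linear in the normalized tract length
(0 at Q2, 1 at Q78). Displaced pieces are regenerated with re-tuned
arc lengths rather than transformed pointwise, preserving bond
geometry exactly; the lysine mask is allele-invariant (same protein).
No quantitative magnitude for the real conformational shift is
available, so the scale is a free parameter chosen to make the
directional effect clearly detectable through the noisy observation
model; recovery tests are directional only.

**CD synthesis.** The helix template is an empirical three-Gaussian
curve with minima exactly at 208 and 222 nm and a positive 195 nm
peak, scaled by a helicity level and converted to raw millidegrees
with the cell metadata. Melts are flat to the onset, then a raised
cosine to a denatured plateau (−20,000 → −2,000 deg·cm²/dmol by
default) completing at 2·midpoint − onset; cooling retraces only
1 − f of the transition for irreversible fraction f. Measurement noise
defaults to 50 MRE units, typical of an averaged scan.

## Orchestration and reproducibility

A single `RunConfig` (YAML-loadable, unknown keys rejected) drives the
pipeline; exactly one crosslink source (tables or simulation) must be
configured. All randomness derives from the run seed through
`numpy.random.SeedSequence` with fixed per-stage keys, so the JSON
summary is byte-identical across repeated runs; the summary embeds a
config hash (excluding output location), the seed and library
versions. Every table in the report also exists as CSV; figures are
optional and degrade to text with a warning on failure.

Default problem sizes — the full 3144-residue chain, three alleles,
ten seeded replicates in the recovery analyses — run in seconds, so no
reduced modes are needed.

## Known limitations

* The generator's geometry, perturbation magnitudes, detection
  probability and decoy rates are stylized; real XL-MS data add
  site-localization ambiguity, digestion bias, isotope-pair structure
  and contaminants that are out of the data model (ambiguous rows must
  be resolved upstream).
* UCD detection assumes lysine positions are known; on real data that
  requires the construct sequence.
* Overlap counts between alleles carry no significance estimate.
* The melt onset is only resolved to the temperature grid step, and
  the irreversibility index compares curves only at shared grid
  temperatures.
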