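# Methods

This note documents the models, conventions, parameter choices and known
limitations of `rnacad`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mass engine

Residues are nucleosides; a sequence of length L with 5′-OH/3′-OH termini
has composition `Σ nucleosides + (L−1)·HPO3 − (L−1)·H2O`. Phosphate
termini add one HPO3 each. Atomic masses are hard-coded monoisotopic
IUPAC/CODATA values (H 1.0078250319, C 12, N 14.0030740052,
O 15.9949146221, P 30.97376151; proton 1.00727646): sub-ppm agreement on
~4.8 kDa species requires at least five decimals, and hard-coding makes
the engine independent of any external constants table. The deaza residue
compositions follow from N→CH substitution of adenosine (c1A/c3A/c7A:
C11H14N4O4; c13A: C12H15N3O4; each substitution shifts the mass by
−0.995249 Da) and dA is adenosine minus one oxygen. No published elemental
formulas exist for these phosphoramidite-derived residues in the data we
reproduce; the substitution rule is fixed by the chemistry and by the
observed mass shifts.

The `basic_n3` flag on a residue marks an adenine-type ring nitrogen N3
available for protonation. It drives the synthetic generator's enhancement
rule. Cytidine also protonates at N3 in solution, but its protonated
gas-phase conformers do not hydrogen-bond to the backbone, so it does not
carry the flag. dA does: the 2′-deoxy modification removes the nucleophile
on the ribose, not the nitrogen on the base.

## Fragment conventions

Site *i* is the linkage between residues *i* and *i+1* (1 ≤ i ≤ L−1).
5′-side series are indexed by cleavage site; 3′-side series by fragment
length, so y_j breaks site L−j. Compositions: b = 5′ prefix with OH/OH
ends, a = b − H2O, d = b + HPO3, c = d − H2O (the 2′,3′-cyclic phosphate);
y = 3′ suffix with OH/OH ends, z = y − H2O, w = y + HPO3, x = w − H2O.
Complementary pairs (a,w), (b,x), (c,y), (d,z) each sum exactly to the
precursor composition. A config flag selects the linear-3′-phosphate c
convention (c + y = M + H2O) for cross-tool comparability; the cyclic
convention is the default because it is the actual CAD product.

Neutral losses are tracked at the composition level — *which* base was
lost, never from which position, since the spectrum cannot localize it.
Enumeration defaults: series {c, y}, at most one H2O and one base loss
(combined allowed), charges 1..(precursor − 1). Requesting a c fragment at
a site whose 5′-flanking residue lacks the 2′-OH raises a warning, not an
error: annotation of whatever a spectrum contains must remain possible.

Precursor channels support neutral losses (charge kept) and
protonated-base losses (the base leaves with one charge), reproducing
labels like (M+3H−guanine)³⁺ from a 4+ precursor.

## Isotope engine

Aggregated (unit-mass-binned) distributions only: per-element per-atom
distributions over nominal offsets are raised to their atom counts by
binary-exponentiation convolution and convolved across elements. The
distribution is truncated at cumulative 1 − 1e-4 (default) and
renormalized. Cluster peak k of an n+ ion sits at
(M + k·1.0033548 + n·1.00727646)/n. Isotopic fine structure and peak-shape
modeling are out of scope; centroided data carry no such information at
this scale.

## Cluster detection

Greedy longest-run-first chaining: for every peak and candidate charge z,
the chain of peaks spaced 1.0033548/z (each within the spacing tolerance
of its expected position, closest peak wins) is a candidate cluster;
candidates are accepted longest first and consume their members. This
ordering is what makes detection robust on dense spectra — a complete
envelope always beats the spurious sub-runs it contains (the charge-1
reading of every third peak of a 3+ envelope) and beats shorter foreign
chains trying to extend into it. Two guards:

* spacing tolerance, default **0.002 m/z**. Within a cluster the spacing
  error is essentially zero for centroids whose dominant m/z error is
  coherent calibration drift; a loose tolerance only invites cross-species
  peak theft.
* an upward intensity-ratio limit, default **10**: aggregate envelopes
  climb gently (the +1 peak of even a 5 kDa RNA fragment is at most a few
  times its neighbor), so a large upward jump marks a foreign
  monoisotopic peak and ends the chain. Decays are unrestricted, because
  envelope tails and the two-peak envelopes of small fragments fall off
  steeply and legitimately.

Unpartnered peaks become charge-undetermined singleton clusters; they may
match any candidate charge during assignment but are flagged
low-confidence.

## Matching and quantification

Cluster ↔ fragment pairing is by minimal |ppm error| (default tolerance
5 ppm, matching internally calibrated FT-ICR practice), ties broken toward
fewer losses, then the lower site index; each cluster is assigned at most
once and each species claims at most one cluster.

Abundances come from a non-negative least-squares fit of the member
intensities against the theoretical envelopes (scipy NNLS), not from a raw
member sum. For a clean complete cluster the two are identical; the fit
differs exactly where it must:

* **Coincident species.** A fragment of doubled composition at doubled
  charge has *identical* m/z to its half — the study sequence's 5′-GAAG
  repeat makes c8²⁺ ≡ c4¹⁺ and c2¹⁺ ≡ c4²⁺ ≡ c6³⁺. Such species are
  unresolvable by grouping but fully resolvable by envelope shape; the fit
  includes still-unassigned fragments whose monoisotopic m/z coincides
  within tolerance at a different charge and assigns each its fitted
  intensity.
* **Damaged clusters.** If an overlap stole a tail peak, the remaining
  slots still determine the species total exactly through the envelope
  shape.
* **Contaminated slots.** Member slots whose fit residual stays far above
  numerical noise (foreign tail peaks, baseline hits) are trimmed (at most
  5) and the fit repeated.

The assignment score is 1 − ‖residual‖/‖observed‖, clipped to [0, 1].

## Yield statistics

Y(site, series) sums abundances over all charge states including loss
variants, normalized by total backbone-fragment intensity (precursor
species excluded); profiles sum to 1 by construction and the code raises
on zero backbone signal.

Cross-RNA comparison pairs species by (series, site, loss-class, charge),
where the loss class collapses nucleobase identity so a lost A pairs with
a lost c3A. A line through the origin is fit to all pairs (zero signal
must map to zero); pairs whose reference/variant ratio exceeds 3× the
fitted central ratio *or falls below 1/3 of it* are outliers; the fit is
repeated once without them. The two-sided rule makes the comparison
symmetric: swapping reference and variant inverts slope and effect factor.
The effect factor is the geometric mean of the outliers' ratios divided by
the fitted central ratio. The normalization matters: with per-spectrum
intensity normalization, suppressing one site redistributes its share onto
all others, so the *raw* ratio of a 7-fold-suppressed site is
7·(Σw_variant/Σw_reference) ≈ 6.05 under the default weights, while the
deviation from the fitted trend recovers 7. Geometric (not arithmetic)
averaging because the quantity is multiplicative.

Grouped yields take any exact partition of the site range; the defaults
are the adenine-adjacent blocks {1–2} and {6–8} against {3–5} ∪ {9–14},
reported as ratios because ratios damp the charge-partitioning artifacts
that inflate the large 3′-side fragments. Average fragment charge is the
intensity-weighted mean per fragment index, loss variants included.

## Coulombic charge model

n protons on L discrete residue positions at unit spacing, vacuum 1/r,
energy Σ 1/|p_i − p_j|, exhaustively minimized over all C(L, n) placements
(intended for L ≤ 30; C(30, 6) ≈ 6·10⁵ is still immediate). All degenerate
minima are kept and averaged with equal weight — no Boltzmann factor, no
temperature parameter, because the model has no energy scale. Predicted
c_i charge is the mean count of protons at positions ≤ i; complementary
predictions sum to n identically. A hill-climbing fast path exists for
larger problems and doubles as an independent check. The discrete-residue,
unscreened model is the simplest one consistent with extended gas-phase
RNA structures; its outputs are trends, not fitted quantities (for the
15-mer 4+ precursor it places the central sites' c/y fragments at 2+/2+
and the near-terminal 3′ fragments at 3+, as observed).

## Synthetic spectra: what they emulate and what they do not

The generator's defaults are the study conditions: 15-mer sequences at
(M+4H)⁴⁺, 42 eV collision energy metadata, pH 6.8, total intensity 10⁶
(arbitrary units), A-effect α = 7, loss probabilities P(−H2O) = 0.07 and
P(−base) = 0.065 (combined loss fraction 13.05%, matching the ~13%
observed loss share), intensity noise CV 2%, m/z error 2 ppm, charge
jitter probability 0.1.

Mechanism enters only as the site-weight rule: weight 1 per site,
multiplied by α where the 3′-flanking residue carries a basic N3 (A, c1A,
c7A, dA — not c3A/c13A), forced to zero where the 5′-flanking residue
lacks a 2′-OH (dA). The pH dependence is a single scalar shift moving
weight from sites 1–2 to sites 6–8 (linear in pH from 6.8 to 3.0, maximum
shift 0.5), emulating the redistribution of solution protonation from the
near-terminal adenines to the central ones; the shape and magnitude are a
modeling choice, only the monotone trend is asserted.

Charge states: each cleavage event emits the complementary c/y pair with
integer charges summing to n, split between floor and ceiling of the
Coulombic prediction so the expectation equals the model exactly; jitter
moves ±1 with the stated probability; both fragments stay between 1 charge
and one proton per residue (a terminal mononucleotide never carries two).
Intensity noise is one log-normal factor per species; m/z error is one
coherent calibration-drift draw per species cluster (Gaussian, truncated
at ±2σ — internal calibration bounds the error, it does not leave
Gaussian tails), leaving intra-cluster spacing intact, which is the
FT-ICR-like regime the detector is designed for. Peaks closer than
1e-4 m/z merge into one centroid (intensity-weighted position), as any
centroider would merge them. Optional baseline peaks are uniform in m/z
with exponential intensities, default count 0 (averaged FT-ICR spectra
are effectively baseline-free; robustness to baseline is tested with the
knob turned on).

What passing tests therefore show: the analysis pipeline is exact on data
satisfying its own model (noiseless recovery to numerical precision) and
robust at realistic noise levels (planted α = 7 recovered as median ≈ 7
over 20 seeded replicates; ≥ 99% species recall at 2 ppm error and 5 ppm
tolerance). What they do not show: behavior under per-peak centroid
scatter comparable to the calibration error, envelope distortion from
detector saturation, chemical noise, or the low-m/z ion-transfer
discrimination of real instruments (intensities are reported as measured,
uncorrected — a documented limitation of the quantities themselves).

## Problem sizes and runtimes

The default validation sizes — 15-mer sequences, ~250 species and ~2000
peaks per synthetic spectrum, 20 comparison replicates, exhaustive Coulomb
checks to L = 20, n = 6 — keep the entire suite within a couple of
minutes on one core while exercising every code path at the scale of the
actual experiments.

## Known limitations

* Aggregated isotopes only; no fine structure, no resolution model.
* One H2O and one base loss per species by default; higher loss orders
  exist in real spectra at low abundance and would need the caps raised.
* The annotator does not deconvolve same-charge isomers (identical m/z,
  same charge, different site); the matcher's tie rules pick one.
* The Coulomb model ignores dielectric screening, real geometry and
  proton mobility; its charge predictions are averages over exact
  degenerate minima of an idealized chain.
* Solution-phase protonation enters only through the synthetic pH shift
  parameter; no microscopic acidity constants are computed.
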