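# Methods

This note records the models implemented by `parpdyn`, the defaults and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one convention was
defensible.

## Chemical-shift perturbations

CSPs combine the backbone amide ¹H and ¹⁵N shift differences between two
conditions as CSP = √(Δδ(¹H)² + (Δδ(¹⁵N)/5)²), in ppm.  The ¹⁵N scaling
constant (default 5, the common amide convention) is exposed in
`compute_csp(..., n15_scale=...)` for other nuclei conventions.  A CSP is
computed only where the residue is assigned in *both* conditions.
Residues assigned in one condition only are carried with status
`overlapped/unassigned` and no CSP — assigning them zero would fabricate
agreement between the conditions.  Prolines (no backbone amide) and the
persistently unobserved loop category are distinct statuses so that
structure mappings can annotate them separately.

For display, profiles from several samples share a single CSP_max (the
largest CSP anywhere in the set) and a colour value
min(CSP / (0.2·CSP_max), 1): the ramp saturates at one fifth of the
maximum so a few very large perturbations at the ligand site do not
compress the informative mid-range.  Values exactly at the threshold map
to colour 1.0.

Assigned shifts outside 5–13 ppm (¹H) or 95–140 ppm (¹⁵N) trigger
warnings, never errors: unusual shifts are suspicious but not impossible.

## ¹⁵N relaxation and τc

Decay series are fitted as I(t) = I₀·exp(−t/T) by Levenberg–Marquardt
least squares (scipy `curve_fit`, bounded to positive T).  The fit is
initialised from a log-linear regression over points above 5% of the
maximum intensity, falling back to one third of the delay span; parameter
errors are the square roots of the covariance diagonal, scaled by the
residual variance.  Duplicate delays — present in the standard schedules
(T1: 0, 120, 120, 280, 480, 800, 1200, 1200, 2000, 3200, 4800, 6800 ms;
T1ρ: 0.15, 2, 4, 4, 7, 12, 20, 34, 34, 50, 70, 100 ms) — are fitted as
independent observations, and the absolute intensity difference at each
duplicated delay is reported as a reproducibility metric.  Flat series
(fitted T far beyond the delay span) are rejected as undetermined rather
than returned with a meaningless error bar.

Observed T1ρ values are corrected for ¹⁵N resonance offset in the tilted
rotating frame: with spin-lock field ω₁ = 2π·B₁ and offset
Ω = 2π·(δ − δ_carrier)·νN, the tilt is tanθ = ω₁/Ω and
R2_eff = (R1ρ,obs − R1·cos²θ)/sin²θ.  On resonance this is the identity;
residues with sin²θ < 10⁻⁶ (or a non-positive corrected rate) are flagged
undefined rather than returned as numbers.  The field context defaults to
800 MHz ¹H, B₁ = 1.56 kHz, carrier 117.074 ppm; νN is derived from the
¹⁵N/¹H frequency ratio 0.10137 and a >1% override deviation warns.

The rotational correlation time uses the slow-isotropic-tumbling
approximation τc ≈ (1/(4π·νN))·√(6·T1/T1ρ − 7): τc is 0 at
6·T1/T1ρ = 7 and undefined (not an exception) below it.  No model-free
fitting is attempted — τc here is a tumbling diagnostic, not a dynamics
model.  Subdomain summaries report a 10%-per-tail trimmed mean and the sd
of the trimmed values per residue-range selection (HD and ART by
default), flagging the pair as "differing" when the means are further
apart than the pooled sd; identical tumbling of the two subdomains is the
single-rigid-domain outcome.

Heteronuclear NOE ratios are I_sat/I_unsat with the standard two-spectrum
error propagation (both intensities carry the spectrum RMS noise); a
ratio is undefined when the unsaturated intensity is within 3σ of zero.
Rigid backbone amides sit near 0.8 at this field.

## NH solvent exchange

CLEANEX-PM intensities are normalised between samples by
(ΣI^CL)/(ΣI^TR) over reference residues 657, 660 and 661 — unstructured
N-terminal residues that exchange freely and are unlikely to respond to
ligands or HD mutations.  Real-time ²H₂O series are classified from the
3, 12 and 39 h intensities:

- slow-light: I(3) − I(12) > 0.5·I(3)
- slow-medium: not light, and I(12) − I(39) > 0.25·I(12)
- slow-dark: neither

Both published rules are strict inequalities, leaving the boundary open;
equality is assigned to the *slower* class, the conservative protection
call.  Classification precedence is: CLEANEX signal above the detection
threshold → fast; else a detectable 3 h real-time signal → the slow rules
(with later points floored to zero when below threshold); else
unobserved.  The default detection threshold is 3× the spectrum RMS
noise.  Many "unobserved" residues fall in the blind window of roughly
0.5–500 s⁻¹ — too slow for equilibrium experiments, too fast for a
real-time series with ~3 h per spectrum; the classifier reports this as a
category rather than inferring around it.  Cross-spectrum normalisation
of the real-time series is a user-supplied per-spectrum factor (the
acquisition-dependent corrections are instrument-specific and not
derivable from the tables themselves).

`simulate_class_from_rate` maps a first-order rate to its expected class
using only the CLEANEX-detectable floor (default 0.5 s⁻¹, about the amide
¹H R1) for the fast boundary, which makes the predicted class monotone in
the rate; the random-coil ceiling (~10 s⁻¹ at pH 7, 25 °C) lies well
inside the fast regime, and faster amide rates do not occur, so the
generator's CLEANEX window defaults to (0.5 s⁻¹, ∞).

## Structure metrics

Structures are parsed with gemmi (PDB and mmCIF), dropping hydrogens and
waters, keeping occupancies and all alternate locations.  Altlocs are
resolved at lookup time: highest occupancy wins, ties break by label
order with blank/'A' first — the common crystallographic convention.
Residue numbers are the deposited author numbering; no renumbering.

Selections are ordered lists of (chain, inclusive residue range, atom
names); the built-in HD/ART/CAT backbone (N, Cα, C′) sets use the
catalytic-domain ranges given in the README.  Resolution returns a
presence mask alongside coordinates — missing residues or atoms are
flagged, never silently dropped — and pairing between two structures uses
the intersection of masks, with paired counts reported next to every
rmsd, because deposited models differ in which residues are modelled.
Atoms are unweighted in the fits (occupancy weighting would change
Table-style comparisons by well under the reporting precision and is not
a documented convention for them).

Superposition is the Kabsch algorithm via SVD, constrained to proper
rotations (the reflected optimum is never returned).  Fewer than three
atoms or a collinear cloud is an error: the rotation is undetermined.
The two-set rmsd fits the moving structure to the reference over set 1,
then evaluates the rms difference over set 2 with the set-1 transform
unchanged; with set 1 = set 2 this is the conventional rmsd, and for a
rigid displacement of set 2 relative to set 1 it equals the analytic rms
displacement of the set-2 atoms under the relative transform.

Torsions use the standard atan2 formulation with the IUPAC sign
convention, validated against an independent implementation (gemmi) in
the tests.  A torsion is invariant under rigid motion and under reversal
of the point order, and negated by mirror reflection; all three are
property-tested.  The glycosidic χ of a purine nucleoside uses the
O4′–C1′–N9–C4 quartet (the common purine convention; depositions rarely
state theirs) and multi-chain averages are circular means — arithmetic
means are wrong for angles near ±180°, and the two coincide in the
regimes reported here.  The chain compared defaults to A with an explicit
override, since some depositions are best represented by another chain.

## Synthetic data

The generators are pure functions of their parameters and seed
(bit-reproducible), and every generator records enough ground truth to
score the downstream analysis without re-deriving it.

- Two-subdomain toys are ideal poly-alanine helices (1.5 Å rise, 100°
  twist per residue, backbone atoms on coaxial cylinders) with the mobile
  helix rigidly rotated about a hinge axis, optionally kinked at its
  midpoint.  Default 30+30 residues and a 10° hinge — large enough that
  displacement dominates numerical noise, small enough to be realistic
  for a subdomain shift.  No side chains, no packing, no disorder: the
  toys exercise superposition arithmetic, not crystallography.
- Shift pairs draw base shifts uniformly in plausible amide ranges
  (¹H 7–9.5 ppm, ¹⁵N 105–130 ppm) and plant an exponentially decaying
  perturbation around a site, split at a random angle between the two
  dimensions with the ¹⁵N part pre-scaled by 5 so the planted CSP is
  exact by construction.
- Decay series use the experimental delay schedules with homoscedastic
  Gaussian noise (default σ = 2% of I₀, typical of well-resolved peaks).
  Real spectra have correlated, intensity-dependent noise; the generator
  supports first-order robustness checks, not error-model validation.
- Exchange profiles map per-residue rates to exp(−k·t) at 3/12/39 h and
  a CLEANEX signal when the rate is within the detectable window, with
  analytically computed ground-truth classes.

Passing tests on these inputs demonstrates correctness of the arithmetic
and classification logic and first-order robustness to noise.  They do not
demonstrate robustness to peak overlap, baseline distortion, incomplete
assignment transfer or anisotropic tumbling, none of which the generators
model.

## Problem sizes and tolerances

The test and acceptance runs use 60-residue structural toys, 100-residue
shift tables, 200-replicate decay Monte Carlo sets and 50-seed exchange
ensembles of 10 residues spanning all five classes — sizes at which every
stochastic check is stable across seeds while the whole suite stays
interactive.  Exact-construction checks assert at 10⁻⁹–10⁻¹²;
Monte-Carlo checks assert the statistical bands they estimate (interval
coverage 95% ± 4%, noisy class agreement ≥ 95%); comparisons against
deposited coordinates use ±0.05 Å, since modelled-residue sets differ
slightly between depositions.

## Known limitations

- No model-free (Lipari–Szabo) analysis, relaxation dispersion or
  spectral-density mapping; τc is the approximate T1/T1ρ formula only.
- No fitting of continuous exchange rates or protection factors; the
  classifier reproduces the categorical scheme only.
- No peak picking or assignment transfer; tables are taken as given.
- The NMR-STAR reader covers single chemical-shift loops (the deposited
  amide-shift format), not the full STAR grammar.
- Crystallographic data processing and refinement are out of scope; the
  structure module consumes refined coordinates.
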