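# Methods

`capi` implements the quantitative layer used to characterize a cation-pi
"lock" in the neuronal calcium sensor GCAP1: geometric detection of
arginine-tryptophan cation-pi contacts on structures and ensembles,
conformational descriptors over trajectory-like multi-model ensembles,
multi-site ITC isotherm fitting, and CD spectral/thermal-stability
descriptors.  Every estimator is exercised against a seeded synthetic-data
generator with planted ground truth.

## Cation-pi geometry

A ring-cation pair is reduced to three numbers: the centroid-cation
distance `d` (Å), the angle `theta` between the ring-plane normal and the
centroid-to-cation vector folded to [0°, 90°], and the angle `phi` at the
ring centroid between the cation direction and an aromatic hydrogen,
minimized over the ring's hydrogens.

*Theta convention.*  "Angle between the aromatic plane and the cation" is
ambiguous; a lateral (in-plane) contact reported in a 60-90° window is only
consistent with measuring from the **normal** (90° = in plane), which is
also the plane-vector angle convention of the common MD trajectory
utilities.  `theta_from_plane=True` gives the complementary convention.

*Phi hydrogen choice.*  When several ring hydrogens exist, `phi` is the
minimum angle — the hydrogen the cation points at.  Structures without
hydrogens get `phi = NaN` and classification falls back to `theta` and `d`
alone.

*Ring and cation definitions.*  TRP defaults to the six-membered benzene
ring of the indole (CD2, CE2, CE3, CZ2, CZ3, CH2) — one well-defined plane;
the 5-ring and 9-atom variants are available.  PHE/TYR use
CG/CD1/CD2/CE1/CE2/CZ.  The ARG cation point is CZ (approximates the
guanidinium charge centroid and exists in heavy-atom models), with an
NE/NH1/NH2-mean option.

*Classification thresholds.*  `lateral`: theta in (60°, 90°] and
phi ≤ 30°; `axial`: theta ≤ 30°; both gated by d ≤ 6.0 Å.  Only the 60-90°
theta window is a literature value; the distance gate, phi cap and axial
cap are package defaults, configurable and echoed in every report.
`bridge_scan` reports every cation classifying (non-`none`) against two
distinct rings simultaneously — the detector for an R86-bridged W21/W94
lock.

The plane normal is the total-least-squares normal (smallest
right-singular vector of the centered ring coordinates); its sign is fixed
(z ≥ 0, ties to x then y) but irrelevant after theta folding.  Collinear
rings and cation-on-centroid degeneracies raise typed errors.

## Ensemble descriptors

RMSF is computed after least-squares rigid superposition
(scipy's Kabsch-style `align_vectors`) of every frame onto the iteratively
refined mean structure (two refinement passes); `ref="first"` reproduces
the fit-to-reference convention instead.  Superposing onto a fitted frame
absorbs six rigid degrees of freedom, so measured RMSF underestimates a
planted isotropic amplitude by a relative ~`6/(3N)` for N fit atoms — at
the 200-atom, 5000-frame validation scale this sits inside the
3-standard-error band of the closed-form expectation (planted amplitude
`a` with per-coordinate sigma `a/sqrt(3)`; SE ≈ `a/sqrt(2T)`).

Distance series accept named-atom, ring-centroid or side-chain reference
points (ring centroid for TRP/PHE/TYR, CZ for ARG, C-alpha otherwise — the
atoms the interaction is about, with the C-alpha fallback keeping a
glycine at position 86 comparable).  Smoothing is a centered running
mean/population-SD over 100 frames (1 ns at a 10 ps stride) with truncated
edge windows: no data is fabricated at the edges, so plots differ from
padded conventions only there.  The population-vs-sample SD difference is
negligible at window 100.  `twisted_accordion` is the
C-alpha(168)-C-alpha(178) distance trace with this smoothing — the compact
readout of the accordion-like transition between the calcium-loaded
(inhibitor) and magnesium-loaded (activator) states.

## ITC binding model

Independent site classes, one site per protein per class (the sensor has
three functional EF-hands): three classes for Ca2+, two for Mg2+.  Free
ligand X solves the monotone mass balance
`X + M·sum_i X/(K_Di + X) = X_total` (vectorized bisection + Newton
polish, relative tolerance ~1e-12; conservation holds to 1e-10).
Cumulative heat in a perfusion cell of volume V0 is
`Q_k = V0·M_k·sum_i dH_i·X_k/(K_Di + X_k)` and the measured per-injection
heat carries the displaced-volume correction
`dQ_k = Q_k − Q_{k−1} + (dV_k/V0)(Q_k + Q_{k−1})/2`, with cell
concentrations diluted by `(1 − dV/V0)` per injection.  Default schedule:
1.4 mL cell, 20 µM protein, 0.5 mM Ca2+ or 10 mM Mg2+ syringe, 55 × 5 µL
injections, 25 °C — a standard VP-ITC-class protocol reaching a ~1.6
molar-ratio endpoint for the Ca2+ titration.  Blank (reference-injection)
heats are accepted as a column to subtract.

Fitting is multi-start nonlinear least squares on (log10 K_D, dH) per
class with an analytic Jacobian obtained by implicit differentiation of
the mass balance; classes are reported sorted ascending by K_D, which
eliminates label switching between starts.  Independent-site models admit
a degenerate "compensation valley" — two classes merging in K_D while
their enthalpies run to large opposite values (a derivative-like pair that
can absorb noise).  The fitter therefore prefers the best optimum that is
interior to the search box (log10 K_D in [−9, −2], dH in [−20, 25]
kcal/mol) and falls back to a bound-pinned solution only when no interior
start converged; classes on a bound or with standard errors exceeding
their values are flagged unidentifiable.

`kd_apparent` is the geometric mean of the class K_Ds.  The source tables
for this system never define their "overall apparent affinity" explicitly,
but the geometric mean reproduces six of the eight quoted per-variant
values within rounding (≈52, 200, 167, 243, 741 nM and 3.1 µM); the two
discordant quotes (≈992 and ≈73 nM) appear to be rounding or transcription
artifacts in the source and are documented here rather than asserted.

*Identifiability caveat.*  At 20 µM protein, sites with K_D of tens of nM
sit at Wiseman c = M/K_D around 10^3, at or beyond the classic c ≲ 1000
fittable window.  For the wild-type Ca2+ parameter set the Fisher
information at 0.1 µcal noise gives se(log10 K_D1) ≈ 0.7 per titration —
the smallest K_D is only weakly identified, recovered values scatter by
several-fold, and for some noise draws the global optimum is the merged
compensation valley rather than the planted configuration.  The package
reports what the likelihood supports and flags degeneracy; it does not
regularize the estimate toward an expected answer.  The weak Mg2+ site
(K_D ≈ 648 µM with dH 0.34 kcal/mol) is similarly noise-limited
(se(log10 K_D) ≈ 0.22 per titration), so recovered means over 10
replicates carry ~15-20% spread.

## CD descriptors and melt fitting

`theta_222/theta_208` reads both ellipticities by linear interpolation at
exactly 222.0 and 208.0 nm — the two alpha-helical far-UV minima; the
ratio and `(theta_222^ion − theta_222^EGTA)/theta_222^EGTA` are invariant
under uniform scaling, hence independent of units and path length.
Near-UV spectra are baselined by subtracting the mean ellipticity over
310-320 nm, where no protein signal is expected.

Thermal melts at 222 nm are fit with a four-parameter Hill sigmoid **in
Celsius as scanned** (20-96 °C): `theta(T) = theta_f +
(theta_u − theta_f)·T^h/(T_m^h + T^h)`.  The temperature scale choice is
absorbed by the exponent h and does not move the midpoint semantics
(`theta(T_m)` is exactly the baseline midpoint).  The fit multi-starts
over a T_m grid spanning the scan plus one beyond-scan start and
h ∈ {10, 25, 50}.  A melt is censored (reported "> 96"-style) when the
fitted T_m exceeds the scan maximum or the fitted amplitude is below 3×
the residual SD — the operational version of "no clear transition", for
which no numeric rule exists in the source material.  Ellipticity signs
are taken as read from the CSV.

## Synthetic data: what it emulates, what it does not

All generators are bit-exact functions of their arguments including the
seed, and each has an analysis-side inverse or closed-form expectation
asserted in tests.

- `make_ring_cation` builds a carbon hexagon (radius 1.40 Å) with one
  planted aromatic hydrogen at radius 2.48 Å and a cation placed so the
  measured (theta, phi, d) equal the planted values exactly.  Because
  aromatic hydrogens are in-plane, phi is geometrically confined to
  [90° − theta, 90° + theta]; pairs outside that band are unrealizable and
  rejected.  A single hydrogen is emitted at the azimuth that realizes phi
  exactly — a hydrogen grid could shadow the intended minimum.
- `make_bridge_pdb` composes two such assemblies sharing one cation on
  opposite sides, plus optional decoy PHE rings ≥ 12 Å away; overlapping
  ring placements raise an infeasibility error.
- `make_trajectory` adds isotropic Gaussian displacements with
  per-coordinate sigma = amplitude/sqrt(3), so planted RMSF equals the
  amplitude in closed form; an optional two-state mean shift of one atom
  plants a distance switch.  This emulates magnitudes and rank order of
  per-residue flexibility, not force-field dynamics: no correlated
  (Langevin) motion, no secondary-structure coupling — so passing tests
  validate the estimators, not any physical claim about real proteins.
- `make_itc` / `make_melt` add iid Gaussian noise (defaults 0.1 µcal,
  0.3 mdeg) to the exact forward models; real baselines drift and peak
  integration errors are not modeled.
- `make_cd_spectrum` solves a 2×2 linear system for two-Gaussian band
  amplitudes so the planted theta_222/theta_208 values are exact.

Residue numbering of geometry fixtures follows the GCAP1 landmarks
(21/86/94, 168/178) so worked examples read like the biological system.

## Validation scales

Recovery studies use 10 replicate seeds (ITC: 55 injections, 32 fit
starts; melts: 153 scan points).  Property suites use 500 random
geometries for the inverse-generator check (1e-6 tolerance), 5000 frames ×
200 atoms for the RMSF closed form (3 SE), exhaustive brute-force
equivalence for running statistics on series up to length 500, and 1e-10
relative mass-balance conservation.  These sizes were chosen to keep each
statistical check's standard error well below its assertion tolerance.

## Known limitations

- PDB is the only structure format; binary trajectories enter through the
  `(times, frames)` adapter contract, not natively.
- Stoichiometry is fixed at one site per class; sequential/cooperative and
  competition models are out of scope, as are baseline integration of raw
  power traces, secondary-structure deconvolution of CD spectra, and
  van't Hoff enthalpy extraction from melts.
- Hydrogens are read, never added; structures without them lose phi.
- The smallest-K_D recovery limits described under *Identifiability
  caveat* are intrinsic to the titration design, not to this
  implementation.
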