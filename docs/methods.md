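# Methods

This note documents the models implemented in `mechunfold`, the
conventions and defaults chosen where the underlying procedure admits
alternatives, and what the synthetic generators do and do not emulate.

## Units and constants

All lengths are nm, times ns, forces pN; free energies kcal/mol
(per-molecule mechanical energies in pN·nm).  Converters live only in the
readers/writers.  Fixed constants:

- 1 kJ/(mol·nm) = 1.6605390 pN (1/N_A scaling); hence the 500 kJ/(mol·nm²)
  pull spring is 830.27 pN/nm.
- k_B = 0.0138065 pN·nm/K, so k_B·T = 4.142 pN·nm at the 300 K thermostat
  temperature used as default everywhere.
- Molar k_B = 0.0019872 kcal/(mol·K), so k_B·T = 0.59616 kcal/mol at 300 K.

## SASA and contact areas

SASA uses the Shrake–Rupley construction: for each atom, test points on
the probe-extended sphere (radius r_i + probe) are classified against all
other probe-extended spheres; the accessible fraction times 4π(r_i+probe)²
is summed.  The point set is a deterministic golden-angle spiral, so
results are exactly reproducible; with the default 960 points the area of
an isolated sphere is within 1% of 4π(r+probe)².  Defaults: probe 0.14 nm,
Bondi-style element radii (C 0.170, N 0.155, O 0.152, S 0.180, H 0.120 nm)
with per-call overrides; hydrogens are included when present.  These are
package choices — the probe radius, point density and radii set are not
dictated by the procedure itself.

The contact area between regions A and B is
CA = ½(SASA_A + SASA_B − SASA_{A+B}), where SASA_A and SASA_B are
evaluated with each region *alone* in solvent and SASA_{A+B} with both
present.  This degenerate-context convention makes CA exactly zero once
the regions separate beyond one probe diameter, which the event detector
depends on.  Inter-domain interface selections are trimmed by two residues
at each fragment terminus so directly consecutive sequences can reach zero
contact; intra-repeat helix-pair selections use no trim.

Tilt angles α1/α2 are the angles between the pulling axis and the Cα
vectors from a mid anchor to an N-side and C-side anchor (presets:
desmoplakin N375→P342/Y403, plectin N858→P825/Y886), via arccos of the
normalized dot product with clipping to [−1, 1] against rounding.  The
trajectory score is the larger of the two per-frame maxima.

## Event detection

The elongation coordinate is the inter-spring distance x = v·t measured
from the start of pulling; no equilibrium pre-tension offset is
subtracted.  The equilibrium baseline uses type-7 (linear-interpolation)
quantiles; CA_low = Q1 − 1.5·(Q3 − Q1).  Detection is strict first
crossing with no hysteresis or re-arming — one event per feature per
trajectory: start at the first frame with CA < ½·CA_low, end at the first
later frame with CA < 0.002 nm².  If the start threshold would fall below
the 0.002 nm² floor (possible when the equilibrium IQR is wide), it is
clamped to the floor with a warning so the detector stays total.  Events
crossing the start but never the floor are reported open-ended at the last
sampled elongation.  Display windows narrower than 2 nm are widened
symmetrically about the event midpoint and clamped at zero elongation
(shifting right, preserving width).

## Force processing

The combined pull force is F = ½(F1 − F2).  Two-column force files are
treated as a single spring with the second channel synthesized as the
negative of the first, so the combination reduces to F1.  Smoothing is a
discrete Gaussian with width fixed in elongation (default 0.1 nm, i.e.
σ_time = 0.1 nm / v_pull: 10 ns at v = 1/100 nm/ns), truncated at ±4σ and
renormalized at the trace boundaries — a weighted average with no padding,
so constants are preserved exactly and the first peak is not attenuated at
the edges.  The rupture force is the plain maximum of the smoothed force
over the first 20 nm of elongation (the operational definition of "first
peak"), not a prominence-based first local maximum; traces shorter than
the window are used in full and flagged.  Peak counting (used only for
high/low second-peak labelling) uses topographic prominence with declared,
configurable defaults: 100 pN prominence, 5 nm minimum separation, and a
"high" label at ≥ 3 peaks.

## Bell-model fits

F_r is regressed on ln(k_spring·v_pull) by unweighted least squares over
individual records rather than per-velocity means; the two coincide for
balanced designs, and individual records keep replicate information.  The
loading rate uses the single spring constant and full pull velocity.
Derived parameters: x_b = k_B·T/A, k_off = B/A; slope per decade of
velocity is A·ln 10.  A non-positive slope flags the fit (anti-Bell trend)
instead of producing unphysical parameters, and the zero-force rate is
only available with an explicit extrapolation warning.  More elaborate
rupture-force–loading-rate relations (e.g. Dudko–Hummer–Szabo) are out of
scope by design: with data clustered at high loading rates they overfit.

## Bayesian ΔΔG from unfolding order

P(A first) = p links to the barrier difference ΔΔG = ΔG_A − ΔG_B through
p = 1/(1+exp(ΔΔG/k_B·T)).  The prior is uniform on p (not on ΔΔG), giving
a Beta(k+1, n−k+1) posterior on p; the density over ΔΔG includes the
change-of-variables Jacobian p(1−p)/kT, hence ∝ p^(k+1)(1−p)^(n−k+1), with
closed-form mode k_B·T·ln((n−k+1)/(k+1)).  The 95% interval is
equal-tailed, obtained by mapping the 0.975/0.025 Beta quantiles through
the (decreasing) link — quantiles transform without a Jacobian.  This
convention is adopted because it simultaneously reproduces all four
published worked-example values (mode 1.2 with interval [0.7, 2.0] for
3/33; mode ≈ −0.03 with interval [−0.4, 0.4] for 17/33); the grid mode is
cross-checked against the closed form within one grid step (default
0.001 kcal/mol on ±10 kcal/mol).  k = 0 or k = n flags a one-sided
interval.  First-unfolding attribution from event catalogs uses strict
comparison of start elongations; exact ties count 0.5 to each side and are
flagged.

## Z-test and ROC

Two rupture-force sets differ significantly when |mean1 − mean2| ≥
2·√(ε1²+ε2²) with ε the standard errors of the mean (sample standard
deviation, n−1 denominator); the multi-velocity verdict requires the rule
to hold at every requested velocity (default: the three fastest, where ten
replicas are available).  The ROC sweeps thresholds over the scores; the
trapezoidal AUC equals the Mann–Whitney pair-ordering probability with
ties counted one half, which the tests verify against exhaustive pair
counting.

## Synthetic data

The generators are pure functions of (spec, seed) through a single
explicit `numpy` Generator each; no global random state.

- Force traces: piecewise-linear loading ramps (default 50 pN/nm effective
  slope) reset by planted fractional drops, antisymmetric channels, iid
  Gaussian channel noise (default 20 pN in the pipeline), 0.05 ns
  sampling, durations chosen so elongation reaches ≥ 25 nm at every
  velocity (covering the 20-nm first-peak window).
- Rupture forces: exact inverse-CDF samples of the force-ramp
  first-passage law S(F) = exp[−(k_off·kT)/(r·x_b)·(e^{F·x_b/kT} − 1)],
  whose modal force follows the Bell equation — the generator-side inverse
  of the fitted model, kept separate from the fitting code.
- Contact areas: a stationary AR(1) segment (default mean 5 nm²,
  coefficient 0.8, innovation sd 0.15 nm²) for baseline estimation,
  continued into a pulled segment where planted sigmoidal losses
  (steepness width/10) multiply the mean; the fluctuation amplitude scales
  with the remaining envelope so noise vanishes with the contact.  The
  noiseless envelope is exposed so tests can compute planted-truth
  crossings independently.
- Toy structures: sphere pairs (analytic SASA/contact-area oracles),
  parallel Cα rods (monotone contact-loss fixtures), tilted rods (exact
  tilt-angle oracles).
- Order counts: Binomial(n, p) through the logistic link.

The study-shaped end-to-end configuration mirrors the published design —
two systems × four velocities (1, 1/3, 1/10, 1/30 nm/ns) × 10 replicas,
33 event trajectories — with Bell parameters (x_b = 0.3 nm;
k_off = 10⁻⁶ vs 2.2·10⁻⁵ ns⁻¹) chosen so system A's rupture forces exceed
system B's by ≈ 20% at these loading rates.  What the generators do *not*
emulate: real force-field energetics, worm-like-chain elasticity between
ruptures, refolding, correlated multi-feature unfolding, or solvent
effects on SASA; passing tests therefore validate the analysis chain and
its statistics, not any claim about real proteins.

## Scale of the shipped computations

The test suite and example runs use scaled problem sizes chosen as sanity
envelopes: SASA oracles at 960 points on few-atom fixtures, 50 seeded
event-recovery fixtures, 200-repetition bias checks and 500-replicate
coverage checks for the estimators, and pipeline smoke runs at 2 velocities
× 4 replicas with the full study shape exercised once in the acceptance
suite.  The acceptance script itself is deterministic desk-scale
arithmetic on the published counts.

## Known limitations

- The SASA implementation is O(n·m) per atom over neighbor candidates and
  is meant for interface-sized selections, not whole-proteome sweeps.
- PDB/GRO parsing covers fixed-column ATOM/coordinate records (the
  dialects the pipeline touches), not insertion codes, altlocs or large
  (>9999) residue numbering; binary trajectory formats are out of scope.
- Element inference from atom names is heuristic for files lacking an
  element column; ambiguous two-letter ions should carry explicit element
  columns or radius overrides.
- The ΔΔG link assumes a single dominant barrier per domain and
  force-independent ΔΔG over the compared events.
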