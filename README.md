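# mechunfold

Analysis tools for force-probe (steered) molecular-dynamics unfolding
trajectories of multi-domain proteins, built around the mechano-sensing
question posed by the SH3 insertion in plakin-family spectrin repeats
(desmoplakin, plectin): when and in what order do domains and interfaces
let go under force, how strong are the rupture events, and what do the
replicate statistics say about the underlying kinetics and barriers?

The package covers the complete trajectory-analysis layer downstream of the
MD engine, plus synthetic generators that emulate the engine's outputs so
every stage is testable offline:

- **Contact areas** between residue regions A and B from Shrake–Rupley
  solvent-accessible surface areas:
  `CA(A↔B) = ½·(SASA_A + SASA_B − SASA_{A+B})`.
- **Unfolding events** from contact-area series against the equilibrium IQR
  fence `CA_low = Q1 − 1.5·(Q3 − Q1)`: an event starts when CA first drops
  below `½·CA_low` and ends below the 0.002 nm² numerical floor.
- **Rupture forces**: the pull force `F = ½(F1 − F2)` smoothed with a
  Gaussian of fixed elongation width (0.1 nm), maximized over the first
  20 nm of elongation.
- **Bell-model kinetics** over a pulling-velocity ladder:
  `F_r = (k_B T/x_b)·ln(k·v·x_b/(k_B T·k_off)) = A·ln(k·v/B)`,
  fitted by least squares over individual records.
- **Bayesian ΔΔG** between competing unfolding events from first-unfolding
  counts k of n, with a uniform prior on p = P(A first), the logistic link
  `p = 1/(1+exp(ΔΔG/k_B T))`, posterior mode
  `ΔΔG* = k_B T·ln((n−k+1)/(k+1))` and equal-tailed Beta-quantile credible
  intervals.
- **Classification**: per-velocity Z-test margins `2·√(ε1²+ε2²)` on rupture
  forces, and ROC/AUC of maximum tilt angles against high/low second-peak
  force (shearing vs tearing pathways).
- **I/O**: GROMACS-style XVG pull-force files, PDB/GRO structures, TSV
  tables; all internal units nm / ns / pN / kcal·mol⁻¹.

## Worked example

Estimating the barrier difference between the two central spectrin repeats
from which of them unfolds first across 33 replicate pulls
(`examples/01_ddg_from_unfolding_order.py`):

```python
from mechunfold import OrderCounts, posterior

post = posterior(OrderCounts(n=33, k=3, label_a="SR5", label_b="SR4"))
print(post.mode, post.ci_low, post.ci_high)
```

prints

```
desmoplakin: SR5 first in 3/33 pulls
  ddG(SR5,SR4) mode = +1.22 kcal/mol
  95% credible interval = [+0.70, +2.01]
plectin: SR5 first in 17/33 pulls
  ddG(SR5,SR4) mode = -0.03 kcal/mol
  95% credible interval = [-0.44, +0.37]
```

A mode of +1.22 kcal/mol means the rarely-first repeat (SR5) carries the
higher unfolding barrier; the plectin interval straddles zero, i.e. no
detectable order preference.  The other examples cover rupture-force
extraction and Bell fits (`02`), contact-area event detection (`03`),
tilt/ROC classification (`04`), and the five-stage end-to-end pipeline
(`05`).  A thin CLI mirrors the main entry points:
`mechunfold {ddg|bell|rupture|compare|roc|simulate|run}`.

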