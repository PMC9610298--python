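# chesar

A toolkit for structure–activity analysis of cholinesterase inhibitors,
built around a panel of 48 quaternary *Cinchona*-alkaloid derivatives
(cinchonidine/cinchonine and their 10,11-dihydro analogues) tested against
human acetylcholinesterase (AChE) and butyrylcholinesterase (BChE).  It is
aimed at medicinal-chemistry and QSAR practitioners who need the whole chain
from raw inhibition assays to cross-validated activity models:

- **Kinetics** — enzyme–inhibitor dissociation constants K_I from
  reversible-inhibition assays via the Hunter–Downs linearization
  K_i,app = v_i·[I]/(v_0 − v_i) = K_I + (K_I/K_S)·S, fitted by OLS.
- **SAR tables** — selectivity indices SI = K_i(AChE)/K_i(BChE) and
  pseudo-enantiomer stereoselectivity ratios, with the publication rounding
  conventions; the reference Ki panel ships as a packaged dataset.
- **Drug-likeness** — oral-activity rule compliance (MW, logP, HBD, HBA,
  RB, PSA) and four-level blood–brain-barrier classification of logBBB
  values.
- **PCA** — mean-centered covariance principal component analysis by the
  NIPALS algorithm (X = Σ tᵢ pᵢᵀ), with deterministic sign conventions and
  projection of new compounds.
- **PES sampling** — a small velocity-Verlet MD engine (Maxwell
  initialisation, velocity-scaling thermostat) over a pluggable force-field
  contract, condensing each trajectory into a fixed-length potential-energy
  *fingerprint*.
- **Model search** — exhaustive best-subset polynomial regression
  (B = (XᵀX)⁻¹XᵀY via SVD), leave-one-out cross-validation through the hat
  matrix (PRESS, predicted R²), and parsimony-aware model selection; the
  3-variable 4th-order space holds 2³⁴ = 17,179,869,184 models, supported
  through exact counting and budgeted enumeration.
- **Pipeline** — per-series regression of the activity PC1 on the leading
  principal components of the compound × fingerprint matrix, plus synthetic
  generators with known ground truth for every stage.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import numpy as np
from chesar.datasets import load_ki_table
from chesar.pca import nipals_pca
from chesar.sar import selectivity_table, ki_range

table = load_ki_table()                      # 48 compounds, Ki in µM
si = selectivity_table(table)
best = si.loc[si["SI"].idxmax()]
print(f"most selective: {best['compound']} (SI = {best['SI_printed']:.0f})")
print("BChE Ki range (uM):", ki_range(table, "BChE"))

result = nipals_pca(table[["Ki_BChE_uM", "Ki_AChE_uM"]].to_numpy(), k=2)
print(f"PC1 explains {100*result.explained_fraction[0]:.2f}% of the activity variance")
```

prints

```
most selective: CD 3F (SI = 533)
BChE Ki range (uM): (0.075, 19.0)
PC1 explains 99.13% of the activity variance
```

The *N*-(3-fluorobenzyl)cinchonidinium derivative ("CD 3F") binds BChE
533-fold more tightly than AChE — the most BChE-selective compound of the
panel — and BChE inhibition constants span three orders of magnitude down
to 75 nM.  The first principal component of the two-enzyme activity matrix
carries essentially all of the variance, so one score per compound suffices
as the response for regression modelling.

The same operations are available from the shell:

```sh
chesar sar --out sar/                 # selectivity + stereoselectivity tables
chesar ki-fit --in assay.csv --out fits.csv
chesar md-sample --steps 10000 --seed 7 --out traj.xyz
chesar fingerprint --traj traj.xyz --q 64 --out fp.csv
chesar search --x pcs.csv --y activity.csv --order 4 --count-only
chesar pipeline --ki ki.csv --fingerprints fp.csv --out report.json
chesar simulate assay --seed 1 --out assay.csv
```

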