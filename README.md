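# phylocomp

Phylogenetic comparative regression of gene-family size against
life-history traits.

Closely related species are not independent data points: under Brownian
trait evolution on a phylogeny, the expected covariance between two species
equals the branch length they share from the root to their most recent
common ancestor.  `phylocomp` implements the two classical corrections for
this non-independence and applies them to the question of whether the size
of the CD33-related Siglec (CD33rSiglec) immune-receptor gene family tracks
maximum lifespan across mammals, with three negative-control families (KLK,
TLR, IgG Fc receptors) analyzed identically.

It is written for comparative biologists who want the estimators as
reusable, validated building blocks:

* **PGLS** — generalized least squares with error covariance
  `Σ = σ² V(λ)`, where `V` is the phylogenetic variance–covariance matrix
  and Pagel's λ ∈ [0, 1] scales its off-diagonal entries (λ = 1: full
  Brownian structure; λ = 0: phylogenetic independence).  λ may be held
  fixed or estimated by maximizing the profile log-likelihood.
* **Independent contrasts** — Felsenstein's pruning recursion produces
  `n − 1` standardized contrasts `(x₁ − x₂)/√(v₁′ + v₂′)`; regression of
  y-contrasts on x-contrasts is forced through the origin and, under
  Brownian motion, recovers exactly the PGLS(λ = 1) slope.
* **A trait simulator** — Yule trees and correlated Brownian traits with
  known λ and evolutionary cross-covariance, so every estimator is
  validated by parameter recovery and type-I-error calibration rather than
  by trust.

The packaged 14-species dataset (`phylocomp/data/synthetic_*`) is a clearly
labelled synthetic stand-in that emulates the design of the original study
(one focal family strongly associated with log lifespan, three weak
controls, one of them driven by a single outlier species); see
`phylocomp/data/__init__.py` and `docs/methods.md`.

## Worked example

```python
import numpy as np
import pandas as pd
from phylocomp import PGLS, PhyloTree
from phylocomp.pipeline import (
    AnalysisConfig, load_trait_table, align_table_and_tree,
)

cfg = AnalysisConfig.reproduction()          # packaged synthetic dataset
table = load_trait_table(cfg.trait_table)
tree = PhyloTree.from_file(cfg.tree_paths["Tree I"])
tab, ptree = align_table_and_tree(table, tree)

df = pd.DataFrame({
    "gene_count": tab["cd33rsiglec_count"].astype(float),
    "log_lifespan": np.log10(tab["max_lifespan_years"]),
    "log_body_weight": np.log10(tab["body_weight_grams"]),
}, index=tab.index)

res = PGLS.from_dataframe(df, "log_lifespan", ["gene_count"], ptree) \
          .fit(lam=1.0, df_convention="paper")
print(res.summary())
```

```
Phylogenetic GLS regression
==============================================================
n obs:    14    df resid:  11 (paper)
lambda: 1.000000 (fixed)    sigma2: 0.000344454    logLik: 5.9642
R2 (squared corr): 0.8555
--------------------------------------------------------------
                      coef     std err         t       P>|t|
         const   -0.285572    0.258896   -1.1030    0.293559
    gene_count    0.240133    0.033977    7.0675 2.07895e-05
==============================================================
```

Each extra gene in the focal family predicts a 0.24 increase in log₁₀
maximum lifespan (≈ 1.7-fold per gene), and the association survives the
full Brownian correction (t = 7.07 on 11 df, two-tailed p ≈ 2 × 10⁻⁵).
Adding log body weight as a covariate and letting the data choose λ:

```python
res2 = PGLS.from_dataframe(df, "gene_count",
                           ["log_lifespan", "log_body_weight"], ptree) \
           .fit(lam="ml", df_convention="paper")
```

gives λ̂ = 0.866 with a lifespan coefficient of t = 4.42 (p ≈ 0.001) while
body weight contributes nothing (t = 0.65) — the association is not a body-
size artifact.  The same grid over all four families and both trees, plus
sensitivity refits, runs from the shell:

```sh
phylocomp reproduce --out report/     # full grid on the packaged dataset
phylocomp validate                    # fixture sanity checks
phylocomp simulate --n-taxa 50 --seed 1 --out sim   # synthetic data
```

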