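# masslasso

Fast estimation of L1-regularized (lasso) linear models in the
mass-univariate setting: many response time series (e.g. fMRI voxels)
are fitted independently against **one shared design matrix**, and the
package exploits that sharing aggressively.

## Who this is for

Neuroimaging analyses that need many predictors per model — single-trial
designs (one predictor per trial), FIR designs (one predictor per
post-stimulus time bin), or encoding models with high-dimensional
stimulus feature spaces — and that prefer sparse (L1) over dense (L2)
regularization. Once the number of predictors `p` approaches or exceeds
the number of time points `n`, regularization is mandatory, and the
lasso's iterative fits become the bottleneck of whole-brain analyses.
`masslasso` removes most of the redundant work across voxels.

## The model

For a design matrix `X` (n × p, columns z-scored: mean 0 and
(1/n)·Σᵢxᵢⱼ² = 1, no intercept column) and responses `Y` (n × v), each
voxel `j` solves

```
minimize over (Bⱼ, B⁰ⱼ):   (1/2n)‖Yⱼ − X Bⱼ − 1·B⁰ⱼ‖₂² + λ‖Bⱼ‖₁
```

Because `X` is column-centered and the intercept is unpenalized,
`B⁰ⱼ = mean(Yⱼ)` exactly for every λ, and the coefficient problem
reduces to the Gram matrix `C = (1/n)XᵀX` and cross-products
`c = (1/n)XᵀY` — computed **once** and shared by all voxels.

Two solvers minimize the same objective:

* **`cd`** — per-voxel cyclic coordinate descent with covariance
  updates (no residual vectors), active sets, warm starts along a
  decreasing λ sequence, sparse output buffers, and a deterministic
  parallel voxel loop.
* **`admmbatch`** — batched ADMM that updates whole blocks of voxels
  simultaneously via matrix products, with the quadratic-block
  factorization cached per design; when `p > n` the p × p solve is
  rewritten through the matrix-inversion (Woodbury) lemma as an n × n
  one. Outputs are returned in single precision.

`λ_start = max|(1/n)XᵀY|` is the smallest penalty at which every
voxel's solution is all-zero; λ sequences conventionally start there
and decrease on a log₂ scale.

## Worked example

```python
import numpy as np
from masslasso import MassLasso

rng = np.random.default_rng(0)
X = rng.standard_normal((40, 10))        # 40 time points, 10 predictors
Y = rng.standard_normal((40, 6))         # 6 voxels

model = MassLasso(Y, X, standardize=True)
print(round(model.lambda_start(), 4))    # 0.4381
res = model.fit(model.lambda_grid(4), method="cd")
print(res.summary())
```

prints

```
0.4381
Mass-univariate lasso path (solver=cd, n=40, p=10, v=6)
      lambda  mean N_nz  max N_nz  mean iters  converged
    0.438061       0.00         0         2.0      100%
    0.219031       1.33         3         3.5      100%
    0.109515       4.83         7         5.3      100%
   0.0547577       6.67         8         6.0      100%
```

At the top of the path (λ = λ_start) every coefficient is zero; as λ
halves, more predictors enter (`mean N_nz` grows) and the warm-started
fits stay cheap (`mean iters` is sweeps per voxel). `res.coefficients(-1)`
returns the dense p × v coefficient matrix at the last λ;
`res.intercepts` holds the per-voxel intercepts (the response means);
`res.save("fit.h5")` / `LassoPathResults.load` round-trip everything.

The same fits run from the shell:

```sh
masslasso simulate --label B --n 60 --p 40 --v 100 --seed 1 \
    --out-design X.txt --out-responses Y.txt
masslasso fit X.txt Y.txt --solver cd --lambdas start,5,1 --out fit.h5
masslasso convert fit.h5 --out-dir betas_txt
```

NIfTI input is supported: `masslasso fit bold.nii mask.nii ...` treats
in-mask voxels as columns (first spatial axis fastest) and records the
voxel index map in the result metadata.

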