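# Methods

## Problem and notation

`masslasso` fits, for each of `v` response series sharing one design,
the lasso objective

    (1/2n) ‖Yⱼ − X Bⱼ − 1·B⁰ⱼ‖₂² + λ ‖Bⱼ‖₁ ,

with `X` (n × p) column-z-scored in the *population* convention:
column mean 0 and (1/n)Σxᵢⱼ² = 1, i.e. divisor `n`, **not** the `n−1`
of most statistics routines. `check_standardized` verifies exactly
this; a matrix standardized with divisor n−1 fails the second-moment
check (moment (n−1)/n). Constant columns are refused outright: an
intercept column must not be part of `X` — the intercept is unpenalized
and, because `X` is centered, equals the response mean exactly at every
λ. It is therefore computed once (`compute_intercepts`) and never
enters either solver. `Y` is deliberately *not* re-centered: centering
is absorbed by the intercept, and skipping it avoids copying `Y`.

All solver work happens in the sufficient statistics
`C = (1/n)XᵀX` (Gram/correlation matrix, unit diagonal) and
`c = (1/n)XᵀY`, computed once per dataset.

## Coordinate-descent solver (`cd`)

Per voxel, cyclic coordinate descent with exact coordinate
minimization: `βⱼ ← S(cⱼ − Σ_{k≠j, βₖ≠0} C_jk βₖ, λ)` with
`S(z,t) = sign(z)·max(|z|−t, 0)` and unit denominator (Gram diagonal
is 1). The gradient sum runs only over currently nonzero coordinates,
read from precomputed Gram rows ("covariance updates") — no residual
vector exists.

Sweep schedule: one full sweep over all `p` coordinates; then repeated
sweeps over the *active set* (every coordinate that has ever been
nonzero) until the largest coordinate change in a sweep is below
`tol_value`; then one closing full sweep — if it activates a new
coordinate or moves anything by ≥ `tol_value`, the active-set loop
resumes, otherwise the voxel has converged. One *iteration* is one
sweep; `n_iter_max` (default 1e5) bounds total sweeps per voxel per λ,
which keeps the default budget meaningful for both tiny and large `p`.
Coordinate order is fixed cyclic `0…p−1` — no randomization — so
results are exactly reproducible.

λ paths are fitted in the given order with warm starts (the first λ
from zero). A decreasing sequence is recommended and a non-decreasing
one only triggers a warning, since it is still a valid request.
λ = 0 is accepted only when `p ≤ n`; the unregularized
overparameterized fit is non-unique and is refused with a message
recommending a positive λ.

Voxels are distributed over `max(1, floor(cpu_load_factor · cores))`
workers (joblib); since voxels are independent and each fit is
deterministic, results are bitwise identical for any worker count.

### Sparse buffers

Outputs are stored sparsely (values, 0-based predictor indexes,
per-voxel counts `N_nz`). Capacity is `⌈buffer_factor · n⌉` entries
per voxel (default factor 3). The overflow check runs *during*
solving, against the transient nonzero count: coordinate descent can
activate coordinates temporarily that later leave the model, and a
cold start at a small λ can transiently hold far more nonzeros than
the final solution (warm-started paths rarely do — one more reason to
use them). Overflow aborts the call with
`"N_nz over maximum, larger buffer is required!"`; exhausting the sweep
budget raises `"Max. iter. reached, no convergence!"`. These two
messages are stable API.

## Batched ADMM solver (`admmbatch`)

ADMM splits the objective into a quadratic block, a soft-thresholding
block and a dual update; for a whole batch of voxels at once (matrix
products, GPU-style even though execution here is CPU BLAS):

    B ← (C + ρI)⁻¹ (c + ρ(Z − U));  Z ← S(B + U, λ/ρ);  U ← U + B − Z.

`ρ = 1` is fixed (exposed as an option) so the system matrix can be
Cholesky-factorized once per design and reused across batches,
iterations and λ values. When `p > n` the solve uses the
matrix-inversion lemma, `(C + ρI)⁻¹ = (1/ρ)(I − Xᵀ(nρI + XXᵀ)⁻¹X)`,
so only an n × n factorization is ever formed.

**Stopping rule.** A voxel is converged when *both* the dual movement
`max|Z_new − Z_old|` *and* the primal residual `max|B − Z|` are below
`tol_value`. The dual movement alone is not a safe criterion: `Z` can
sit still (typically pinned at zero in early iterations) while `B` and
`U` are far from the fixed point, which silently freezes voxels at
wrong solutions. Requiring primal feasibility as well makes the
`max|B − Z| ≤ 10·tol_value` guarantee hold by construction and brings
per-voxel objectives within `10·tol_value` of the coordinate-descent
solutions in every tested configuration. Converged voxels' columns are
frozen (not removed), keeping updates dense and batch composition
irrelevant: fitting with `buffer_size` 100 or 7 gives bitwise-identical
results.

Warm starts carry the full `(B, Z, U)` triple across λ values within a
batch. Iterates are double precision by default and outputs (B⁰ and
the coefficients) are downcast to single precision — the format of this
algorithm family's GPU implementations; `single_precision=True`
iterates fully in float32 for fidelity experiments. On CPU there is no
speed incentive for float32, so correctness-first double iterates are
the default.

## Tunable parameters

| parameter | default | unit/scale | role |
|---|---|---|---|
| `tol_value` | 1e-3 | standardized-coefficient scale | stopping threshold of both solvers |
| `n_iter_max` | 1e5 | sweeps (CD) / iterations (ADMM) | budget before the convergence error |
| `buffer_factor` | 3 | × n nonzeros per voxel | CD sparse output capacity |
| `cpu_load_factor` | 1 | fraction of cores | CD parallelism (0 → one core, 0.99 → all but one) |
| `buffer_size` | 8192 | voxels | ADMM batch width |
| `rho` | 1 | penalty scale | ADMM augmented-Lagrangian weight (fixed to cache the factorization) |

`tol_value` is interpreted on the scale the solvers work in — the
standardized-coefficient scale — so its meaning is independent of the
predictors' original units.

## Synthetic data

`generate_benchmark` reproduces two canonical workloads with `X`, `Y`
drawn i.i.d. standard normal (then `X` z-scored): an overparameterized
encoding-model shape (full size n=300, p=5000, v=65536,
λ ∈ {2⁻²…2⁻⁶}) and a well-defined single-trial/FIR shape (p=200,
λ = 2⁻⁴). Tests and the acceptance script run them scaled to desk size
(n=60, p=300, v=64 and n=60, p=40, v=100) so the whole battery
finishes in about a minute on one core; full size is available by
simply not passing scaled dimensions. `generate_planted` adds a sparse
ground truth (k nonzeros of fixed magnitude and random sign per voxel,
Gaussian noise) for recovery scoring. All generators are pure
functions of their seed.

What this does *not* emulate: fMRI noise structure — temporal
autocorrelation, scanner drift, physiological noise, spatial
correlation. Passing tests certify solver correctness on the stated
objective, not robustness of the lasso to realistic fMRI noise.

## Verification strategy

The independent oracle is plain ISTA (proximal gradient, fixed step
1/L with L the top Gram eigenvalue, no warm starts, no active sets),
sharing only the scalar soft-threshold with production code. On random
batteries spanning `p < n` and `p > n`, CD at `tol 1e-8` matches the
oracle objective within 1e-6 and ADMM at defaults within
`10·tol_value`; every converged CD solution carries a KKT certificate
(`kkt_residual ≤ 5·tol_value`). A second, library-independent
cross-check fits the identical objective with scikit-learn's Lasso in
one test. Recovery thresholds on the planted model (median support
sign-agreement ≥ 0.9; median false-positive count < k) were frozen
from a single pilot run at the committed seed and are regression tests
of this package's behavior, not claims about the lasso in general: at
noise_sd 0.5 a tail of voxels does pick up more than k spurious
predictors, so only the median is bounded.

## Numerical and design notes

* Standardization tolerances: centering within 1e-8·n, second moment
  within 1e-6 — loose enough for float32 input files.
* The Gram product is explicitly symmetrized ((C + Cᵀ)/2) against BLAS
  rounding asymmetry.
* `λ_start` is one scalar, the max over all voxels (matching the
  single-value contract of the path runner); a per-voxel variant is
  exposed separately.
* The full λ path is stored, one sparse set per λ; the last-λ slice
  reproduces a single-solution reading. Text export numbers predictors
  1-based (Matlab heritage of the format); everything internal and the
  HDF5 container are 0-based.
* Degenerate inputs: non-finite entries are rejected everywhere;
  constant design columns are named by index in the error; an all-zero
  mask or mismatched NIfTI grids fail fast.
* CD ties: `S(z, λ)` maps `|z| ≤ λ` to exactly 0; there are no other
  ties to break under cyclic order.

## Known limitations

* No GPU execution; the ADMM module is written so a GPU backend could
  replace the batched BLAS calls without changing results beyond
  stated tolerances.
* No elastic-net mixing, no strong-rule screening, no cross-validation
  for λ (the intended workflow chooses λ a priori on a log₂ grid from
  `λ_start`).
* Writing per-predictor coefficient NIfTI volumes is not implemented
  (the voxel index map in the result metadata makes it straightforward
  downstream).
* Memory estimates (`estimate_memory`) are coarse itemized bounds for
  the dominant buffers, not allocator-accurate accounting.
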