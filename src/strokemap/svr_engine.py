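"""Core multivariate machinery shared by voxelwise and connectome-wise LSM.

Three stages:

1. **Residualization** — nuisance and behavioral covariates are regressed
   out of both the feature matrix (lesion status per voxel, or disconnection
   status per edge) and the behavioral target by ordinary least squares,
   prior to any model fitting.
2. **SVR fit with beta back-projection** — an epsilon-insensitive support
   vector regression of behavior on the residualized features. With the
   default linear kernel the back-projected beta vector equals the primal
   weight vector exactly (beta_j = sum_i alpha_i X_ij over support vectors);
   with an rbf kernel the same dual-coefficient formula is used as a
   sensitivity-map-style approximation.
3. **Permutation null** — the residualized target is shuffled and the model
   refit; feature-wise one-tailed (negative) p-values use the add-one rank
   formula p_j = (1 + #{b : beta_j^(b) <= beta_j^obs}) / (n_perm + 1), so a
   p-value is never 0 and its floor is 1/(n_perm+1).

Damage is coded 1 and higher scores mean better performance, so a deficit
shows as a *negative* beta — all inference in this package is one-tailed
negative.

Permutations shuffle the already-residualized target (covariates have been
removed from both sides, so the rows are exchangeable under the null);
permutation b uses the seeded shuffle ``default_rng(scheme.seed + b)``,
making every run bit-reproducible.

scikit-learn's SVR does the heavy lifting, called with a precomputed Gram
matrix so the (subjects x subjects) kernel is built once per design and
reused across all permutations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVR

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    DataError,
    EmptyDesignError,
)


@dataclass(frozen=True)
class SvrConfig:
    """Hyperparameters of the support vector regression.

    Defaults: linear kernel, C=1.0, epsilon=0.1, target standardized to
    unit variance after residualization. Feature columns are *not*
    re-standardized: lesion/disconnection residuals carry lesion-frequency
    information that standardization would erase. ``normalize_design``
    instead rescales the whole matrix by one global constant so the mean
    squared sample norm is 1 — relative column scales are preserved, C
    stays interpretable across designs of different width, and the SMO
    solver is well conditioned (wide lesion designs otherwise produce
    kernels with entries in the hundreds and pathological iteration
    counts).
    """

    kernel: str = "linear"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | str = "scale"
    standardize_y: bool = True
    normalize_design: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ConfigurationError("C must be positive")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be nonnegative")


@dataclass(frozen=True)
class PermutationScheme:
    """Permutation-based familywise error correction settings.

    ``voxel_forming_p`` and ``connectivity`` apply only to the voxelwise
    clusterwise correction. The tail is fixed one-sided negative.
    """

    n_perm: int = 10_000
    tail: str = "negative"
    alpha: float = 0.05
    voxel_forming_p: float = 0.005
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self):
        if self.tail != "negative":
            raise ConfigurationError("tail is fixed one-sided negative")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError("connectivity must be 6, 18, or 26")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be positive")


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Replace each column of M by its OLS residual on [intercept, C].

    Returned columns are orthogonal to the intercept and every covariate
    column (checked to 1e-8 by the test suite). Rank deficiency of the
    design raises :class:`CollinearityError` naming the dependent columns.
    Idempotent: residualizing twice equals residualizing once.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] == 1 and M.size > 1:
        M = M.T
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != M.shape[0] and C.shape[1] == M.shape[0]:
        C = C.T
    n = M.shape[0]
    if C.shape[0] != n:
        raise DataError("M and C have misaligned rows")
    D = np.hstack([np.ones((n, 1)), C])
    if D.shape[1] >= n:
        raise DataError("more covariates (plus intercept) than subjects")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        dep = _dependent_columns(D)
        raise CollinearityError(
            f"covariate design is rank deficient; dependent columns "
            f"(0=intercept): {dep}", dependent_columns=dep)
    coef, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ coef


def _dependent_columns(D: np.ndarray) -> list[int]:
    """Columns of D linearly dependent on their predecessors (QR pivoting)."""
    dep = []
    _, R = np.linalg.qr(D)
    diag = np.abs(np.diag(R))
    tol = max(D.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    for j, d in enumerate(diag):
        if d < tol:
            dep.append(j)
    return dep


# ---------------------------------------------------------------------------
# SVR fitting
# ---------------------------------------------------------------------------

def _normalize_design(X: np.ndarray, cfg: SvrConfig) -> np.ndarray:
    """Scale X globally so the mean squared row norm is 1 (if enabled)."""
    if not cfg.normalize_design:
        return X
    scale = np.mean((X ** 2).sum(axis=1))
    return X / np.sqrt(scale) if scale > 0 else X


def _gram_matrix(X: np.ndarray, cfg: SvrConfig) -> np.ndarray:
    if cfg.kernel == "linear":
        return X @ X.T
    if cfg.gamma == "scale":
        var = X.var()
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    else:
        gamma = float(cfg.gamma)
    return rbf_kernel(X, gamma=gamma)


def _standardize(y: np.ndarray, cfg: SvrConfig) -> np.ndarray:
    if not cfg.standardize_y:
        return y
    sd = y.std()
    return y / sd if sd > 0 else y


def _fit_dual(K: np.ndarray, y: np.ndarray, cfg: SvrConfig) -> np.ndarray:
    """Fit SVR on a precomputed Gram matrix; return full-length dual vector."""
    model = SVR(kernel="precomputed", C=cfg.C, epsilon=cfg.epsilon)
    model.fit(K, y)
    alpha = np.zeros(K.shape[0])
    if model.support_.size:
        alpha[model.support_] = model.dual_coef_[0]
    return alpha


def _validate_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] == 0:
        raise EmptyDesignError("no features in design")
    if X.shape[0] != y.shape[0]:
        raise DataError("X and y have misaligned rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DataError("NaN in SVR inputs")
    return X, y


def fit_svr_beta(X: np.ndarray, y: np.ndarray, cfg: SvrConfig = SvrConfig()) -> np.ndarray:
    """Fit the SVR and back-project the feature-space beta vector.

    ``X`` and ``y`` should already be residualized. The beta vector is the
    intercept-free linear sensitivity beta = alpha @ X (equal to the primal
    weight vector for the linear kernel). Deterministic given inputs.
    """
    X, y = _validate_design(X, y)
    X = _normalize_design(X, cfg)
    y = _standardize(y, cfg)
    K = _gram_matrix(X, cfg)
    alpha = _fit_dual(K, y, cfg)
    return alpha @ X


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Observed betas, permuted betas, and one-tailed negative p-values.

    ``beta_perm`` has one row per permutation. ``p`` follows the add-one
    rank formula and is therefore never 0; its floor is 1/(n_perm+1).
    """

    beta_obs: np.ndarray       # (k,)
    beta_perm: np.ndarray      # (n_perm, k)
    p: np.ndarray              # (k,)
    scheme: PermutationScheme

    def perm_p(self) -> np.ndarray:
        """Per-permutation p maps, computed symmetrically with the observed.

        Permutation b's p at feature j counts permutations (including b
        itself, playing the add-one role) with beta <= beta_j^(b):
        p_j^(b) = rank / (n_perm + 1). These drive each permutation's own
        suprathreshold map in clusterwise correction. Tie-exact via sorted
        search (ties can occur, e.g. betas exactly 0).
        """
        B = self.beta_perm
        S = np.sort(B, axis=0)
        out = np.empty_like(B)
        for j in range(B.shape[1]):
            out[:, j] = np.searchsorted(S[:, j], B[:, j], side="right")
        return out / (self.scheme.n_perm + 1.0)


def permutation_null(X: np.ndarray, y: np.ndarray,
                     cfg: SvrConfig = SvrConfig(),
                     scheme: PermutationScheme = PermutationScheme()) -> PermutationNull:
    """Observed fit plus ``scheme.n_perm`` label-shuffled refits.

    Requires residualized inputs. Permutation b shuffles y with
    ``default_rng(scheme.seed + b)`` (b = 1..n_perm) and refits on the same
    Gram matrix. At least 100 permutations are required for any inference.
    """
    if scheme.n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100 for inference")
    X, y = _validate_design(X, y)
    X = _normalize_design(X, cfg)
    y = _standardize(y, cfg)
    n = y.shape[0]
    K = _gram_matrix(X, cfg)

    alphas = np.empty((scheme.n_perm + 1, n))
    alphas[0] = _fit_dual(K, y, cfg)
    for b in range(1, scheme.n_perm + 1):
        # only labels move; the subjects (and hence K) are unchanged
        order = np.random.default_rng(scheme.seed + b).permutation(n)
        alphas[b] = _fit_dual(K, y[order], cfg)
    betas = alphas @ X
    beta_obs, beta_perm = betas[0], betas[1:]
    p = (1.0 + (beta_perm <= beta_obs).sum(axis=0)) / (scheme.n_perm + 1.0)
    return PermutationNull(beta_obs=beta_obs, beta_perm=beta_perm, p=p, scheme=scheme)
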