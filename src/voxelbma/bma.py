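"""Closed-form g-prior Bayesian model averaging for one voxel.

The response at a voxel is modelled as ``y = b0 + X_j beta_j + eps`` for
every covariate subset ``M_j`` of the k design columns. With a flat prior
``p(b0, sigma) ~ 1/sigma`` and the Zellner-type prior
``beta_j ~ N(0, sigma^2 (g X_j'X_j)^{-1})`` the marginal likelihood of a
model is available in closed form (up to a constant shared by all models
at the voxel):

    log p(D|M_j) = (k_j/2) log(g/(g+1))
                   - ((n-1)/2) log( SSR_j/(g+1) + g TSS/(g+1) )

where SSR_j is the residual sum of squares of the *centered* response on
the *centered* included columns and TSS the total (centered) sum of
squares. The null model (k_j = 0) has log marginal -((n-1)/2) log TSS.
Note g multiplies X'X, so g = 1/max{n, k^2} is the reciprocal of the
conventional Zellner g: it is the unit-information / BRIC prior.

All 2^k models are enumerated under a uniform model prior; posterior
model probabilities, posterior inclusion probabilities (PIPs) and
model-averaged coefficient means follow by direct summation. Everything
X-only (centered columns, per-model QR factorizations) is precomputed in
:class:`ModelSpace` and shared across voxels, since the design does not
vary over the brain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import logsumexp

from .design import DesignMatrix

#: Enumeration is refused above this many covariates; use MC3 instead.
ENUMERATION_GUARD = 20

_NORMALIZATION_TOL = 1e-8


class ConstantResponseError(ValueError):
    """Raised when a voxel's response is constant (TSS = 0)."""


@dataclass(frozen=True)
class RegressionModel:
    """A covariate subset, encoded as a bit mask over the k design columns.

    Bit i (least significant first) set means column i is included.
    """

    mask: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.mask < (1 << self.k):
            raise ValueError(f"mask {self.mask} out of range for k={self.k}")

    @property
    def k_j(self) -> int:
        """Number of included covariates."""
        return int(self.mask).bit_count()

    @property
    def included(self) -> np.ndarray:
        """Indices of included columns, ascending."""
        return np.flatnonzero(self.inclusion_mask)

    @property
    def inclusion_mask(self) -> np.ndarray:
        """Length-k 0/1 vector, entry i = bit i of the mask."""
        return np.array([(self.mask >> i) & 1 for i in range(self.k)], dtype=int)


@dataclass(frozen=True)
class GPrior:
    """Shrinkage constant of the g-prior; beta ~ N(0, sigma^2 (g X'X)^{-1})."""

    g: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g) and self.g > 0):
            raise ValueError(f"g must be a positive real, got {self.g!r}")


def default_g(n: int, k: int) -> GPrior:
    """Default shrinkage g = 1 / max{n, k^2} (unit-information / BRIC rule)."""
    if n < 2 or k < 1:
        raise ValueError(f"need n >= 2 and k >= 1, got n={n}, k={k}")
    return GPrior(g=1.0 / max(n, k * k))


@dataclass(frozen=True)
class ModelPosterior:
    """Posterior over all 2^k models at one voxel, masks in ascending integer order."""

    log_marginals: np.ndarray
    posterior_probs: np.ndarray
    prior_probs: np.ndarray

    @property
    def n_models(self) -> int:
        return len(self.log_marginals)

    @property
    def k(self) -> int:
        return int(self.n_models).bit_length() - 1

    def __post_init__(self) -> None:
        n = len(self.log_marginals)
        if n == 0 or n & (n - 1):
            raise ValueError(f"number of models must be a power of 2, got {n}")
        total = float(np.sum(self.posterior_probs))
        if abs(total - 1.0) > _NORMALIZATION_TOL or np.any(self.posterior_probs < 0):
            raise ValueError("posterior_probs must be non-negative and sum to 1")


def _as_design_values(X: DesignMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D array")
    return X


def _check_response(y: np.ndarray, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != design rows {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if np.ptp(y) == 0:
        raise ConstantResponseError("constant response at this voxel (TSS = 0)")
    return y


class ModelSpace:
    """Precomputed per-model factorizations of a fixed design matrix.

    For every inclusion mask m (ascending integer order, bit 0 = first
    column) this holds a thin QR of the centered included columns, so a
    voxel's 2^k marginal likelihoods reduce to one matrix product. Models
    whose centered submatrix is rank-deficient are flagged and receive
    posterior probability zero.
    """

    def __init__(self, X: DesignMatrix | np.ndarray, guard: int = ENUMERATION_GUARD):
        values = _as_design_values(X)
        self.n, self.k = values.shape
        if self.n < 2:
            raise ValueError("need at least 2 rows")
        if self.k > guard:
            raise ValueError(
                f"k={self.k} exceeds the enumeration guard ({guard}); "
                "use the MC3 sampler for large model spaces"
            )
        self.n_models = 1 << self.k
        self.Xc = values - values.mean(axis=0)

        col_scale = np.linalg.norm(self.Xc, axis=0)
        rank_tol = self.n * np.finfo(float).eps * max(col_scale.max(), 1.0)

        q_blocks: list[np.ndarray] = []
        b_blocks: list[np.ndarray] = []
        row_model: list[np.ndarray] = []
        row_cov: list[np.ndarray] = []
        k_j = np.zeros(self.n_models, dtype=int)
        valid = np.ones(self.n_models, dtype=bool)

        for m in range(1, self.n_models):
            idx = [i for i in range(self.k) if (m >> i) & 1]
            k_j[m] = len(idx)
            sub = self.Xc[:, idx]
            q, r = np.linalg.qr(sub)
            if np.min(np.abs(np.diag(r))) <= rank_tol:
                valid[m] = False
                continue
            q_blocks.append(q)
            # conditional posterior mean of beta given M: OLS/(1+g), OLS = R^{-1} Q'yc
            b_blocks.append(np.linalg.solve(r, q.T))
            row_model.append(np.full(len(idx), m))
            row_cov.append(np.array(idx))

        self.valid = valid
        self.k_j = k_j
        self.n_rank_deficient = int(np.sum(~valid))
        if self.n_rank_deficient:
            warnings.warn(
                f"{self.n_rank_deficient} of {self.n_models} models have "
                "rank-deficient centered submatrices; they receive posterior "
                "probability 0",
                stacklevel=2,
            )
        # (total included columns over valid models) x n stacks
        self._Q = np.vstack([q.T for q in q_blocks]) if q_blocks else np.empty((0, self.n))
        self._B = np.vstack(b_blocks) if b_blocks else np.empty((0, self.n))
        self._row_model = (
            np.concatenate(row_model) if row_model else np.empty(0, dtype=int)
        )
        row_cov_flat = np.concatenate(row_cov) if row_cov else np.empty(0, dtype=int)
        nrows = len(row_cov_flat)
        self._scatter = sparse.csr_matrix(
            (np.ones(nrows), (row_cov_flat, np.arange(nrows))),
            shape=(self.k, max(nrows, 1)),
        )
        # membership[m, i] = bit i of mask m, for PIP summation
        masks = np.arange(self.n_models, dtype=np.int64)
        self.membership = ((masks[:, None] >> np.arange(self.k)) & 1).astype(float)

    # -- per-voxel quantities -------------------------------------------------

    def log_marginals(self, y: np.ndarray, prior: GPrior) -> np.ndarray:
        """Log marginal likelihoods of all models, shared constant dropped."""
        return self.batch_log_marginals(np.asarray(y, dtype=float)[:, None], prior)[:, 0]

    def batch_log_marginals(self, Y: np.ndarray, prior: GPrior) -> np.ndarray:
        """Log marginals for a stack of voxels; Y is n x V, result 2^k x V."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != self.n:
            raise ValueError(f"Y must be {self.n} x V")
        for v in range(Y.shape[1]):
            _check_response(Y[:, v], self.n)
        Yc = Y - Y.mean(axis=0)
        tss = np.einsum("nv,nv->v", Yc, Yc)

        z = self._Q @ Yc  # rows x V projections onto per-model orthonormal bases
        expl = np.zeros((self.n_models, Y.shape[1]))
        np.add.at(expl, self._row_model, z**2)
        ssr = np.clip(tss[None, :] - expl, 0.0, None)

        g = prior.g
        half_nm1 = 0.5 * (self.n - 1)
        lml = 0.5 * self.k_j[:, None] * np.log(g / (g + 1.0)) - half_nm1 * np.log(
            ssr / (g + 1.0) + (g / (g + 1.0)) * tss[None, :]
        )
        lml[~self.valid, :] = -np.inf
        return lml

    def batch_posteriors(self, Y: np.ndarray, prior: GPrior) -> np.ndarray:
        """Normalized posterior model probabilities (uniform prior), 2^k x V."""
        lml = self.batch_log_marginals(Y, prior)
        return np.exp(lml - logsumexp(lml, axis=0, keepdims=True))

    def batch_pips_and_coefficients(
        self, Y: np.ndarray, prior: GPrior
    ) -> tuple[np.ndarray, np.ndarray]:
        """PIPs and model-averaged coefficient means for a voxel stack.

        Returns ``(pips, coefs)``, each k x V. Coefficients are the
        unconditional posterior means: per-model shrunk least-squares
        estimates weighted by posterior model probability, zero for
        excluded covariates.
        """
        Y = np.asarray(Y, dtype=float)
        probs = self.batch_posteriors(Y, prior)
        pips = self.membership.T @ probs

        Yc = Y - Y.mean(axis=0)
        betas = (self._B @ Yc) / (1.0 + prior.g)
        weighted = betas * probs[self._row_model, :]
        coefs = np.asarray(self._scatter @ weighted)
        return pips, coefs


def log_marginal_likelihood(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    model: RegressionModel,
    prior: GPrior,
) -> float:
    """Closed-form log marginal of one model, up to the voxel-shared constant.

    Both y and the included design columns are centered before the
    projection; a rank-deficient included submatrix yields -inf (the
    model gets posterior probability zero) with a warning.
    """
    values = _as_design_values(X)
    n = values.shape[0]
    if model.k != values.shape[1]:
        raise ValueError(f"model is over k={model.k} covariates, design has {values.shape[1]}")
    y = _check_response(y, n)
    yc = y - y.mean()
    tss = float(yc @ yc)
    half_nm1 = 0.5 * (n - 1)
    if model.k_j == 0:
        return -half_nm1 * np.log(tss)

    sub = values[:, model.included]
    sub = sub - sub.mean(axis=0)
    q, r = np.linalg.qr(sub)
    col_scale = max(float(np.linalg.norm(sub, axis=0).max()), 1.0)
    if np.min(np.abs(np.diag(r))) <= n * np.finfo(float).eps * col_scale:
        warnings.warn(
            f"model mask {model.mask}: rank-deficient centered submatrix; "
            "assigning log marginal -inf",
            stacklevel=2,
        )
        return -np.inf
    proj = q.T @ yc
    ssr = max(tss - float(proj @ proj), 0.0)
    g = prior.g
    return float(
        0.5 * model.k_j * np.log(g / (g + 1.0))
        - half_nm1 * np.log(ssr / (g + 1.0) + (g / (g + 1.0)) * tss)
    )


def enumerate_models(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    prior: GPrior,
    space: ModelSpace | None = None,
) -> ModelPosterior:
    """Exhaustive posterior over all 2^k covariate subsets at one voxel.

    Masks are ordered by their integer value (bit 0 = first column);
    normalization is done in log space, so any finite spread of log
    marginals is handled without underflow. Pass a prebuilt
    :class:`ModelSpace` to amortize the X-only factorizations over voxels.
    """
    if space is None:
        space = ModelSpace(X)
    lml = space.log_marginals(np.asarray(y, dtype=float), prior)
    probs = np.exp(lml - logsumexp(lml))
    probs /= probs.sum()  # remove residual rounding so the contract holds exactly
    prior_probs = np.full(space.n_models, 1.0 / space.n_models)
    return ModelPosterior(log_marginals=lml, posterior_probs=probs, prior_probs=prior_probs)


def posterior_inclusion_probabilities(post: ModelPosterior) -> np.ndarray:
    """PIP of each covariate: total posterior mass of models that include it."""
    probs = np.asarray(post.posterior_probs, dtype=float)
    if abs(probs.sum() - 1.0) > _NORMALIZATION_TOL:
        raise ValueError("posterior is not normalized")
    k = post.k
    masks = np.arange(len(probs), dtype=np.int64)
    membership = ((masks[:, None] >> np.arange(k)) & 1).astype(float)
    return membership.T @ probs


@dataclass(frozen=True)
class AveragedCoefficients:
    """Unconditional model-averaged posterior coefficient means and their signs."""

    mean: np.ndarray
    sign: np.ndarray


def model_averaged_coefficients(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    post: ModelPosterior,
    prior: GPrior,
    space: ModelSpace | None = None,
) -> AveragedCoefficients:
    """Model-averaged posterior means of the k coefficients at one voxel.

    Within a model the conditional posterior mean is the least-squares
    estimate on centered data shrunk by 1/(1+g); excluded covariates
    contribute zero. The unconditional mean weights these by the
    posterior model probabilities supplied in ``post``.
    """
    if space is None:
        space = ModelSpace(X)
    probs = np.asarray(post.posterior_probs, dtype=float)
    if len(probs) != space.n_models:
        raise ValueError("posterior and design disagree on the number of models")
    if abs(probs.sum() - 1.0) > _NORMALIZATION_TOL:
        raise ValueError("posterior is not normalized")
    y = _check_response(np.asarray(y, dtype=float), space.n)
    yc = y - y.mean()
    betas = (space._B @ yc) / (1.0 + prior.g)
    weighted = betas * probs[space._row_model]
    mean = np.asarray(space._scatter @ weighted).reshape(-1)
    return AveragedCoefficients(mean=mean, sign=np.sign(mean))
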