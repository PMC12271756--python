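"""Generative model: annotation-softmax prior and collapsed marginal likelihood.

The model is a Bayesian variance-components ("GCTA-style") regression for a
standardized phenotype ``Y`` on a standardized participants x features matrix
``X`` with ``B >> n``::

    Y = X beta + eps,   eps ~ N(0, (1 - h2) I_n)
    beta ~ N(0, h2 * Psi)

where ``Psi = diag(psi_1, ..., psi_B)`` allocates the total prior variance
``h2`` across features through a softmax of per-feature annotation scores::

    psi_k = exp(z_k' alpha) / sum_j exp(z_j' alpha)

With ``alpha = 0`` every feature receives ``h2 / B`` and the model reduces to
the homoscedastic GCTA prior.  Hyperpriors are ``h2 ~ Beta(a, d)`` and
``alpha ~ N(0, sigma_alpha_sq I_M)``.

Because ``n << B``, inference works with the n-dimensional marginal
likelihood obtained by integrating ``beta`` out analytically::

    Y | h2, alpha ~ N(0, V),   V = h2 * X Psi X' + (1 - h2) I_n
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "ModelData",
    "PriorSpec",
    "ParameterState",
    "compute_psi",
    "enrichment_ratio",
    "log_prior",
    "log_marginal_likelihood",
    "MarginalLikelihood",
]

# h2 proposals outside this open interval are rejected, never clamped, so the
# chain's stationary distribution stays exact on (0, 1).
H2_EPS = 1e-8

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class ModelData:
    """Standardized design matrix, phenotype and feature annotations.

    Parameters
    ----------
    X
        ``(n, B)`` matrix of standardized imaging-derived features (each
        column mean 0, unit variance).
    Y
        ``(n,)`` standardized phenotype vector.
    Z
        ``(B, M)`` annotation matrix (binary or continuous).  ``M = 0``
        (shape ``(B, 0)``) gives the homoscedastic no-annotation model.
    feature_ids, annotation_names
        Optional identifiers used in reports and for alignment checks.
    validate
        When True (default), check standardization and finiteness.
    """

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray | None = None
    feature_ids: list[str] | None = None
    annotation_names: list[str] | None = None
    validate: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D participants x features matrix")
        n, B = self.X.shape
        if self.Y.shape[0] != n:
            raise ValueError(f"Y has length {self.Y.shape[0]}, expected {n}")
        if self.Z is None:
            self.Z = np.empty((B, 0))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != B:
            if self.Z.shape[1] == B:  # tolerate a transposed single column
                self.Z = self.Z.T
            else:
                raise ValueError(
                    f"Z has {self.Z.shape[0]} rows, expected B={B}"
                )
        if self.feature_ids is not None and len(self.feature_ids) != B:
            raise ValueError("feature_ids length does not match B")
        if self.annotation_names is not None and len(self.annotation_names) != self.M:
            raise ValueError("annotation_names length does not match M")
        if self.validate:
            self._check_standardized()

    def _check_standardized(self, atol: float = 1e-6) -> None:
        for arr, what in ((self.X, "X"), (self.Y, "Y")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{what} contains non-finite values")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("Z contains non-finite values")
        col_means = self.X.mean(axis=0)
        if np.abs(col_means).max() > 1e-3:
            raise ValueError(
                "columns of X are not centered; standardize X first"
            )
        if abs(float(self.Y.mean())) > 1e-3:
            raise ValueError("Y is not centered; standardize Y first")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def B(self) -> int:
        return self.X.shape[1]

    @property
    def M(self) -> int:
        return self.Z.shape[1]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: ``h2 ~ Beta(a, d)``, ``alpha ~ N(0, sigma_alpha_sq I)``.

    Defaults ``a = d = 1`` (uniform prior on h2) and a diffuse
    ``sigma_alpha_sq = 100``.
    """

    a: float = 1.0
    d: float = 1.0
    sigma_alpha_sq: float = 100.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.d > 0 and self.sigma_alpha_sq > 0):
            raise ValueError("PriorSpec fields must be strictly positive")


@dataclass
class ParameterState:
    """One point in parameter space; ``beta`` is absent in collapsed states."""

    h2: float
    alpha: np.ndarray
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha must be finite")
        if not (H2_EPS < self.h2 < 1.0 - H2_EPS):
            raise ValueError(f"h2={self.h2} outside the open interval (0, 1)")


def compute_psi(Z: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Softmax allocation of prior variance across features.

    Returns the length-B vector ``psi`` with ``psi_k` proportional to
    ``exp(z_k' alpha)`` and ``sum_k psi_k = 1``.  Computed in log space with
    max-subtraction so scores up to ``|z'alpha| ~ 700`` do not overflow.
    Invariant to adding a constant to every score; ``alpha = 0`` gives the
    uniform allocation ``1/B``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be finite")
    if Z.shape[1] != alpha.shape[0]:
        raise ValueError(
            f"Z has {Z.shape[1]} annotation columns but alpha has length "
            f"{alpha.shape[0]}"
        )
    scores = Z @ alpha
    scores -= scores.max()
    w = np.exp(scores)
    return w / w.sum()


def enrichment_ratio(alpha_m: float) -> float:
    """Per-feature variance multiplier ``exp(alpha_m)`` for a binary annotation.

    A weight of 0.19 means each annotated feature explains
    ``exp(0.19) = 1.21`` times as much variance, on average, as an
    unannotated one.
    """
    if not np.isfinite(alpha_m):
        raise ValueError("annotation weight must be finite")
    return float(np.exp(alpha_m))


def log_prior(
    state: ParameterState, prior: PriorSpec, psi: np.ndarray | None = None
) -> float:
    """Joint log prior density of ``(h2, alpha[, beta])``.

    The beta term ``log N(beta; 0, h2 * diag(psi))`` is included only when
    the state carries an explicit ``beta`` (requires ``psi``).
    """
    if not (H2_EPS < state.h2 < 1.0 - H2_EPS):
        raise ValueError("h2 outside the open interval (0, 1)")
    lp = float(stats.beta.logpdf(state.h2, prior.a, prior.d))
    alpha = state.alpha
    lp += float(
        -0.5 * alpha.size * (_LOG_2PI + np.log(prior.sigma_alpha_sq))
        - 0.5 * (alpha @ alpha) / prior.sigma_alpha_sq
    )
    if state.beta is not None:
        if psi is None:
            raise ValueError("psi is required to evaluate the beta prior term")
        var = state.h2 * np.asarray(psi, dtype=float)
        beta = np.asarray(state.beta, dtype=float)
        lp += float(
            -0.5 * np.sum(_LOG_2PI + np.log(var) + beta**2 / var)
        )
    return lp


def log_marginal_likelihood(
    data: ModelData, h2: float, alpha: np.ndarray
) -> float:
    """Collapsed log likelihood ``log N(Y; 0, h2 X Psi X' + (1-h2) I_n)``.

    Formed explicitly as an ``n x n`` covariance (cost O(n^2 B)) since the
    intended regime is ``B >> n``; no B-dimensional formulation is provided
    for ``B < n``.  Evaluated through a Cholesky factorization.
    """
    if not (H2_EPS < h2 < 1.0 - H2_EPS):
        raise ValueError("h2 outside the open interval (0, 1)")
    psi = compute_psi(data.Z, alpha) if data.M else np.full(data.B, 1.0 / data.B)
    V = h2 * ((data.X * psi) @ data.X.T)
    V[np.diag_indices_from(V)] += 1.0 - h2
    return _gaussian_logpdf_chol(data.Y, V)


def _gaussian_logpdf_chol(y: np.ndarray, V: np.ndarray) -> float:
    V = 0.5 * (V + V.T)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "marginal covariance is not positive definite "
            "(degenerate X or h2 at a boundary)"
        ) from err
    w = linalg.solve_triangular(L, y, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (y.size * _LOG_2PI + logdet + w @ w))


@dataclass
class _LikelihoodState:
    """Cached factorization of V at one (h2, alpha); reused for beta draws."""

    value: float
    h2: float
    psi: np.ndarray  # per-feature prior-variance shares
    _chol: np.ndarray | None = None  # lower Cholesky of V (gram/dense paths)
    _eig_diag: np.ndarray | None = None  # eigenvalues of V (single-group path)

    def solve(self, rhs: np.ndarray, evaluator: "MarginalLikelihood") -> np.ndarray:
        """Apply V^{-1} to ``rhs`` using the cached factorization."""
        if self._chol is not None:
            return linalg.cho_solve((self._chol, True), rhs, check_finite=False)
        # eigen path: V = U diag(d) U'
        U = evaluator._eigvecs
        return U @ ((U.T @ rhs) / self._eig_diag)


class MarginalLikelihood:
    """Efficient repeated evaluation of the collapsed likelihood.

    Strategy depends on the annotation structure:

    * features grouped by their unique annotation rows; when the number of
      groups G is small (binary network annotations give G <= M + 1) the
      per-group Gram matrices ``X_g X_g'`` are precomputed once and each
      evaluation costs O(G n^2 + n^3) instead of O(n^2 B);
    * a single group (e.g. no annotations) makes Psi independent of alpha,
      so ``X X' / B`` is eigendecomposed once and each evaluation is O(n);
    * otherwise fall back to the dense O(n^2 B) build.
    """

    def __init__(self, data: ModelData, max_gram_groups: int = 64) -> None:
        self.data = data
        n, B = data.n, data.B
        if data.M == 0:
            self._group_rows = np.zeros((1, 0))
            self._codes = np.zeros(B, dtype=np.intp)
        else:
            self._group_rows, self._codes = np.unique(
                data.Z, axis=0, return_inverse=True
            )
        self.n_groups = self._group_rows.shape[0]
        self._counts = np.bincount(self._codes, minlength=self.n_groups).astype(float)

        self._eigvals: np.ndarray | None = None
        self._eigvecs: np.ndarray | None = None
        self._grams: np.ndarray | None = None
        if self.n_groups == 1:
            A = (data.X @ data.X.T) / B
            vals, vecs = linalg.eigh(0.5 * (A + A.T))
            self._eigvals = np.maximum(vals, 0.0)
            self._eigvecs = vecs
            self._y_rot = vecs.T @ data.Y
        elif self.n_groups <= max_gram_groups:
            grams = np.empty((self.n_groups, n * n))
            for g in range(self.n_groups):
                Xg = data.X[:, self._codes == g]
                grams[g] = (Xg @ Xg.T).ravel()
            self._grams = grams

    def group_psi(self, alpha: np.ndarray) -> np.ndarray:
        """Per-feature softmax weight shared by each annotation group."""
        scores = self._group_rows @ alpha
        scores = scores - scores.max()
        e = np.exp(scores)
        return e / (self._counts @ e)

    def psi(self, alpha: np.ndarray) -> np.ndarray:
        """Full length-B vector of prior-variance shares."""
        return self.group_psi(np.atleast_1d(np.asarray(alpha, float)))[self._codes]

    def __call__(self, h2: float, alpha: np.ndarray) -> _LikelihoodState:
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        if not (H2_EPS < h2 < 1.0 - H2_EPS):
            raise ValueError("h2 outside the open interval (0, 1)")
        n = self.data.n
        if self._eigvals is not None:
            d = h2 * self._eigvals + (1.0 - h2)
            value = float(
                -0.5 * (n * _LOG_2PI + np.sum(np.log(d)) + np.sum(self._y_rot**2 / d))
            )
            psi = np.full(self.data.B, 1.0 / self.data.B)
            return _LikelihoodState(value, h2, psi, _eig_diag=d)
        gpsi = self.group_psi(alpha)
        if self._grams is not None:
            V = (h2 * gpsi @ self._grams).reshape(n, n)
        else:
            psi_full = gpsi[self._codes]
            V = h2 * ((self.data.X * psi_full) @ self.data.X.T)
        V[np.diag_indices_from(V)] += 1.0 - h2
        try:
            L = linalg.cholesky(V, lower=True, check_finite=False, overwrite_a=True)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                "marginal covariance is not positive definite"
            ) from err
        w = linalg.solve_triangular(L, self.data.Y, lower=True, check_finite=False)
        value = float(
            -0.5 * (n * _LOG_2PI + 2.0 * np.sum(np.log(np.diag(L))) + w @ w)
        )
        return _LikelihoodState(value, h2, gpsi[self._codes], _chol=L)
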