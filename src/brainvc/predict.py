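"""Out-of-sample prediction: polyvertex scores and incremental variance explained.

A polyvertex score is the linear predictor ``PVS = X_new @ beta_hat``
applied to a new cohort — the imaging analogue of a polygenic score.  Its
value is assessed as (a) the squared correlation with the new phenotype
(the out-of-sample h2 estimate) and (b) the incremental R^2 over a
covariate-only regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .report import pool_chains
from .sampler import PosteriorDraws

__all__ = [
    "TrainedCoefficients",
    "PredictionResult",
    "polyvertex_score",
    "incremental_r2",
    "out_of_sample_h2",
    "out_of_sample_h2_value",
]


@dataclass
class TrainedCoefficients:
    """Posterior point estimate of the effect vector, with provenance.

    ``point_estimate`` records the convention used ("median" of the pooled
    chains by default, "mean" when beta draws were not stored).
    """

    beta_hat: np.ndarray
    feature_ids: list[str]
    point_estimate: str = "median"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=float).ravel()
        if len(self.feature_ids) != self.beta_hat.size:
            raise ValueError("feature_ids length does not match beta_hat")

    @classmethod
    def from_draws(
        cls,
        draws: PosteriorDraws,
        feature_ids: list[str] | None = None,
        point_estimate: str = "median",
        **metadata,
    ) -> "TrainedCoefficients":
        if point_estimate == "median":
            if draws.beta_draws is None:
                raise ValueError(
                    "median point estimate needs stored beta draws; "
                    "use point_estimate='mean'"
                )
            pooled = pool_chains(draws)["beta"]
            beta_hat = np.median(pooled, axis=0)
        elif point_estimate == "mean":
            beta_hat = draws.beta_mean
        else:
            raise ValueError("point_estimate must be 'median' or 'mean'")
        if feature_ids is None:
            feature_ids = [f"f{k}" for k in range(beta_hat.size)]
        return cls(beta_hat, list(feature_ids), point_estimate, metadata)


@dataclass
class PredictionResult:
    pvs: np.ndarray
    full_r2: float
    covariate_r2: float

    @property
    def incremental_r2(self) -> float:
        return self.full_r2 - self.covariate_r2


def polyvertex_score(
    X_new: np.ndarray,
    coef: TrainedCoefficients,
    feature_ids: list[str] | None = None,
) -> np.ndarray:
    """Linear predictor ``X_new @ beta_hat`` with feature alignment by ID.

    When ``feature_ids`` of the new matrix are given they must match the
    training IDs as a set; columns are reordered accordingly.  Mismatches
    raise (silent positional alignment across cohorts is the classic
    cross-study bug).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != coef.beta_hat.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} features, coefficients have "
            f"{coef.beta_hat.size}"
        )
    if feature_ids is not None:
        if list(feature_ids) != list(coef.feature_ids):
            pos = {fid: k for k, fid in enumerate(feature_ids)}
            missing = [f for f in coef.feature_ids if f not in pos]
            extra = [f for f in feature_ids if f not in set(coef.feature_ids)]
            if missing or extra:
                raise ValueError(
                    f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
                )
            X_new = X_new[:, [pos[f] for f in coef.feature_ids]]
    return X_new @ coef.beta_hat


def _ols_r2(y: np.ndarray, design: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("collinear design (rank-deficient); remove redundant columns")
    resid = y - design @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss


def incremental_r2(
    Y_new: np.ndarray,
    pvs: np.ndarray,
    covariates: np.ndarray | None = None,
) -> PredictionResult:
    """Variance in ``Y_new`` explained by the score over and above covariates.

    Fits ordinary least squares of Y on [intercept, covariates] and on
    [intercept, covariates, pvs]; the incremental R^2 is the difference of
    the two (plain, not adjusted) coefficients of determination.
    """
    Y_new = np.asarray(Y_new, dtype=float).ravel()
    pvs = np.asarray(pvs, dtype=float).ravel()
    if not (np.all(np.isfinite(Y_new)) and np.all(np.isfinite(pvs))):
        raise ValueError("missing or non-finite values in Y or PVS")
    n = Y_new.size
    intercept = np.ones((n, 1))
    if covariates is None:
        base = intercept
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        base = np.hstack([intercept, covariates])
    cov_r2 = _ols_r2(Y_new, base) if base.shape[1] > 1 else 0.0
    full_r2 = _ols_r2(Y_new, np.hstack([base, pvs[:, None]]))
    return PredictionResult(pvs=pvs, full_r2=full_r2, covariate_r2=cov_r2)


def out_of_sample_h2_value(
    X_test: np.ndarray, Y_test: np.ndarray, beta_hat: np.ndarray
) -> float:
    """Squared correlation of ``X_test @ beta_hat`` with ``Y_test``."""
    score = np.asarray(X_test) @ np.asarray(beta_hat)
    if score.std() == 0:
        raise ValueError("zero-variance polyvertex score")
    r = np.corrcoef(score, np.asarray(Y_test, dtype=float).ravel())[0, 1]
    return float(r**2)


def out_of_sample_h2(
    X_test: np.ndarray,
    Y_test: np.ndarray,
    coef: TrainedCoefficients,
    feature_ids: list[str] | None = None,
) -> float:
    """Out-of-sample h2 estimate: squared correlation of the PVS with Y_test.

    With error-free coefficients (infinite training data) this approaches
    the true fraction of variance explained; finite training shrinks it
    below the in-sample estimate.
    """
    score = polyvertex_score(X_test, coef, feature_ids)
    if score.std() == 0:
        raise ValueError("zero-variance polyvertex score")
    r = np.corrcoef(score, np.asarray(Y_test, dtype=float).ravel())[0, 1]
    return float(r**2)
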