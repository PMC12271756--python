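"""Collapsed Metropolis MCMC for (h2, alpha) with exact conditional beta draws.

The sampler targets the collapsed posterior ``p(h2, alpha | Y)`` obtained by
integrating the B-dimensional effect vector out of the model analytically:
random-walk Metropolis on ``alpha`` (Gaussian proposal, joint by default)
and on ``logit(h2)`` (with the Jacobian correction), both accepted against
the n-dimensional marginal likelihood.  This mixes far better than
Metropolis-within-Gibbs conditioning on ``beta``, because ``beta`` and
``h2`` are strongly coupled a posteriori.

``beta`` is drawn exactly from its Gaussian conditional posterior once per
collected iteration — for recording, the running posterior mean, and the
per-iteration empirical variance explained ``R^2 = var(X beta) / var(Y)`` —
using a perturbation trick that never forms a B x B matrix:
draw ``u ~ N(0, h2 Psi)``, ``delta ~ N(0, (1-h2) I_n)``, solve the n x n
system ``V w = Y - (X u + delta)`` and return
``beta = u + h2 Psi X' w``.  Proposal scales adapt during burn-in
(Robbins-Monro on the log scale) and are frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .prior_model import (
    H2_EPS,
    MarginalLikelihood,
    ModelData,
    PriorSpec,
    _LikelihoodState,
)

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "run_mcmc",
    "sample_beta_conditional",
    "mh_update_alpha",
    "mh_update_h2",
    "simulation_based_calibration",
    "SbcReport",
]


@dataclass(frozen=True)
class McmcConfig:
    """Chain schedule and proposal settings.

    Defaults follow the real-data schedule: 10,000 iterations per chain
    with a 3,000-iteration burn-in, thinning rate 10, six chains.
    """

    n_iterations: int = 10_000
    n_burnin: int = 3_000
    thin: int = 10
    n_chains: int = 6
    seed: int = 0
    proposal_sd_alpha: float = 0.5
    proposal_sd_h2: float = 0.5
    adapt: bool = True
    alpha_update: str = "hybrid"  # "hybrid" | "joint" | "componentwise"
    target_acceptance: float = 0.3
    store_beta: bool = True

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin must be >= 1 and n_chains >= 1")
        if self.proposal_sd_alpha <= 0 or self.proposal_sd_h2 <= 0:
            raise ValueError("proposal scales must be positive")
        if self.alpha_update not in ("hybrid", "joint", "componentwise"):
            raise ValueError(
                "alpha_update must be 'hybrid', 'joint' or 'componentwise'"
            )

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, per chain.

    ``beta_draws`` is ``None`` when storage was disabled; ``beta_mean``
    (the running posterior mean over all kept iterations, pooled across
    chains) is always available.
    """

    h2_draws: np.ndarray  # (chains, kept)
    alpha_draws: np.ndarray  # (chains, kept, M)
    r2_draws: np.ndarray  # (chains, kept)
    beta_mean: np.ndarray  # (B,)
    beta_draws: np.ndarray | None  # (chains, kept, B) or None
    acceptance_rates: dict[str, np.ndarray]  # per chain, post burn-in
    config: McmcConfig
    annotation_names: list[str] | None = None

    @property
    def n_chains(self) -> int:
        return self.h2_draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.h2_draws.shape[1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("h2", data=self.h2_draws)
            f.create_dataset("alpha", data=self.alpha_draws)
            f.create_dataset("r2", data=self.r2_draws)
            f.create_dataset("beta_mean", data=self.beta_mean)
            if self.beta_draws is not None:
                f.create_dataset("beta", data=self.beta_draws)
            for key, val in self.acceptance_rates.items():
                f.create_dataset(f"acceptance/{key}", data=val)
            cfg = f.create_group("config")
            for key, val in vars(self.config).items():
                cfg.attrs[key] = val
            if self.annotation_names:
                f.attrs["annotation_names"] = self.annotation_names

    @classmethod
    def from_hdf5(cls, path) -> "PosteriorDraws":
        import h5py

        with h5py.File(path, "r") as f:
            cfg = McmcConfig(**{k: v.item() if hasattr(v, "item") else v
                                for k, v in f["config"].attrs.items()})
            names = list(f.attrs.get("annotation_names", [])) or None
            return cls(
                h2_draws=f["h2"][()],
                alpha_draws=f["alpha"][()],
                r2_draws=f["r2"][()],
                beta_mean=f["beta_mean"][()],
                beta_draws=f["beta"][()] if "beta" in f else None,
                acceptance_rates={k: f["acceptance"][k][()]
                                  for k in f["acceptance"]},
                config=cfg,
                annotation_names=names,
            )


def sample_beta_conditional(
    data: ModelData,
    h2: float,
    psi: np.ndarray,
    rng: np.random.Generator,
    lik_state: _LikelihoodState | None = None,
    evaluator: MarginalLikelihood | None = None,
) -> np.ndarray:
    """One exact draw from the conditional posterior of beta.

    The target is ``N(Sigma X'Y / (1-h2), Sigma)`` with
    ``Sigma = [X'X/(1-h2) + (h2 diag(psi))^{-1}]^{-1}``; the draw is built
    from an n x n solve only.  A cached likelihood factorization at the
    same (h2, psi) can be passed to avoid refactorizing V.
    """
    psi = np.asarray(psi, dtype=float)
    u = rng.standard_normal(data.B) * np.sqrt(h2 * psi)
    delta = rng.standard_normal(data.n) * np.sqrt(1.0 - h2)
    resid = data.Y - (data.X @ u + delta)
    if lik_state is not None and evaluator is not None:
        w = lik_state.solve(resid, evaluator)
    else:
        from scipy import linalg

        V = h2 * ((data.X * psi) @ data.X.T)
        V[np.diag_indices_from(V)] += 1.0 - h2
        try:
            w = linalg.solve(0.5 * (V + V.T), resid, assume_a="pos")
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                "singular marginal covariance (duplicated participants "
                "or h2 at a boundary)"
            ) from err
    return u + h2 * psi * (data.X.T @ w)


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _log_prior_h2(h2: float, prior: PriorSpec) -> float:
    return float(stats.beta.logpdf(h2, prior.a, prior.d))


def _log_prior_alpha(alpha: np.ndarray, prior: PriorSpec) -> float:
    return float(-0.5 * (alpha @ alpha) / prior.sigma_alpha_sq)


@dataclass
class _ChainState:
    h2: float
    alpha: np.ndarray
    lik: _LikelihoodState
    log_post: float  # marginal loglik + log priors of (h2, alpha)


def _make_state(
    evaluator: MarginalLikelihood, h2: float, alpha: np.ndarray, prior: PriorSpec
) -> _ChainState:
    lik = evaluator(h2, alpha)
    lp = lik.value + _log_prior_h2(h2, prior) + _log_prior_alpha(alpha, prior)
    return _ChainState(h2, alpha, lik, lp)


def mh_update_alpha(
    evaluator: MarginalLikelihood,
    state: _ChainState,
    prior: PriorSpec,
    scale: np.ndarray | float,
    rng: np.random.Generator,
    component: int | None = None,
) -> tuple[_ChainState, bool]:
    """Random-walk Metropolis step on alpha against the collapsed posterior.

    ``component=None`` proposes all M weights jointly; otherwise only the
    given component moves.
    """
    alpha = state.alpha
    if alpha.size == 0:
        return state, True
    prop = alpha.copy()
    if component is None:
        prop = alpha + np.asarray(scale) * rng.standard_normal(alpha.size)
    else:
        prop[component] = alpha[component] + float(np.asarray(scale)) * rng.standard_normal()
    if not np.all(np.isfinite(prop)):
        return state, False
    lik = evaluator(state.h2, prop)
    log_post = lik.value + _log_prior_h2(state.h2, prior) + _log_prior_alpha(prop, prior)
    if np.log(rng.uniform()) < log_post - state.log_post:
        return _ChainState(state.h2, prop, lik, log_post), True
    return state, False


def mh_update_h2(
    evaluator: MarginalLikelihood,
    state: _ChainState,
    prior: PriorSpec,
    scale: float,
    rng: np.random.Generator,
) -> tuple[_ChainState, bool]:
    """Random walk on logit(h2) with the change-of-variables Jacobian.

    Proposals landing outside ``(1e-8, 1 - 1e-8)`` are rejected outright.
    """
    eta = _logit(state.h2) + scale * rng.standard_normal()
    h2_prop = float(1.0 / (1.0 + np.exp(-eta)))
    if not (H2_EPS < h2_prop < 1.0 - H2_EPS):
        return state, False
    lik = evaluator(h2_prop, state.alpha)
    log_post = (
        lik.value + _log_prior_h2(h2_prop, prior) + _log_prior_alpha(state.alpha, prior)
    )
    # Jacobian of h2 = sigmoid(eta): dh2/deta = h2 (1 - h2)
    log_jac_ratio = np.log(h2_prop * (1.0 - h2_prop)) - np.log(
        state.h2 * (1.0 - state.h2)
    )
    if np.log(rng.uniform()) < log_post - state.log_post + log_jac_ratio:
        return _ChainState(h2_prop, state.alpha, lik, log_post), True
    return state, False


def _run_single_chain(
    evaluator: MarginalLikelihood,
    prior: PriorSpec,
    config: McmcConfig,
    chain_seed: int,
) -> dict:
    data = evaluator.data
    rng = np.random.default_rng(chain_seed)
    M = data.M
    h2_init = float(np.clip(rng.beta(prior.a, prior.d), 1e-3, 1.0 - 1e-3))
    state = _make_state(evaluator, h2_init, np.zeros(M), prior)
    if not np.isfinite(state.log_post):
        raise ValueError(
            "non-finite posterior at initialization; is the input standardized?"
        )

    mode = config.alpha_update if M > 1 else "joint"
    log_s_joint = np.log(config.proposal_sd_alpha)
    log_s_comp = np.full(M or 1, np.log(config.proposal_sd_alpha))
    log_s_h2 = np.log(config.proposal_sd_h2)
    # scalar updates mix best near 44% acceptance, joint multivariate lower
    target_joint = 0.44 if M == 1 else config.target_acceptance

    kept = config.n_kept
    h2_out = np.empty(kept)
    alpha_out = np.empty((kept, M))
    r2_out = np.empty(kept)
    beta_out = np.empty((kept, data.B)) if config.store_beta else None
    beta_sum = np.zeros(data.B)
    acc = {"alpha": 0, "h2": 0}
    n_post = 0
    var_y = float(np.var(data.Y))
    k = 0
    for it in range(config.n_iterations):
        in_burnin = it < config.n_burnin
        gamma = (it + 1) ** -0.6 if (config.adapt and in_burnin) else 0.0
        if M:
            n_prop = 0
            n_acc = 0
            if mode in ("joint", "hybrid"):
                state, ok = mh_update_alpha(
                    evaluator, state, prior, np.exp(log_s_joint), rng
                )
                n_prop += 1
                n_acc += ok
                if gamma:
                    log_s_joint += gamma * (float(ok) - target_joint)
            if mode == "componentwise":
                for m in rng.permutation(M):
                    state, ok = mh_update_alpha(
                        evaluator, state, prior, np.exp(log_s_comp[m]), rng,
                        component=m,
                    )
                    n_prop += 1
                    n_acc += ok
                    if gamma:
                        log_s_comp[m] += gamma * (float(ok) - 0.44)
            elif mode == "hybrid":
                # one extra single-component move per iteration (random scan)
                m = int(rng.integers(M))
                state, ok = mh_update_alpha(
                    evaluator, state, prior, np.exp(log_s_comp[m]), rng,
                    component=m,
                )
                n_prop += 1
                n_acc += ok
                if gamma:
                    log_s_comp[m] += gamma * (float(ok) - 0.44)
            acc_inc = n_acc / n_prop
        else:
            acc_inc = np.nan
        state, ok_h2 = mh_update_h2(evaluator, state, prior, np.exp(log_s_h2), rng)
        if gamma:
            log_s_h2 += gamma * (float(ok_h2) - 0.44)
        if not in_burnin:
            n_post += 1
            if M:
                acc["alpha"] += acc_inc
            acc["h2"] += ok_h2
            if (it - config.n_burnin) % config.thin == config.thin - 1 and k < kept:
                beta = sample_beta_conditional(
                    data, state.h2, state.lik.psi, rng,
                    lik_state=state.lik, evaluator=evaluator,
                )
                h2_out[k] = state.h2
                alpha_out[k] = state.alpha
                r2_out[k] = float(np.var(data.X @ beta)) / var_y
                beta_sum += beta
                if beta_out is not None:
                    beta_out[k] = beta
                k += 1
    if k == 0:
        raise ValueError("no iterations kept after burn-in and thinning")
    return {
        "h2": h2_out[:k],
        "alpha": alpha_out[:k],
        "r2": r2_out[:k],
        "beta": None if beta_out is None else beta_out[:k],
        "beta_sum": beta_sum,
        "n_beta": k,
        "acc_alpha": acc["alpha"] / max(n_post, 1) if M else np.nan,
        "acc_h2": acc["h2"] / max(n_post, 1),
    }


def run_mcmc(
    data: ModelData,
    prior: PriorSpec | None = None,
    config: McmcConfig | None = None,
    evaluator: MarginalLikelihood | None = None,
) -> PosteriorDraws:
    """Run independent chains and collect thinned post-burn-in draws.

    Chain ``c`` uses seed ``config.seed + c``; all randomness flows through
    one generator per chain.  Per iteration: a collapsed Metropolis update
    of alpha, then of h2, and on collected iterations an exact conditional
    draw of beta with its empirical ``R^2``.
    """
    prior = prior or PriorSpec()
    config = config or McmcConfig()
    if config.n_kept < 1:
        raise ValueError("schedule keeps zero draws; increase n_iterations")
    evaluator = evaluator or MarginalLikelihood(data)
    chains = [
        _run_single_chain(evaluator, prior, config, config.seed + c)
        for c in range(config.n_chains)
    ]
    kept = min(ch["h2"].size for ch in chains)
    beta_draws = None
    if config.store_beta:
        beta_draws = np.stack([ch["beta"][:kept] for ch in chains])
    beta_mean = sum(ch["beta_sum"] for ch in chains) / sum(
        ch["n_beta"] for ch in chains
    )
    return PosteriorDraws(
        h2_draws=np.stack([ch["h2"][:kept] for ch in chains]),
        alpha_draws=np.stack([ch["alpha"][:kept] for ch in chains]),
        r2_draws=np.stack([ch["r2"][:kept] for ch in chains]),
        beta_mean=beta_mean,
        beta_draws=beta_draws,
        acceptance_rates={
            "alpha": np.array([ch["acc_alpha"] for ch in chains]),
            "h2": np.array([ch["acc_h2"] for ch in chains]),
        },
        config=config,
        annotation_names=data.annotation_names,
    )


@dataclass
class SbcReport:
    """Rank statistics from simulation-based calibration.

    Under a correct sampler the rank of each true parameter among the
    thinned posterior draws is uniform on {0, ..., L}; ``pvalues`` holds a
    chi-square uniformity test per parameter over binned ranks.
    """

    ranks: dict[str, np.ndarray]
    n_draws_per_replicate: int
    pvalues: dict[str, float] = field(default_factory=dict)
    n_bins: int = 10

    def __post_init__(self) -> None:
        L = self.n_draws_per_replicate
        edges = np.linspace(0, L + 1, self.n_bins + 1)
        for name, r in self.ranks.items():
            counts, _ = np.histogram(r, bins=edges)
            self.pvalues[name] = float(stats.chisquare(counts).pvalue)


def simulation_based_calibration(
    prior: PriorSpec | None = None,
    n: int = 100,
    B: int = 200,
    M: int = 2,
    n_replicates: int = 100,
    annotation_fraction: float = 0.25,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> SbcReport:
    """Self-consistency check of the sampler on prior-predictive data.

    For each replicate, (h2, alpha, beta) are drawn from the prior, a
    phenotype is generated from the model (no post-hoc standardization,
    so the generative and inferential models coincide exactly), the chain
    is run, and the rank of each true parameter among the kept draws is
    recorded.  Ranks are uniform iff the sampler targets the right
    posterior.
    """
    prior = prior or PriorSpec(sigma_alpha_sq=0.5)
    mcmc = mcmc or McmcConfig(
        n_iterations=1_200, n_burnin=400, thin=8, n_chains=1,
        store_beta=False,
    )
    rng = np.random.default_rng(seed)
    # fixed disjoint binary annotations
    Z = np.zeros((B, M))
    size = int(B * annotation_fraction)
    for m in range(M):
        Z[m * size:(m + 1) * size, m] = 1.0
    ranks_h2 = np.empty(n_replicates, dtype=int)
    ranks_alpha = np.empty((n_replicates, M), dtype=int)
    L = None
    for rep in range(n_replicates):
        h2_true = float(np.clip(rng.beta(prior.a, prior.d), 1e-3, 1 - 1e-3))
        alpha_true = rng.normal(0.0, np.sqrt(prior.sigma_alpha_sq), size=M)
        X = rng.standard_normal((n, B))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        from .prior_model import compute_psi

        psi = compute_psi(Z, alpha_true)
        beta = rng.standard_normal(B) * np.sqrt(h2_true * psi)
        # Y deliberately left uncentered/unscaled: SBC requires the
        # generative and inferential models to coincide exactly.
        Y = X @ beta + rng.standard_normal(n) * np.sqrt(1.0 - h2_true)
        data = ModelData(X, Y, Z, validate=False)
        cfg_rep = McmcConfig(**{**vars(mcmc), "seed": int(rng.integers(2**31 - 1))})
        draws = run_mcmc(data, prior, cfg_rep)
        h2_pool = draws.h2_draws.ravel()
        alpha_pool = draws.alpha_draws.reshape(-1, M)
        L = h2_pool.size
        ranks_h2[rep] = int(np.sum(h2_pool < h2_true))
        ranks_alpha[rep] = np.sum(alpha_pool < alpha_true, axis=0)
    ranks = {"h2": ranks_h2}
    for m in range(M):
        ranks[f"alpha_{m}"] = ranks_alpha[:, m]
    return SbcReport(ranks=ranks, n_draws_per_replicate=int(L))
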