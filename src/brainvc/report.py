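"""Posterior summarization and simulation-study scoring.

Chains are pooled by intermixing: post-burn-in, thinned draws from all
chains are concatenated per parameter before computing medians and
equal-tailed 95% percentile credible intervals (linear interpolation
between order statistics; equal-tailed, not HPD, matching the printed
asymmetric intervals).  Enrichment ratios exponentiate the alpha
summaries — exact for percentile intervals since exp is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = [
    "pool_chains",
    "credible_interval",
    "summarize",
    "PosteriorSummary",
    "evaluate_coverage",
    "CoverageReport",
    "significance_flag",
    "write_summary_table",
]


def pool_chains(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Concatenate kept draws across chains, per parameter."""
    n_pooled = draws.n_chains * draws.n_kept
    pooled = {
        "h2": draws.h2_draws.reshape(n_pooled),
        "alpha": draws.alpha_draws.reshape(n_pooled, draws.alpha_draws.shape[-1]),
        "r2": draws.r2_draws.reshape(n_pooled),
    }
    if draws.beta_draws is not None:
        pooled["beta"] = draws.beta_draws.reshape(n_pooled, draws.beta_draws.shape[-1])
    return pooled


def credible_interval(x: np.ndarray, level: float = 0.95, axis=0):
    """Equal-tailed percentile interval (linear-interpolated order statistics)."""
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [tail, 100.0 - tail], axis=axis)
    return lo, hi


@dataclass
class PosteriorSummary:
    """Medians, 95% CIs and enrichment ratios from intermixed chains.

    ``scalars`` has one row per parameter (h2, each annotation weight, and
    the per-iteration empirical R^2) with columns ``median``, ``lo``,
    ``hi``; annotation rows also carry ``enrichment`` columns
    (``exp`` of the summary) and the significance flag.
    """

    scalars: pd.DataFrame
    n_draws: int
    acceptance: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> pd.Series:
        return self.scalars.loc[name]


def summarize(
    draws: PosteriorDraws, annotation_names: list[str] | None = None
) -> PosteriorSummary:
    """Pool chains and summarize every scalar parameter.

    Requires at least 40 pooled draws for the 95% interval endpoints to be
    interior order statistics.
    """
    pooled = pool_chains(draws)
    if pooled["h2"].size < 40:
        raise ValueError(
            f"only {pooled['h2'].size} pooled draws; need >= 40 to summarize"
        )
    names = annotation_names or draws.annotation_names
    M = pooled["alpha"].shape[1]
    if names is None:
        names = [f"annot_{m + 1}" for m in range(M)]
    rows = {}
    for key, vec in (("h2", pooled["h2"]), ("r2", pooled["r2"])):
        lo, hi = credible_interval(vec)
        rows[key] = {"median": float(np.median(vec)), "lo": float(lo), "hi": float(hi)}
    for m in range(M):
        vec = pooled["alpha"][:, m]
        lo, hi = credible_interval(vec)
        med = float(np.median(vec))
        rows[names[m]] = {
            "median": med,
            "lo": float(lo),
            "hi": float(hi),
            "enrichment": float(np.exp(med)),
            "enrichment_lo": float(np.exp(lo)),
            "enrichment_hi": float(np.exp(hi)),
            "flag": significance_flag(float(lo), float(hi)),
        }
    return PosteriorSummary(
        scalars=pd.DataFrame(rows).T,
        n_draws=int(pooled["h2"].size),
        acceptance=draws.acceptance_rates,
    )


def significance_flag(lo: float, hi: float) -> str:
    """'enriched' / 'depleted' when the 95% CI excludes 0, else 'not-enriched'."""
    if lo > 0:
        return "enriched"
    if hi < 0:
        return "depleted"
    return "not-enriched"


@dataclass
class CoverageReport:
    """Whether credible intervals captured the generating truth.

    ``scalar_covered``: pooled 95% CI contains the true value;
    ``chains_covering``: how many individual chains' CIs contain it;
    ``beta_coverage``: fraction of features whose pooled per-feature 95% CI
    contains the true effect (the Monte Carlo 'coverage rate of beta'),
    with a binomial Monte Carlo standard error.
    """

    scalar_covered: dict[str, bool]
    chains_covering: dict[str, int]
    n_chains: int
    beta_coverage: float | None = None
    beta_coverage_se: float | None = None
    beta_coverage_per_chain: np.ndarray | None = None


def _scalar_series(draws: PosteriorDraws, name: str) -> np.ndarray:
    if name == "h2":
        return draws.h2_draws
    if name.startswith("alpha_"):
        m = int(name.split("_", 1)[1]) - 1
        return draws.alpha_draws[..., m]
    raise KeyError(name)


def evaluate_coverage(
    draws: PosteriorDraws,
    truth: dict[str, float],
    beta_true: np.ndarray | None = None,
    level: float = 0.95,
) -> CoverageReport:
    """Score 95% CI coverage of scalars (pooled and per chain) and of beta.

    ``truth`` maps parameter names ("h2", "alpha_1", "alpha_2", ...) to
    generating values; ``beta_true`` enables the per-feature coverage rate
    from pooled per-feature percentile intervals (computed streaming over
    features).
    """
    scalar_covered, chains_covering = {}, {}
    for name, true_val in truth.items():
        series = _scalar_series(draws, name)  # (chains, kept)
        lo, hi = credible_interval(series.reshape(-1), level)
        scalar_covered[name] = bool(lo <= true_val <= hi)
        los, his = credible_interval(series, level, axis=1)
        chains_covering[name] = int(np.sum((los <= true_val) & (true_val <= his)))
    rep = CoverageReport(
        scalar_covered=scalar_covered,
        chains_covering=chains_covering,
        n_chains=draws.n_chains,
    )
    if beta_true is not None:
        if draws.beta_draws is None:
            raise ValueError("beta coverage requires stored beta draws")
        B = beta_true.size
        pooled = draws.beta_draws.reshape(-1, B)
        hits = np.empty(B, dtype=bool)
        for start in range(0, B, 1024):  # bounded memory for the percentile pass
            sl = slice(start, min(start + 1024, B))
            lo, hi = credible_interval(pooled[:, sl], level, axis=0)
            hits[sl] = (lo <= beta_true[sl]) & (beta_true[sl] <= hi)
        p = float(hits.mean())
        rep.beta_coverage = p
        rep.beta_coverage_se = float(np.sqrt(p * (1 - p) / B))
        per_chain = np.empty(draws.n_chains)
        for c in range(draws.n_chains):
            lo, hi = credible_interval(draws.beta_draws[c], level, axis=0)
            per_chain[c] = float(np.mean((lo <= beta_true) & (beta_true <= hi)))
        rep.beta_coverage_per_chain = per_chain
    return rep


def write_summary_table(
    summaries: dict[str, PosteriorSummary], path, sep: str = "\t"
) -> pd.DataFrame:
    """Write a per-annotation results table (one single-annotation model per row).

    Columns mirror the reporting convention: annotation name, alpha median
    and CI, h2 median and CI, R^2 median and CI, enrichment ratio with CI,
    and the significance flag.
    """

    def _fmt(row) -> str:
        return f"{row['median']:.2f} ({row['lo']:.2f},{row['hi']:.2f})"

    rows = []
    for name, summ in summaries.items():
        a = summ[name] if name in summ.scalars.index else summ.scalars.iloc[2]
        rows.append(
            {
                "annotation": name,
                "alpha": _fmt(a),
                "h2": _fmt(summ["h2"]),
                "r2": _fmt(summ["r2"]),
                "enrichment": (
                    f"{a['enrichment']:.2f} "
                    f"({a['enrichment_lo']:.2f},{a['enrichment_hi']:.2f})"
                ),
                "flag": a["flag"],
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(path, sep=sep, index=False)
    return table
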