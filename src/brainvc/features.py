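"""Edge-feature construction, annotation building and preprocessing.

Turns upstream artifacts into model inputs: per-participant node x node
correlation matrices become Fisher-z edge features (upper-triangle
vectorization), node -> network label tables become within-network binary
edge annotations, and covariate residualization plus column
standardization prepare X and Y for the standardized model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "fisher_z",
    "EdgeFeatureSet",
    "build_edge_features",
    "edge_index",
    "unvectorize_edges",
    "build_within_network_annotation",
    "build_annotation_matrix",
    "residualize",
    "standardize",
    "Standardizer",
    "NETWORKS",
]

#: the 13 named resting-state networks plus the unlabeled category
NETWORKS = (
    "Auditory", "CinguloOperc", "CinguloParietal", "Default", "DorsalAttn",
    "FrontoParietal", "RetrosplenialTemporal", "SMhand", "SMmouth",
    "Salience", "Subcort", "VentralAttn", "Visual",
)
NONE_LABEL = "None"

_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z-transform ``atanh(r)`` of correlations.

    Values with ``|r| >= 1 - 1e-7`` are clipped to that bound (atanh is
    unbounded at +-1) with a warning; ``|r| > 1`` is an error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) >= _CLIP):
        warnings.warn(
            "correlations within 1e-7 of +-1 clipped before Fisher z",
            stacklevel=2,
        )
        r = np.clip(r, -_CLIP, _CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def edge_index(P: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i < j) edge ordering over P nodes."""
    return [(i, j) for i in range(P) for j in range(i + 1, P)]


@dataclass
class EdgeFeatureSet:
    """Participants x edges matrix of Fisher-z connectivities.

    Edges are unordered node pairs in row-major upper-triangle order over
    the declared node order; ``edge_ids`` are "nodeA-nodeB" strings with A
    before B in that order.
    """

    values: np.ndarray  # (participants, edges)
    edges: list[tuple[int, int]]
    node_ids: list[str]
    edge_ids: list[str]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def build_edge_features(
    matrices: np.ndarray,
    node_ids: list[str] | None = None,
    rtol: float = 1e-8,
) -> EdgeFeatureSet:
    """Vectorize per-participant correlation matrices into Fisher-z edges.

    ``matrices`` is ``(participants, P, P)`` (or a single ``(P, P)``
    matrix); each must be symmetric with unit diagonal and share the node
    order.  A P-node parcellation yields ``P (P - 1) / 2`` edge features.
    """
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim == 2:
        matrices = matrices[None]
    n, P, P2 = matrices.shape
    if P != P2:
        raise ValueError("correlation matrices must be square")
    if not np.allclose(matrices, matrices.transpose(0, 2, 1), atol=rtol):
        raise ValueError("asymmetric correlation matrix encountered")
    if not np.allclose(np.diagonal(matrices, axis1=1, axis2=2), 1.0, atol=1e-6):
        raise ValueError("correlation matrices must have unit diagonal")
    if node_ids is None:
        node_ids = [f"node{p}" for p in range(P)]
    iu = np.triu_indices(P, k=1)
    values = fisher_z(matrices[:, iu[0], iu[1]])
    edges = edge_index(P)
    edge_ids = [f"{node_ids[i]}-{node_ids[j]}" for i, j in edges]
    return EdgeFeatureSet(np.atleast_2d(values), edges, list(node_ids), edge_ids)


def unvectorize_edges(
    feature_set: EdgeFeatureSet, participant: int = 0
) -> np.ndarray:
    """Rebuild the symmetric z-matrix (zero diagonal) for one participant."""
    P = len(feature_set.node_ids)
    out = np.zeros((P, P))
    iu = np.triu_indices(P, k=1)
    out[iu] = feature_set.values[participant]
    return out + out.T


def build_within_network_annotation(
    edges: list[tuple[int, int]],
    labels: pd.DataFrame,
    network: str,
    node_ids: list[str] | None = None,
) -> np.ndarray:
    """Binary column: 1 iff both edge endpoints carry the queried network label.

    ``labels`` is a two-column table (node_id, network); nodes outside any
    named network are labeled "None", and querying network="None" marks
    edges between two unlabeled nodes (the "None-None" category).
    """
    if network not in NETWORKS and network != NONE_LABEL:
        raise ValueError(f"unknown network {network!r}")
    labels = labels.rename(columns=dict(zip(labels.columns, ["node_id", "network"])))
    if labels["node_id"].duplicated().any():
        raise ValueError("duplicate node_ids in label table")
    lut = dict(zip(labels["node_id"], labels["network"]))
    if node_ids is None:
        node_ids = list(labels["node_id"])
    try:
        node_net = [lut[nid] for nid in node_ids]
    except KeyError as err:
        raise ValueError(f"edge endpoint {err} missing from label table") from err
    return np.array(
        [float(node_net[i] == network and node_net[j] == network) for i, j in edges]
    )


def build_annotation_matrix(
    feature_set: EdgeFeatureSet,
    labels: pd.DataFrame,
    networks: list[str] | None = None,
) -> pd.DataFrame:
    """Features x annotations table with "Net-Net" column names."""
    networks = list(networks) if networks is not None else list(NETWORKS) + [NONE_LABEL]
    cols = {
        f"{net}-{net}": build_within_network_annotation(
            feature_set.edges, labels, net, feature_set.node_ids
        )
        for net in networks
    }
    return pd.DataFrame(cols, index=feature_set.edge_ids)


def residualize(
    values: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """Least-squares residuals of each column on [intercept, covariates].

    Categorical covariates must already be indicator-coded.  Residuals are
    orthogonal to the covariate span; rank-deficient covariates raise.
    """
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    V = values[:, None] if one_d else values
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != V.shape[0]:
        C = C.T
    design = np.hstack([np.ones((V.shape[0], 1)), C])
    q, r = np.linalg.qr(design)
    if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
        raise ValueError("rank-deficient covariates")
    resid = V - q @ (q.T @ V)
    return resid.ravel() if one_d else resid


class Standardizer:
    """Column standardization with stored moments for held-out data.

    Means and SDs (denominator n-1) are learned from training data and can
    be re-applied to new matrices; zero-variance columns are reported by
    feature ID.
    """

    def __init__(self, feature_ids: list[str] | None = None):
        self.feature_ids = feature_ids
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "Standardizer":
        V = np.atleast_2d(np.asarray(values, dtype=float))
        if V.shape[0] == 1 and np.asarray(values).ndim == 1:
            V = V.T
        self.means_ = V.mean(axis=0)
        self.sds_ = V.std(axis=0, ddof=1)
        bad = np.where(self.sds_ == 0)[0]
        if bad.size:
            ids = (
                [self.feature_ids[k] for k in bad[:5]]
                if self.feature_ids
                else bad[:5].tolist()
            )
            raise ValueError(f"zero-variance columns: {ids}")
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise ValueError("Standardizer not fitted")
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            return (values - self.means_[0]) / self.sds_[0] if self.means_.size == 1 \
                else (values - self.means_) / self.sds_
        return (values - self.means_) / self.sds_


def standardize(
    values: np.ndarray, feature_ids: list[str] | None = None
) -> tuple[np.ndarray, Standardizer]:
    """Standardize columns to mean 0, SD 1 (n-1 denominator).

    Returns the standardized copy and the fitted :class:`Standardizer`
    holding the transformation for held-out data.
    """
    scaler = Standardizer(feature_ids).fit(values)
    return scaler.transform(values), scaler
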