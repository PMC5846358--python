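"""Sequential self-organizing map, Ward clustering and pattern naming.

The movement-pattern classifier is a Kohonen self-organizing map trained
sequentially on min-max-normalized 7-parameter feature vectors. For each
presented vector x the squared Euclidean distance to every node's weight
vector,

    d_j(t) = sum_i (x_i - w_ij(t))^2,

selects the best-matching unit (BMU, the "winner"; ties break to the
lowest node index — argmin over squared distance is equivalent to argmin
over the distance itself), and every node is pulled toward x:

    w_ij(t+1) = w_ij(t) + alpha(t) * h_cj(t) * (x_i - w_ij(t)),

with learning rate alpha(t) and a Gaussian neighborhood
``h_cj = exp(-lattice_dist(c, j)^2 / (2 sigma(t)^2))`` centred on the
winner c. alpha and sigma decay linearly over the total number of
presentations; the presentation order is a fresh seeded permutation each
epoch, and node weights are initialized from distinct data rows (seeded),
so training is bit-for-bit reproducible for a fixed seed.

The trained codebook (R*C weight vectors) is then clustered by Ward's
minimum-variance agglomerative linkage and cut into k=6 clusters — the
six canonical movement patterns. Clusters are named P1..P6 by a
deterministic profile-ranking rule that replaces the reference study's
visual inspection: P1 (line) has the highest mean speed, P6 (stay) the
longest stop time, P3 (cross) the highest acceleration, and the
remaining three are ordered by decreasing speed as P2 (loop), P4
(shaking), P5 (swirl).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .features import FEATURE_NAMES

PATTERNS = ("P1", "P2", "P3", "P4", "P5", "P6")

#: Archetype label of each pattern (the shapes of the six clusters).
PATTERN_ARCHETYPES = {
    "P1": "line",
    "P2": "loop",
    "P3": "cross",
    "P4": "shaking",
    "P5": "swirl",
    "P6": "stay",
}

_MODEL_FORMAT = "daphmove-som"
_MODEL_VERSION = 1


class PatternNamingError(ValueError):
    """Cluster profiles tie; patterns cannot be named automatically."""


@dataclass(frozen=True)
class NormalizationStats:
    """Per-parameter min/max for min-max scaling to [0, 1].

    Held-out vectors are always scaled with the *training* statistics,
    never their own range.
    """

    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mins) / (self.maxs - self.mins)

    def inverse(self, Xn: np.ndarray) -> np.ndarray:
        Xn = np.asarray(Xn, dtype=float)
        return Xn * (self.maxs - self.mins) + self.mins


def normalize(
    data: pd.DataFrame | np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, NormalizationStats]:
    """Min-max scale each parameter to [0, 1]; return data and stats.

    A DataFrame is restricted to the seven movement parameters when they
    are all present (metadata columns are ignored). A constant column is
    an error naming the parameter.
    """
    if isinstance(data, pd.DataFrame):
        if feature_names is None:
            if all(c in data.columns for c in FEATURE_NAMES):
                feature_names = FEATURE_NAMES
            else:
                feature_names = tuple(data.columns)
        X = data[list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty 2-D data matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite values")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    constant = maxs <= mins
    if np.any(constant):
        name = feature_names[int(np.argmax(constant))]
        raise ValueError(
            f"parameter {name!r} is constant and cannot be min-max scaled"
        )
    stats = NormalizationStats(tuple(feature_names), mins, maxs)
    return stats.transform(X), stats


@dataclass
class SOMModel:
    """Trained lattice of weight vectors with its training schedules."""

    rows: int
    cols: int
    weights: np.ndarray  # (rows*cols, P)
    alpha0: float
    alphaT: float
    sigma0: float
    sigmaT: float
    epochs: int
    seed: int
    normalization: NormalizationStats | None = None
    qe_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def n_params(self) -> int:
        return self.weights.shape[1]

    def lattice_coords(self) -> np.ndarray:
        """(row, col) position of each node, node index = row*cols + col."""
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c]).astype(float)


def _lattice_sqdist(rows: int, cols: int) -> np.ndarray:
    r, c = np.divmod(np.arange(rows * cols), cols)
    dr = r[:, None] - r[None, :]
    dc = c[:, None] - c[None, :]
    return (dr**2 + dc**2).astype(float)


def _present(
    weights: np.ndarray,
    x: np.ndarray,
    alpha: float,
    sigma: float,
    lat2: np.ndarray,
) -> int:
    """One sequential presentation: find the winner, update all weights
    in place with the Gaussian-neighborhood rule. Returns the winner."""
    d2 = ((weights - x) ** 2).sum(axis=1)
    winner = int(np.argmin(d2))
    h = np.exp(-lat2[winner] / (2.0 * sigma * sigma))
    weights += alpha * h[:, None] * (x - weights)
    return winner


def train_som(
    data: np.ndarray,
    rows: int = 8,
    cols: int = 8,
    epochs: int = 10,
    alpha0: float = 0.5,
    alphaT: float = 0.01,
    sigma0: float | None = None,
    sigmaT: float = 0.5,
    seed: int = 0,
    normalization: NormalizationStats | None = None,
) -> SOMModel:
    """Train a rows x cols SOM by sequential presentation.

    ``data`` must already be normalized. ``sigma0`` defaults to
    ``max(rows, cols) / 2``. Weights are initialized from ``rows*cols``
    distinct data rows drawn with the given seed.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty 2-D data matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite values")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n, n_nodes = len(X), rows * cols
    if n < n_nodes:
        raise ValueError(
            f"need at least rows*cols={n_nodes} data rows to initialize "
            f"the codebook, got {n}"
        )
    if sigma0 is None:
        sigma0 = max(rows, cols) / 2.0
    rng = np.random.default_rng(seed)
    weights = X[rng.choice(n, size=n_nodes, replace=False)].copy()
    lat2 = _lattice_sqdist(rows, cols)

    total = epochs * n
    qe_history = np.empty(epochs)
    s = 0
    for epoch in range(epochs):
        for i in rng.permutation(n):
            frac = s / (total - 1) if total > 1 else 1.0
            alpha = alpha0 + (alphaT - alpha0) * frac
            sigma = sigma0 + (sigmaT - sigma0) * frac
            _present(weights, X[i], alpha, sigma, lat2)
            s += 1
        # quantization error: mean distance of each vector to its BMU
        d = cdist(X, weights)
        qe_history[epoch] = float(d.min(axis=1).mean())

    return SOMModel(
        rows=rows,
        cols=cols,
        weights=weights,
        alpha0=alpha0,
        alphaT=alphaT,
        sigma0=float(sigma0),
        sigmaT=sigmaT,
        epochs=epochs,
        seed=seed,
        normalization=normalization,
        qe_history=qe_history,
    )


def train_on_features(
    matrix: pd.DataFrame,
    **kwargs,
) -> SOMModel:
    """Normalize a feature matrix and train a SOM on it."""
    Xn, stats = normalize(matrix)
    return train_som(Xn, normalization=stats, **kwargs)


def bmu(model: SOMModel, x: np.ndarray) -> int:
    """Best-matching unit of one normalized vector (lowest index on ties)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_params,):
        raise ValueError(
            f"vector has shape {x.shape}, model expects ({model.n_params},)"
        )
    d2 = ((model.weights - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def bmu_batch(model: SOMModel, X: np.ndarray) -> np.ndarray:
    """Best-matching units of many normalized vectors."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_params:
        raise ValueError(
            f"matrix has shape {X.shape}, model expects (*, {model.n_params})"
        )
    d2 = ((X[:, None, :] - model.weights[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def quantization_error(model: SOMModel, X: np.ndarray) -> float:
    """Mean Euclidean distance of each vector to its BMU."""
    d = cdist(np.asarray(X, float), model.weights)
    return float(d.min(axis=1).mean())


@dataclass
class ClusterModel:
    """Ward merge tree over the codebook, cut into k pattern clusters."""

    linkage: np.ndarray  # scipy linkage matrix over the codebook
    k: int
    node_to_cluster: np.ndarray  # cluster id (0-based) per lattice node
    cluster_names: dict[int, str] | None = None  # cluster id -> P1..P6

    def pattern_of_node(self, node: int) -> str:
        if self.cluster_names is None:
            raise ValueError("clusters are unnamed; run name_patterns first")
        return self.cluster_names[int(self.node_to_cluster[node])]


def ward_cluster(model: SOMModel, k: int = 6) -> ClusterModel:
    """Ward-linkage clustering of the codebook vectors, cut to k clusters."""
    if not 1 <= k <= model.n_nodes:
        raise ValueError(f"k={k} not in [1, {model.n_nodes}] codebook vectors")
    Z = linkage(model.weights, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    found = len(np.unique(labels))
    if found != k:
        raise ValueError(
            f"Ward cut produced {found} clusters instead of {k} "
            "(degenerate codebook)"
        )
    return ClusterModel(linkage=Z, k=k, node_to_cluster=labels)


def cluster_profiles(model: SOMModel, clusters: ClusterModel) -> pd.DataFrame:
    """Mean denormalized weight vector of each cluster (one row per cluster)."""
    W = model.weights
    if model.normalization is not None:
        W = model.normalization.inverse(W)
        names = model.normalization.feature_names
    else:
        names = tuple(f"x{i}" for i in range(model.n_params))
    rows = {}
    for cid in range(clusters.k):
        rows[cid] = W[clusters.node_to_cluster == cid].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(names))


def _argmax_unique(values: pd.Series, what: str) -> int:
    order = values.sort_values(ascending=False)
    if len(order) > 1 and np.isclose(order.iloc[0], order.iloc[1], rtol=1e-12):
        raise PatternNamingError(
            f"tie on {what} between clusters {order.index[0]} and "
            f"{order.index[1]}; assign pattern names manually"
        )
    return int(order.index[0])


def name_patterns(model: SOMModel, clusters: ClusterModel) -> ClusterModel:
    """Name the k=6 clusters P1..P6 from their movement-parameter profiles.

    P1 = highest mean speed (line), P6 = longest stop time (stay),
    P3 = highest acceleration among the rest (cross), remaining three by
    decreasing speed: P2 (loop), P4 (shaking), P5 (swirl). Profile ties
    raise :class:`PatternNamingError`.
    """
    if clusters.k != 6:
        raise ValueError(f"pattern naming requires k=6 clusters, got {clusters.k}")
    prof = cluster_profiles(model, clusters)
    for col in ("speed", "stop_time", "acceleration"):
        if col not in prof.columns:
            raise ValueError(
                "pattern naming needs movement-parameter profiles; "
                f"column {col!r} missing (was the model trained on the "
                "seven movement parameters with normalization stats?)"
            )
    names: dict[int, str] = {}
    remaining = prof
    p1 = _argmax_unique(remaining["speed"], "speed")
    names[p1] = "P1"
    remaining = remaining.drop(index=p1)
    p6 = _argmax_unique(remaining["stop_time"], "stop_time")
    names[p6] = "P6"
    remaining = remaining.drop(index=p6)
    p3 = _argmax_unique(remaining["acceleration"], "acceleration")
    names[p3] = "P3"
    remaining = remaining.drop(index=p3)
    speeds = remaining["speed"].sort_values(ascending=False)
    if np.isclose(speeds.iloc[0], speeds.iloc[1], rtol=1e-12) or np.isclose(
        speeds.iloc[1], speeds.iloc[2], rtol=1e-12
    ):
        raise PatternNamingError(
            "tie on speed among the remaining clusters; assign manually"
        )
    for cid, pat in zip(speeds.index, ("P2", "P4", "P5")):
        names[int(cid)] = pat
    return ClusterModel(
        linkage=clusters.linkage,
        k=clusters.k,
        node_to_cluster=clusters.node_to_cluster.copy(),
        cluster_names=names,
    )


def classify_segments(
    model: SOMModel,
    clusters: ClusterModel,
    matrix: pd.DataFrame,
) -> np.ndarray:
    """Pattern label (P1..P6) of every row of a feature matrix.

    Rows are scaled with the model's stored normalization statistics,
    mapped to their BMU, and labelled with the BMU's cluster pattern.
    """
    if model.normalization is None:
        raise ValueError("model has no normalization stats; cannot classify")
    if clusters.cluster_names is None:
        raise ValueError("clusters are unnamed; run name_patterns first")
    names = model.normalization.feature_names
    missing = [c for c in names if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing training parameters {missing}")
    Xn = model.normalization.transform(matrix[list(names)].to_numpy(float))
    nodes = bmu_batch(model, Xn)
    cids = clusters.node_to_cluster[nodes]
    return np.array([clusters.cluster_names[int(c)] for c in cids])


def component_planes(model: SOMModel) -> dict[str, np.ndarray]:
    """Denormalized rows x cols lattice of weights, one plane per parameter."""
    W = model.weights
    if model.normalization is not None:
        W = model.normalization.inverse(W)
        names = model.normalization.feature_names
    else:
        names = tuple(f"x{i}" for i in range(model.n_params))
    return {
        name: W[:, i].reshape(model.rows, model.cols).copy()
        for i, name in enumerate(names)
    }


def ward_newick(clusters: ClusterModel, leaf_names: list[str] | None = None) -> str:
    """Ward merge tree as a Newick string (dendrogram export).

    Branch lengths are differences of merge heights; leaves sit at
    height 0.
    """
    Z = clusters.linkage
    n = len(Z) + 1
    if leaf_names is None:
        leaf_names = [f"n{i}" for i in range(n)]
    heights = np.concatenate([np.zeros(n), Z[:, 2]])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{leaf_names[node]}:{length:.10g}"
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{length:.10g}"

    root = n + len(Z) - 1
    root_h = heights[root]
    left = render(int(Z[-1, 0]), root_h)
    right = render(int(Z[-1, 1]), root_h)
    return f"({left},{right});"


def save_model(
    model: SOMModel,
    path: str | Path,
    clusters: ClusterModel | None = None,
) -> None:
    """Serialize a model (and optional clustering) to a versioned JSON file."""
    payload: dict = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "rows": model.rows,
        "cols": model.cols,
        "weights": model.weights.tolist(),
        "alpha0": model.alpha0,
        "alphaT": model.alphaT,
        "sigma0": model.sigma0,
        "sigmaT": model.sigmaT,
        "epochs": model.epochs,
        "seed": model.seed,
        "qe_history": model.qe_history.tolist(),
    }
    if model.normalization is not None:
        payload["normalization"] = {
            "feature_names": list(model.normalization.feature_names),
            "mins": model.normalization.mins.tolist(),
            "maxs": model.normalization.maxs.tolist(),
        }
    if clusters is not None:
        payload["clusters"] = {
            "linkage": clusters.linkage.tolist(),
            "k": clusters.k,
            "node_to_cluster": clusters.node_to_cluster.tolist(),
            "cluster_names": (
                {str(k): v for k, v in clusters.cluster_names.items()}
                if clusters.cluster_names is not None
                else None
            ),
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[SOMModel, ClusterModel | None]:
    """Load a model (and clustering, if saved) from JSON."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(f"{path}: unsupported version {payload.get('version')}")
    stats = None
    if "normalization" in payload:
        ns = payload["normalization"]
        stats = NormalizationStats(
            tuple(ns["feature_names"]),
            np.array(ns["mins"], float),
            np.array(ns["maxs"], float),
        )
    model = SOMModel(
        rows=payload["rows"],
        cols=payload["cols"],
        weights=np.array(payload["weights"], float),
        alpha0=payload["alpha0"],
        alphaT=payload["alphaT"],
        sigma0=payload["sigma0"],
        sigmaT=payload["sigmaT"],
        epochs=payload["epochs"],
        seed=payload["seed"],
        normalization=stats,
        qe_history=np.array(payload["qe_history"], float),
    )
    clusters = None
    if "clusters" in payload:
        cl = payload["clusters"]
        clusters = ClusterModel(
            linkage=np.array(cl["linkage"], float),
            k=cl["k"],
            node_to_cluster=np.array(cl["node_to_cluster"], int),
            cluster_names=(
                {int(k): v for k, v in cl["cluster_names"].items()}
                if cl["cluster_names"] is not None
                else None
            ),
        )
    return model, clusters
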