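"""The 24 network parameters of a stem-loop structure graph.

Per-node, per-edge and per-pair quantities are summarized by their
population mean and population variance (``ddof=0``); graph-level
quantities enter the vector directly.  The canonical order of the 24
features is :data:`FEATURE_NAMES` and is part of the public contract
(TSV headers, model metadata).

Conventions, fixed for reproducibility:

* betweenness is unnormalized Freeman betweenness with fractional
  counting over tied shortest paths; endpoints are excluded for node
  betweenness and included for edge betweenness;
* closeness is ``(n-1) / sum_u d(v, u)``;
* the hub score is the Perron eigenvector of the adjacency matrix scaled
  so its maximum entry is 1 (power iteration on ``A + I``, which has a
  strictly dominant eigenvalue even for bipartite graphs, to relative
  tolerance 1e-10);
* cocitation/bibliographic coupling are means over all unordered distinct
  node pairs, zeros included (identical for undirected graphs; both are
  kept for fidelity to the original parameter list);
* the girth of an acyclic graph is reported as 0 — a finite sentinel
  outside the attainable cycle-length range;
* modularity is the Newman-Girvan Q of the partition found by greedy
  agglomerative (CNM) merging with a deterministic tie-break: on equal
  dQ the candidate pair with the lexicographically smallest community
  labels (communities labelled by their smallest member node) is merged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import StructureGraph, build_graph
from .records import HairpinError, RnaRecord

FEATURE_NAMES: tuple[str, ...] = (
    "degree_mean", "degree_var",
    "node_betweenness_mean", "node_betweenness_var",
    "edge_betweenness_mean", "edge_betweenness_var",
    "closeness_mean",
    "constraint_mean", "constraint_var",
    "hub_score_mean", "coreness_mean",
    "cocitation_mean", "bibcoupling_mean",
    "avg_path_length", "shortest_path_var", "diameter",
    "girth", "transitivity", "density", "modularity",
    "n_articulation_points",
    "motif4_path", "motif4_star", "motif4_cycle",
)

N_FEATURES = len(FEATURE_NAMES)


def _as_igraph(g: StructureGraph | ig.Graph) -> ig.Graph:
    return g.graph if isinstance(g, StructureGraph) else g


def _mean_var(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.var())


# ---------------------------------------------------------------------------
# individual parameters

def degree_stats(g) -> tuple[float, float]:
    """Mean and population variance of node degrees (mean == 2|E|/n)."""
    return _mean_var(_as_igraph(g).degree())


def betweenness(g) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized node and edge betweenness (fractional tied-path counting)."""
    ga = _as_igraph(g)
    return (np.asarray(ga.betweenness(), dtype=float),
            np.asarray(ga.edge_betweenness(), dtype=float))


def closeness(g) -> np.ndarray:
    """Closeness centrality ``(n-1) / sum of distances``; requires connectivity."""
    ga = _as_igraph(g)
    _require_connected(ga)
    return np.asarray(ga.closeness(normalized=True), dtype=float)


def burt_constraint(g) -> np.ndarray:
    """Burt's constraint per node, uniform tie weights ``p_ij = 1/deg(i)``."""
    return np.asarray(_as_igraph(g).constraint(), dtype=float)


def hub_score(g) -> np.ndarray:
    """Kleinberg hub score: Perron vector of A, max entry scaled to 1.

    For a connected undirected graph the Perron vector is unique and
    strictly positive, so the score is well defined even on bipartite
    graphs (where the generic HITS formulation via A^2 degenerates).
    Computed by dense symmetric eigendecomposition — exact to machine
    precision and deterministic.
    """
    ga = _as_igraph(g)
    _require_connected(ga)
    n = ga.vcount()
    if n == 1:
        return np.ones(1)
    a = np.array(ga.get_adjacency().data, dtype=float)
    _, vecs = np.linalg.eigh(a)
    v = vecs[:, -1]           # eigenvector of the largest eigenvalue
    v = np.abs(v)             # Perron vector has a constant sign
    return v / v.max()


def coreness(g) -> np.ndarray:
    """k-core number per node (iterated minimum-degree peeling)."""
    return np.asarray(_as_igraph(g).coreness(), dtype=float)


def cocitation_coupling(g) -> np.ndarray:
    """Common-neighbour count for each unordered distinct node pair."""
    ga = _as_igraph(g)
    m = np.asarray(ga.cocitation(), dtype=float)
    iu = np.triu_indices(ga.vcount(), k=1)
    return m[iu]


def bibliographic_coupling(g) -> np.ndarray:
    """Shared-reference count per pair; equals cocitation on undirected graphs."""
    ga = _as_igraph(g)
    m = np.asarray(ga.bibcoupling(), dtype=float)
    iu = np.triu_indices(ga.vcount(), k=1)
    return m[iu]


def path_metrics(g) -> tuple[float, float, float]:
    """(mean, population variance, max) of the shortest-path-length multiset."""
    ga = _as_igraph(g)
    _require_connected(ga)
    d = np.asarray(ga.distances(), dtype=float)
    iu = np.triu_indices(ga.vcount(), k=1)
    lengths = d[iu]
    if lengths.size == 0:
        return 0.0, 0.0, 0.0
    return float(lengths.mean()), float(lengths.var()), float(lengths.max())


def girth(g) -> float:
    """Length of the shortest cycle; 0 for acyclic graphs."""
    value = _as_igraph(g).girth()
    return float(value) if np.isfinite(value) else 0.0


def transitivity(g) -> float:
    """Global clustering coefficient 3*triangles/triples (0 if no triples)."""
    return float(_as_igraph(g).transitivity_undirected(mode="zero"))


def density(g) -> float:
    """2|E| / (n (n-1))."""
    ga = _as_igraph(g)
    if ga.vcount() < 2:
        raise HairpinError("density needs at least 2 nodes")
    return float(ga.density())


def articulation_points(g) -> int:
    """Number of cut vertices."""
    return len(_as_igraph(g).articulation_points())


# -- greedy (CNM) modularity -------------------------------------------------

def community_partition(g) -> tuple[list[frozenset[int]], float]:
    """Greedy agglomerative modularity maximization.

    Starts from singleton communities and repeatedly merges the connected
    community pair with the largest modularity gain (ties: smallest pair
    of community labels, a community being labelled by its minimum member
    node).  Returns the best partition encountered and its Newman-Girvan Q.
    """
    ga = _as_igraph(g)
    _require_connected(ga)
    n = ga.vcount()
    m = ga.ecount()
    if m == 0:
        return [frozenset(range(n))], 0.0

    deg = ga.degree()
    d = {v: float(deg[v]) for v in range(n)}          # community degree sums
    internal = {v: 0.0 for v in range(n)}             # internal edge counts
    members: dict[int, set[int]] = {v: {v} for v in range(n)}
    between: dict[tuple[int, int], float] = {}        # edges between communities
    for e in ga.es:
        a, b = sorted(e.tuple)
        if a != b:
            between[(a, b)] = between.get((a, b), 0.0) + 1.0

    two_m = 2.0 * m
    q = sum(internal[c] / m - (d[c] / two_m) ** 2 for c in d)
    best_q = q
    best_partition = [frozenset(s) for s in members.values()]

    while between:
        best_pair, best_gain = None, -np.inf
        for (a, b), e_ab in between.items():
            gain = e_ab / m - 2.0 * (d[a] / two_m) * (d[b] / two_m)
            if gain > best_gain or (gain == best_gain and (a, b) < best_pair):
                best_pair, best_gain = (a, b), gain
        a, b = best_pair
        # merge b into a (a < b so the merged label stays the minimum member)
        q += best_gain
        internal[a] += internal[b] + between.pop((a, b))
        d[a] += d[b]
        members[a] |= members.pop(b)
        del internal[b], d[b]
        for (x, y) in list(between):
            if b in (x, y):
                other = y if x == b else x
                e_cnt = between.pop((x, y))
                key = (min(a, other), max(a, other))
                between[key] = between.get(key, 0.0) + e_cnt
        if q > best_q + 1e-12:
            best_q = q
            best_partition = [frozenset(s) for s in members.values()]
    return best_partition, float(best_q)


def modularity(g) -> float:
    """Newman-Girvan Q of the greedily detected community partition."""
    return community_partition(g)[1]


# -- four-node motif census --------------------------------------------------

def _isoclass4(edges) -> int:
    return ig.Graph(4, list(edges)).isoclass()

_P4 = _isoclass4([(0, 1), (1, 2), (2, 3)])
_STAR = _isoclass4([(0, 1), (0, 2), (0, 3)])
_C4 = _isoclass4([(0, 1), (1, 2), (2, 3), (3, 0)])
_PAW = _isoclass4([(0, 1), (1, 2), (0, 2), (2, 3)])
_DIAMOND = _isoclass4([(0, 1), (1, 2), (0, 2), (2, 3), (1, 3)])
_K4 = _isoclass4(list(itertools.combinations(range(4), 2)))


def motif4_counts(g) -> dict[str, int]:
    """Counts of connected induced 4-node subgraphs by isomorphism class."""
    ga = _as_igraph(g)
    if ga.vcount() < 4:
        counts = [0] * 11
    else:
        counts = ga.motifs_randesu(size=4)
    def grab(idx):
        v = counts[idx]
        return 0 if (isinstance(v, float) and np.isnan(v)) else int(v)
    return {
        "path": grab(_P4), "star": grab(_STAR), "cycle": grab(_C4),
        "paw": grab(_PAW), "diamond": grab(_DIAMOND), "clique": grab(_K4),
    }


def motif4_census(g) -> tuple[int, int, int]:
    """(P4 paths, K1,3 stars, C4 cycles) among connected induced 4-subgraphs.

    These are the only three classes realizable in a triangle-free
    maximum-degree-3 graph, hence the only ones a valid structure graph
    can contain.
    """
    c = motif4_counts(g)
    return c["path"], c["star"], c["cycle"]


def _require_connected(ga: ig.Graph) -> None:
    if not ga.is_connected():
        raise HairpinError("graph is not connected — not a valid structure "
                           "graph")


# ---------------------------------------------------------------------------
# the full vector

def compute_features(g: StructureGraph | RnaRecord | str) -> pd.Series:
    """The canonical 24-feature vector of one structure graph.

    Accepts a :class:`StructureGraph`, an :class:`RnaRecord` or a bare
    dot-bracket string.  Deterministic: identical structures give
    bit-identical vectors.  Raises :class:`HairpinError` on graphs that
    cannot arise from a valid structure (disconnected, or containing
    triangle motifs).
    """
    if not isinstance(g, StructureGraph):
        g = build_graph(g)
    ga = g.graph
    if ga.vcount() < 5:
        raise HairpinError("structure too short for feature extraction")
    _require_connected(ga)

    deg_mean, deg_var = degree_stats(g)
    node_b, edge_b = betweenness(g)
    clo = closeness(g)
    con = burt_constraint(g)
    hub = hub_score(g)
    core = coreness(g)
    coc = cocitation_coupling(g)
    bib = bibliographic_coupling(g)
    apl, sp_var, diam = path_metrics(g)
    motifs = motif4_counts(g)
    if motifs["paw"] or motifs["diamond"] or motifs["clique"]:
        raise HairpinError("triangle-containing 4-node motifs found — not a "
                           "valid structure graph")

    values = {
        "degree_mean": deg_mean, "degree_var": deg_var,
        "node_betweenness_mean": float(node_b.mean()),
        "node_betweenness_var": float(node_b.var()),
        "edge_betweenness_mean": float(edge_b.mean()),
        "edge_betweenness_var": float(edge_b.var()),
        "closeness_mean": float(clo.mean()),
        "constraint_mean": float(con.mean()), "constraint_var": float(con.var()),
        "hub_score_mean": float(hub.mean()),
        "coreness_mean": float(core.mean()),
        "cocitation_mean": float(coc.mean()),
        "bibcoupling_mean": float(bib.mean()),
        "avg_path_length": apl, "shortest_path_var": sp_var, "diameter": diam,
        "girth": girth(g), "transitivity": transitivity(g),
        "density": density(g), "modularity": modularity(g),
        "n_articulation_points": float(articulation_points(g)),
        "motif4_path": float(motifs["path"]),
        "motif4_star": float(motifs["star"]),
        "motif4_cycle": float(motifs["cycle"]),
    }
    vec = pd.Series([values[k] for k in FEATURE_NAMES], index=FEATURE_NAMES,
                    dtype=float)
    if not np.isfinite(vec.to_numpy()).all():
        raise HairpinError("non-finite feature value computed")
    return vec


# ---------------------------------------------------------------------------
# containers and the sklearn-style transformer

@dataclass
class FeatureMatrix:
    """Ids, feature matrix and optional labels for a record set.

    Full matrices carry the canonical 24 columns in canonical order;
    feature-subset matrices (as produced during recursive elimination)
    are allowed, but a matrix presenting all 24 canonical names must
    present them in the canonical order.
    """

    ids: list[str]
    X: pd.DataFrame
    y: np.ndarray | None = None

    def __post_init__(self):
        cols = list(self.X.columns)
        if len(cols) != len(set(cols)) or not cols:
            raise HairpinError("feature columns must be unique and non-empty")
        if set(cols) == set(FEATURE_NAMES) and cols != list(FEATURE_NAMES):
            raise HairpinError("feature columns do not match the canonical "
                               "24-feature order")
        if self.X.isna().to_numpy().any():
            raise HairpinError("feature matrix contains missing values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=object)
            if len(self.y) != len(self.ids):
                raise HairpinError("label vector length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df.insert(0, "id", self.ids)
        df["label"] = self.y if self.y is not None else ""
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "id" not in df.columns:
            raise HairpinError("feature table missing the 'id' column")
        feature_cols = [c for c in df.columns if c not in ("id", "label")]
        y = None
        if "label" in df.columns:
            labels = df["label"].fillna("").astype(str)
            if (labels != "").any():
                y = labels.to_numpy(dtype=object)
        return cls(ids=[str(v) for v in df["id"]],
                   X=df[feature_cols].astype(float).reset_index(drop=True),
                   y=y)


def featurize_records(records: Sequence[RnaRecord]) -> FeatureMatrix:
    """Compute the feature matrix of a record list (labels carried over)."""
    rows = [compute_features(rec) for rec in records]
    X = pd.DataFrame(rows, columns=list(FEATURE_NAMES)).reset_index(drop=True)
    labels = [rec.label for rec in records]
    y = (np.asarray(labels, dtype=object)
         if any(l is not None for l in labels) else None)
    return FeatureMatrix(ids=[rec.id for rec in records], X=X, y=y)


class NetworkFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: RNA records in, 24-feature matrix out.

    Stateless — ``fit`` only records the output feature names, so the
    transformer composes with :class:`sklearn.pipeline.Pipeline`.
    """

    def fit(self, X: Iterable[RnaRecord], y=None) -> "NetworkFeaturizer":
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X: Iterable[RnaRecord]) -> pd.DataFrame:
        X = list(X)
        rows = [compute_features(rec) for rec in X]
        ids = [rec.id if isinstance(rec, RnaRecord) else str(i)
               for i, rec in enumerate(X)]
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES),
                            index=ids)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
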