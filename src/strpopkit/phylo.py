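"""Ordination and neighbor-joining trees for population frequency data.

PCA works on the populations × allele-frequency matrix (one column per
(locus, allele) pair in the union allele universe, absent alleles = 0),
classical (Torgerson) MDS embeds a distance matrix through double-centred
squared distances, and neighbor-joining agglomerates a distance matrix
with the Saitou–Nei Q-criterion.  All tie-breaks are lexicographic on
labels and eigenvector signs follow a fixed convention, so output is
byte-reproducible across platforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .str_data import DistanceMatrix, FrequencyTable, StrDataError


@dataclass
class OrdinationResult:
    """Low-dimensional coordinates plus percent of variance explained."""

    coordinates: pd.DataFrame  # populations × components
    explained_percent: np.ndarray

    @property
    def labels(self) -> list[str]:
        return list(self.coordinates.index)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude loading of each
    component is made positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def frequency_matrix(
    tables: Mapping[str, FrequencyTable], loci: Sequence[str] | None = None
) -> pd.DataFrame:
    """Populations × (locus, allele) frequency matrix over the union
    allele universe; absent alleles contribute 0."""
    pops = list(tables)
    panel = list(loci) if loci is not None else [
        l for l in tables[pops[0]].loci if all(l in tables[p].freqs for p in pops)
    ]
    if not panel:
        raise StrDataError("empty shared locus panel")
    columns = []
    for locus in panel:
        alleles = sorted({a for p in pops for a in tables[p].freqs[locus]})
        columns += [(locus, a) for a in alleles]
    data = np.zeros((len(pops), len(columns)))
    for i, p in enumerate(pops):
        for j, (locus, a) in enumerate(columns):
            data[i, j] = tables[p].freqs[locus].get(a, 0.0)
    return pd.DataFrame(data, index=pops, columns=[f"{l}:{a}" for l, a in columns])


def pca_frequencies(
    tables: Mapping[str, FrequencyTable],
    loci: Sequence[str] | None = None,
    k: int | None = None,
    scale: bool = False,
) -> OrdinationResult:
    """PCA of population allele-frequency profiles.

    Columns are centred (and optionally scaled to unit variance when
    ``scale`` is set); components come from the SVD of the centred matrix
    and are ordered by decreasing eigenvalue.
    """
    if len(tables) < 3:
        raise StrDataError("PCA needs at least 3 populations")
    X = frequency_matrix(tables, loci)
    M = X.to_numpy() - X.to_numpy().mean(axis=0, keepdims=True)
    if scale:
        sd = M.std(axis=0, ddof=1)
        M = M / np.where(sd > 0, sd, 1.0)
    n = M.shape[0]
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    # singular values that are numerical dust are exact zeros scientifically
    s = np.where(s > 1e-9 * max(s.max(initial=0.0), 1.0), s, 0.0)
    eig = s ** 2 / (n - 1)
    rank = min(n - 1, M.shape[1])
    if k is None:
        k = rank
    k = min(k, rank)
    scores = u[:, :k] * s[:k]
    # apply the sign convention through the loadings
    signs = np.ones(k)
    for j in range(k):
        col = vt[j]
        if col[np.argmax(np.abs(col))] < 0:
            signs[j] = -1.0
    scores = scores * signs
    total = eig[:rank].sum()
    explained = 100.0 * eig[:k] / total if total > 0 else np.zeros(k)
    coords = pd.DataFrame(scores, index=list(X.index), columns=[f"PC{i+1}" for i in range(k)])
    return OrdinationResult(coords, explained)


def classical_mds(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Torgerson metric MDS of a distance matrix.

    B = −½ J D² J is eigendecomposed; coordinates use the top-k
    non-negative eigenpairs and negative eigenvalues are truncated to
    zero (they measure departure from Euclidean realizability).
    """
    if k < 1:
        raise StrDataError("classical_mds: k must be >= 1")
    D = np.asarray(dm.values, dtype=float)
    if D.size and np.max(np.abs(D - D.T)) > 1e-9:
        raise StrDataError("classical_mds: matrix not symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.maximum(eigval, 0.0)
    # dust eigenvalues (e.g. collinear point sets) become exact zeros
    pos = np.where(pos > 1e-12 * max(pos.max(initial=0.0), 1.0), pos, 0.0)
    k_eff = min(k, n)
    vecs = _fix_signs(eigvec[:, :k_eff])
    coords = vecs * np.sqrt(pos[:k_eff])
    total = pos.sum()
    explained = 100.0 * pos[:k_eff] / total if total > 0 else np.zeros(k_eff)
    if k_eff < k:  # pad so callers always get k columns
        coords = np.hstack([coords, np.zeros((n, k - k_eff))])
        explained = np.concatenate([explained, np.zeros(k - k_eff)])
    df = pd.DataFrame(coords, index=dm.labels, columns=[f"C{i+1}" for i in range(k)])
    return OrdinationResult(df, explained)


# ---------------------------------------------------------------------------
# neighbor-joining

@dataclass
class UnrootedTree:
    """Unrooted tree with branch lengths; leaves carry population names.

    ``graph`` edges hold ``length`` (non-negative, after clamping) and
    ``raw_length`` (the unclamped neighbor-joining estimate).
    """

    graph: nx.Graph
    leaves: list[str] = field(default_factory=list)

    def path_length_matrix(self) -> DistanceMatrix:
        n = len(self.leaves)
        out = np.zeros((n, n))
        dist = dict(nx.all_pairs_dijkstra_path_length(self.graph, weight="length"))
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = dist[self.leaves[i]][self.leaves[j]]
        return DistanceMatrix(list(self.leaves), out)

    def leaves_form_subtree(self, subset: Sequence[str]) -> bool:
        """True when the minimal spanning subtree of ``subset`` contains no
        other leaf — the unrooted analogue of forming a clade."""
        subset = set(subset)
        nodes: set = set()
        base = next(iter(subset))
        for leaf in subset:
            nodes.update(nx.shortest_path(self.graph, base, leaf))
        return not (nodes & (set(self.leaves) - subset))

    def to_newick(self) -> str:
        """Serialize with branch lengths; an arbitrary internal node (or the
        first leaf for 2-taxon trees) becomes the printing root."""
        internal = [v for v in self.graph if v not in set(self.leaves)]
        root = internal[0] if internal else self.leaves[0]

        def rec(node, parent) -> str:
            children = [w for w in self.graph[node] if w != parent]
            name = node if node in set(self.leaves) else ""
            if not children:
                return str(name)
            inner = ",".join(
                rec(w, node) + f":{self.graph[node][w]['length']:.10g}" for w in children
            )
            return f"({inner}){name}"

        return rec(root, None) + ";"


def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou–Nei neighbor-joining with deterministic tie-breaking.

    At each step the pair minimizing Q_ij = (r−2)d_ij − R_i − R_j is
    joined; ties go to the lexicographically smallest label pair.  Limb
    lengths follow the standard formulas; negative estimates are clamped
    to 0 with the deficit moved to the sibling limb, and the raw values
    are kept on the edges as ``raw_length``.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise StrDataError("nj_tree needs at least 3 taxa")
    D: dict[str, dict[str, float]] = {
        a: {b: float(dm.values[i, j]) for j, b in enumerate(labels)}
        for i, a in enumerate(labels)
    }
    g = nx.Graph()
    active = sorted(labels)
    counter = itertools.count(1)

    def add_edge(u, v, raw):
        g.add_edge(u, v, length=max(raw, 0.0), raw_length=raw)

    while len(active) > 3:
        r = len(active)
        R = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for a, b in itertools.combinations(active, 2):  # active stays sorted
            q = (r - 2) * D[a][b] - R[a] - R[b]
            if q < best_q - 1e-15:
                best_q, best = q, (a, b)
        a, b = best
        new = f"_nj{next(counter)}"
        la = 0.5 * D[a][b] + (R[a] - R[b]) / (2.0 * (r - 2))
        lb = D[a][b] - la
        # clamp negatives, shifting the deficit to the sibling limb
        if la < 0:
            lb += la
            la_raw, la = la, 0.0
        else:
            la_raw = la
        if lb < 0:
            la += lb
            lb_raw, lb = lb, 0.0
            la = max(la, 0.0)
        else:
            lb_raw = lb
        g.add_edge(a, new, length=la, raw_length=la_raw)
        g.add_edge(b, new, length=lb, raw_length=lb_raw)
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[new][c] = D[c][new] = d
        active = sorted([c for c in active if c not in (a, b)] + [new])

    # final three-point join
    a, b, c = active
    center = f"_nj{next(counter)}"
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    for node, raw in ((a, la), (b, lb), (c, lc)):
        add_edge(node, center, raw)
    return UnrootedTree(g, leaves=list(labels))


def pipeline_phylo(
    tables: Mapping[str, FrequencyTable],
    loci: Sequence[str] | None = None,
    out_prefix: str | None = None,
    mds_k: int = 2,
) -> dict:
    """Distance matrices → NJ tree + MDS + PCA, optionally written to disk.

    Returns a dict with the D_A and FST matrices, the NJ tree (built on
    D_A), its Newick string, and the two ordinations.
    """
    from .compare import distance_matrices
    from .str_data import atomic_write_text, write_phylip_distances

    da, fst = distance_matrices(tables, loci)
    tree = nj_tree(da)
    mds = classical_mds(fst.clamped(), k=mds_k)
    pca = pca_frequencies(tables, loci)
    result = {"da": da, "fst": fst, "tree": tree, "newick": tree.to_newick(),
              "mds": mds, "pca": pca}
    if out_prefix is not None:
        da.to_dataframe().to_csv(f"{out_prefix}_da.csv")
        fst.to_dataframe().to_csv(f"{out_prefix}_fst.csv")
        write_phylip_distances(da, f"{out_prefix}_da.phy")
        atomic_write_text(f"{out_prefix}_nj.nwk", result["newick"] + "\n")
        ord_df = mds.coordinates.copy()
        ord_df.loc["explained_percent"] = np.resize(mds.explained_percent, mds_k)
        ord_df.to_csv(f"{out_prefix}_mds.csv")
        pca_df = pca.coordinates.copy()
        pca_df.loc["explained_percent"] = pca.explained_percent
        pca_df.to_csv(f"{out_prefix}_pca.csv")
    return result
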