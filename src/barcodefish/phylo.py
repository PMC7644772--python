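"""Distance-based placement: TN93 distances, neighbor-joining, bootstrap.

The Tamura-Nei (TN93) distance separates the two transition classes
(A<->G among purines, C<->T among pyrimidines) from transversions and
allows unequal base frequencies; base frequencies are estimated from
the pooled pair (the convention of the common desktop phylogenetics
packages).  An optional gamma shape parameter adds among-site rate
variation.  Trees are built by Saitou-Nei neighbor joining and node
support is assessed by nonparametric bootstrap over alignment columns.

For the question this pipeline answers - which candidate lineage
contains a partial query consensus - the placement is topological and
robust, so a distance framework substitutes for full maximum-likelihood
searching.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .core import LabelledSequence

__all__ = [
    "DistanceMatrix",
    "PhyloConfig",
    "tn93_distance",
    "compute_distance_matrix",
    "nj_tree",
    "bootstrap_tree",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string: A,C,G,T -> 0..3, anything else 255.

    Ambiguity codes and missing characters are treated as missing for
    distance estimation (pairwise deletion).
    """
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass
class DistanceMatrix:
    """A symmetric distance matrix; undefined entries are NaN."""

    labels: list[str]
    values: np.ndarray
    model: str = "p"
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if not np.allclose(
                self.values, self.values.T, equal_nan=True
            ):
                raise ValueError("matrix must be symmetric")
        defined = self.values[~np.isnan(self.values)]
        if defined.size and defined.min() < 0:
            raise ValueError("distances must be >= 0")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


@dataclass
class PhyloConfig:
    """Bootstrap and model settings for tree building."""

    bootstrap_replicates: int = 1000
    seed: int = 0
    model: str = "TN93"  # "p" | "TN93" | "TN93+G"
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")
        if self.model not in ("p", "TN93", "TN93+G"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "TN93+G" and not (
            self.gamma_shape and self.gamma_shape > 0
        ):
            raise ValueError("TN93+G requires a positive gamma_shape")


def _p_from_codes(x: np.ndarray, y: np.ndarray) -> float:
    valid = (x < 4) & (y < 4)
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    return float((x[valid] != y[valid]).sum() / n)


def _tn93_from_codes(
    x: np.ndarray, y: np.ndarray, gamma_shape: float | None = None
) -> float:
    """TN93 closed form from encoded sequences; NaN when undefined."""
    valid = (x < 4) & (y < 4)
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    a, b = x[valid], y[valid]

    # observed substitution proportions
    p1 = float((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum() / n)
    p2 = float((((a == 1) & (b == 3)) | ((a == 3) & (b == 1))).sum() / n)
    q = float((a != b).sum() / n) - p1 - p2

    # base frequencies from the pooled pair
    counts = np.bincount(np.concatenate([a, b]), minlength=4)
    fA, fC, fG, fT = counts / counts.sum()
    fR, fY = fA + fG, fC + fT
    if fR <= 0 or fY <= 0 or fA * fG <= 0 or fC * fT <= 0:
        # formula degenerates without both bases of a class present
        if p1 == p2 == q == 0.0:
            return 0.0
        return float("nan")

    k1 = 2.0 * fA * fG / fR
    k2 = 2.0 * fT * fC / fY
    k3 = 2.0 * (fR * fY - fA * fG * fY / fR - fT * fC * fR / fY)
    w1 = 1.0 - p1 / k1 - q / (2.0 * fR)
    w2 = 1.0 - p2 / k2 - q / (2.0 * fY)
    w3 = 1.0 - q / (2.0 * fR * fY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return float("nan")  # saturated: log/power argument non-positive
    if gamma_shape is None:
        d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    else:
        s = gamma_shape
        d = (
            k1 * s * (w1 ** (-1.0 / s) - 1.0)
            + k2 * s * (w2 ** (-1.0 / s) - 1.0)
            + k3 * s * (w3 ** (-1.0 / s) - 1.0)
        )
    return max(d, 0.0)


def tn93_distance(
    a: str, b: str, gamma_shape: float | None = None
) -> float:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Missing characters and ambiguity codes are pairwise-deleted.  With
    ``gamma_shape``, the gamma-rate-corrected variant.  Returns NaN
    (flagged undefined) when a logarithm/power argument is non-positive,
    i.e. the pair is saturated.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    x, y = encode(a), encode(b)
    if not ((x < 4) & (y < 4)).any():
        raise ValueError("no comparable columns")
    return _tn93_from_codes(x, y, gamma_shape)


def _pair_distance(
    x: np.ndarray, y: np.ndarray, model: str, gamma_shape: float | None
) -> float:
    if model == "p":
        return _p_from_codes(x, y)
    return _tn93_from_codes(
        x, y, gamma_shape if model == "TN93+G" else None
    )


def compute_distance_matrix(
    seqs: list[LabelledSequence],
    model: str = "TN93",
    gamma_shape: float | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix under the chosen model."""
    labels = [s.id for s in seqs]
    codes = [encode(s.residues) for s in seqs]
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _pair_distance(
                codes[i], codes[j], model, gamma_shape
            )
    return DistanceMatrix(
        labels=labels, values=values, model=model, gamma_shape=gamma_shape
    )


def _nj_merges(D: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Saitou-Nei agglomeration order on a working copy of ``D``.

    Returns merges as (i, j, branch_i, branch_j) over a growing node
    index space: original leaves are 0..n-1; the k-th merge creates node
    n+k.  Q-criterion ties break on the lowest (i, j) index pair.
    Negative branch lengths are clamped to zero.
    """
    n = D.shape[0]
    D = D.copy()
    active = list(range(n))
    merges: list[tuple[int, int, float, float]] = []
    next_id = n
    idx_of = {i: i for i in range(n)}  # node id -> row in working matrix

    while len(active) > 2:
        r = len(active)
        rows = [idx_of[a] for a in active]
        sub = D[np.ix_(rows, rows)]
        R = sub.sum(axis=1)
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                qv = (r - 2) * sub[ii, jj] - R[ii] - R[jj]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, ii, jj)
        _, ii, jj = best
        di, dj = active[ii], active[jj]
        dij = sub[ii, jj]
        li = dij / 2.0 + (R[ii] - R[jj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # distances from the new node to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for kk in range(r):
            if kk in (ii, jj):
                continue
            dk = 0.5 * (sub[ii, kk] + sub[jj, kk] - dij)
            new_row[idx_of[active[kk]]] = max(dk, 0.0)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :] = new_row
        D[:, -1] = new_row
        idx_of[next_id] = D.shape[0] - 1
        merges.append((di, dj, li, lj))
        active = [a for a in active if a not in (di, dj)] + [next_id]
        next_id += 1

    if len(active) == 2:
        a, b = active
        d = D[idx_of[a], idx_of[b]]
        merges.append((a, b, max(d, 0.0) / 2.0, max(d, 0.0) / 2.0))
    return merges


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; final join is a bifurcation whose
    midpoint is arbitrary, so treat the seed node as unrooted)."""
    if len(D.labels) < 2:
        raise ValueError("need at least 2 labels")
    bad = D.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")

    tns = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(D.labels):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes[i] = node

    merges = _nj_merges(D.values)
    next_id = len(D.labels)
    for i, j, li, lj in merges:
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[next_id] = parent
        next_id += 1
    tree.seed_node = nodes[next_id - 1]
    tree.is_rooted = False
    return tree


def _nj_bipartitions(D: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions (normalised leaf sets) of the NJ tree."""
    n = D.shape[0]
    leafsets: dict[int, frozenset] = {
        i: frozenset([labels[i]]) for i in range(n)
    }
    out: set[frozenset] = set()
    next_id = n
    for i, j, _, _ in _nj_merges(D):
        leafsets[next_id] = leafsets[i] | leafsets[j]
        next_id += 1
    all_labels = frozenset(labels)
    anchor = min(labels)
    for ls in leafsets.values():
        side = frozenset(all_labels - ls) if anchor in ls else ls
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _tree_bipartitions(
    tree: dendropy.Tree,
) -> dict[dendropy.Node, frozenset]:
    """Internal node -> normalised leaf set of the bipartition its edge
    induces (trivial bipartitions excluded)."""
    labels = sorted(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    all_labels = frozenset(labels)
    anchor = min(labels)
    n = len(labels)
    out: dict[dendropy.Node, frozenset] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        ls = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        side = frozenset(all_labels - ls) if anchor in ls else ls
        if 2 <= len(side) <= n - 2:
            out[node] = side
    return out


def bootstrap_tree(
    alignment: list[LabelledSequence], cfg: PhyloConfig
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the support of
    an internal edge is the percentage of replicate trees containing the
    same leaf bipartition, stored as an integer internal-node label (and
    as ``node.support``).  Replicates whose distance matrix has
    undefined entries are skipped and counted; a warning is issued if
    more than 10% are skipped.  Deterministic given ``cfg.seed``.
    """
    if cfg.bootstrap_replicates < 1:
        raise ValueError("bootstrap requires at least 1 replicate")
    # canonical label order makes the result independent of input order
    alignment = sorted(alignment, key=lambda s: s.id)
    labels = [s.id for s in alignment]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids in alignment")
    length = len(alignment[0].residues)
    if any(len(s.residues) != length for s in alignment):
        raise ValueError("sequences are not aligned (unequal lengths)")
    codes = np.stack([encode(s.residues) for s in alignment])
    gamma = cfg.gamma_shape if cfg.model == "TN93+G" else None

    def matrix(cols: np.ndarray) -> np.ndarray:
        sub = codes[:, cols]
        n = len(alignment)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = _pair_distance(
                    sub[i], sub[j], cfg.model, gamma
                )
        return values

    full = matrix(np.arange(length))
    D = DistanceMatrix(
        labels=labels, values=full, model=cfg.model, gamma_shape=gamma
    )
    tree = nj_tree(D)

    rng = np.random.default_rng(cfg.seed)
    counts: dict[frozenset, int] = {}
    skipped = 0
    used = 0
    for _ in range(cfg.bootstrap_replicates):
        cols = rng.integers(0, length, size=length)
        values = matrix(cols)
        if np.isnan(values).any():
            skipped += 1
            continue
        used += 1
        for bp in _nj_bipartitions(values, labels):
            counts[bp] = counts.get(bp, 0) + 1
    if skipped > 0.1 * cfg.bootstrap_replicates:
        warnings.warn(
            f"{skipped}/{cfg.bootstrap_replicates} bootstrap replicates "
            "skipped (undefined distances)",
            stacklevel=2,
        )
    for node, side in _tree_bipartitions(tree).items():
        pct = int(round(100.0 * counts.get(side, 0) / used)) if used else 0
        node.label = str(pct)
        node.support = pct
    tree.bootstrap_replicates_used = used
    tree.bootstrap_replicates_skipped = skipped
    return tree
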