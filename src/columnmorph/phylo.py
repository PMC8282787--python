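"""Phylogeny handling and multivariate Brownian-motion machinery.

A thin wrapper over dendropy trees caches the arrays the comparative
analyses need: taxon order, node depths, per-clade tip sets and the
Brownian-motion covariance C (C[i, j] = shared root-to-MRCA path length).
Rate matrices are estimated from phylogenetic independent contrasts;
simulation accumulates Gaussian increments root-to-tip; PGLS premultiplies
data and design by the inverse square root of C.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import TreeError

_EIG_FLOOR = 1e-12


class Phylogeny:
    """Rooted tree with strictly positive branch lengths (in Ma)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()

    def _index(self):
        tree = self._tree
        self.taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(self.taxa)) != len(self.taxa):
            raise TreeError("duplicate tip labels")
        tip_index = {t: i for i, t in enumerate(self.taxa)}
        self._tip_index = tip_index
        # depths (distance from root) and per-node tip sets, postorder
        self._depth = {}
        self._tips_below = {}
        for node in tree.preorder_node_iter():
            el = node.edge.length
            if node.parent_node is None:
                self._depth[node] = float(el or 0.0)
            else:
                if el is None or el <= 0:
                    raise TreeError(
                        f"non-positive branch length on edge above "
                        f"{node.taxon.label if node.taxon else 'an internal node'}"
                    )
                self._depth[node] = self._depth[node.parent_node] + float(el)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._tips_below[node] = np.array([tip_index[node.taxon.label]])
            else:
                self._tips_below[node] = np.concatenate(
                    [self._tips_below[c] for c in node.child_nodes()]
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        return max(self._depth[leaf] for leaf in self._tree.leaf_node_iter())

    def tip_depths(self) -> np.ndarray:
        out = np.empty(self.n_tips)
        for leaf in self._tree.leaf_node_iter():
            out[self._tip_index[leaf.taxon.label]] = self._depth[leaf]
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= rel_tol * d.max())

    def internal_nodes(self):
        """(forward node time, forward stem time, tip indices) per internal node.

        Times are measured from the root (root node time 0); the root's stem
        time equals its node time.
        """
        root = self._tree.seed_node
        root_depth = self._depth[root]
        out = []
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                continue
            t = self._depth[node] - root_depth
            stem = (
                t if node.parent_node is None
                else self._depth[node.parent_node] - root_depth
            )
            out.append((t, stem, self._tips_below[node]))
        return out

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise TreeError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    def prune_to(self, species) -> tuple["Phylogeny", dict]:
        """Prune to the intersection of tree tips and ``species``.

        Returns the pruned tree and a report listing tips dropped from the
        tree and species absent from it.  An empty intersection is an error.
        """
        species = list(species)
        keep = [s for s in species if s in self._tip_index]
        missing_from_tree = [s for s in species if s not in self._tip_index]
        dropped_tips = [t for t in self.taxa if t not in set(keep)]
        if not keep:
            raise TreeError("no requested species are present in the tree")
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in set(keep)]
        tree.retain_taxa(taxa)
        report = {
            "kept": keep,
            "dropped_tips": dropped_tips,
            "missing_from_tree": missing_from_tree,
        }
        if missing_from_tree:
            warnings.warn(
                f"{len(missing_from_tree)} species absent from the tree: "
                + ", ".join(missing_from_tree[:10]),
                stacklevel=2,
            )
        return Phylogeny(tree), report

    # -- covariance --------------------------------------------------------
    def covariance(self, order: list[str] | None = None) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path lengths."""
        order = list(order) if order is not None else self.taxa
        for s in order:
            if s not in self._tip_index:
                raise TreeError(f"species {s!r} is not a tip of the tree")
        n_all = self.n_tips
        C = np.zeros((n_all, n_all))
        root = self._tree.seed_node
        root_depth = self._depth[root]
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                i = self._tip_index[node.taxon.label]
                C[i, i] = self._depth[node] - root_depth
                continue
            depth = self._depth[node] - root_depth
            children = node.child_nodes()
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = self._tips_below[children[a]]
                    ib = self._tips_below[children[b]]
                    C[np.ix_(ia, ib)] = depth
                    C[np.ix_(ib, ia)] = depth
        sel = [self._tip_index[s] for s in order]
        return C[np.ix_(sel, sel)]

    # -- contrasts ---------------------------------------------------------
    def independent_contrasts(self, tip_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Branch-length-standardised contrasts and the root (GLS) estimate.

        ``tip_data`` is (n_tips, D) in ``self.taxa`` order.  Polytomies must
        be resolved first; zero-length internal branches make the
        standardisation singular and raise.
        """
        X = np.atleast_2d(np.asarray(tip_data, float))
        if X.shape[0] != self.n_tips:
            raise TreeError(
                f"tip data has {X.shape[0]} rows for {self.n_tips} tips"
            )
        vals: dict = {}
        lens: dict = {}
        contrasts = []
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                vals[node] = X[self._tip_index[node.taxon.label]]
                lens[node] = float(node.edge.length or 0.0)
                continue
            children = node.child_nodes()
            if len(children) != 2:
                raise TreeError(
                    "contrasts require a binary tree; resolve polytomies first"
                )
            c1, c2 = children
            v1, v2 = lens[c1], lens[c2]
            denom = v1 + v2
            if denom <= 0:
                raise TreeError(
                    "zero-length sister branches: contrast standardisation fails"
                )
            contrasts.append((vals[c1] - vals[c2]) / np.sqrt(denom))
            vals[node] = (vals[c1] * v2 + vals[c2] * v1) / denom
            lens[node] = float(node.edge.length or 0.0) + v1 * v2 / denom
        root = self._tree.seed_node
        return np.array(contrasts), vals[root]


def read_newick(path: str) -> Phylogeny:
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def phylo_covariance(tree: Phylogeny, order: list[str] | None = None) -> np.ndarray:
    return tree.covariance(order)


@dataclass
class BMModel:
    """Multivariate Brownian motion: per-unit-time trait covariance + root state."""

    rate_matrix: np.ndarray  # (D, D) symmetric PSD
    root_state: np.ndarray  # (D,)

    def validate(self) -> None:
        R = self.rate_matrix
        if not np.allclose(R, R.T, atol=1e-10):
            raise TreeError("rate matrix is not symmetric")
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise TreeError("rate matrix is not positive semidefinite")


def estimate_bm_rates(
    tip_data: np.ndarray,
    tree: Phylogeny,
    diagonal: bool = False,
) -> BMModel:
    """Rate matrix from independent contrasts; root by GLS ancestral estimate.

    The rate matrix is the mean outer product of the standardised contrasts
    (full by default; ``diagonal=True`` keeps only per-trait rates).
    Constant tip data yields a zero rate matrix.
    """
    X = np.atleast_2d(np.asarray(tip_data, float))
    if X.ndim == 2 and X.shape[0] != tree.n_tips and X.shape[1] == tree.n_tips:
        X = X.T
    contrasts, root = tree.independent_contrasts(X)
    R = contrasts.T @ contrasts / contrasts.shape[0]
    if diagonal:
        R = np.diag(np.diag(R))
    model = BMModel(rate_matrix=np.atleast_2d(R), root_state=np.atleast_1d(root))
    model.validate()
    return model


def simulate_bm(
    tree: Phylogeny,
    model: BMModel,
    n_sim: int,
    seed=None,
) -> np.ndarray:
    """Simulate tip states under multivariate BM: (n_sim, n_tips, D).

    Gaussian increments with covariance ``rate * branch_length`` accumulate
    from the root; reproducible given ``seed`` (int or Generator).
    """
    model.validate()
    rng = np.random.default_rng(seed)
    R = np.atleast_2d(model.rate_matrix)
    D = R.shape[0]
    w, V = np.linalg.eigh(R)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    out = np.empty((n_sim, tree.n_tips, D))
    states = {tree._tree.seed_node: np.broadcast_to(
        np.asarray(model.root_state, float), (n_sim, D)
    )}
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is not None:
            b = float(node.edge.length)
            z = rng.standard_normal((n_sim, D))
            states[node] = states[node.parent_node] + np.sqrt(b) * (z @ L.T)
        if node.is_leaf():
            out[:, tree._tip_index[node.taxon.label], :] = states[node]
        # free parent states we no longer need is unnecessary at these sizes
    return out


def inverse_sqrt_covariance(C: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """C^(-1/2) via eigendecomposition with an eigenvalue floor."""
    C = np.asarray(C, float)
    w, V = np.linalg.eigh(C)
    if w.max() <= 0:
        raise TreeError("covariance matrix is not positive definite")
    w = np.clip(w, floor * w.max(), None)
    return (V / np.sqrt(w)) @ V.T


def pgls_transform(
    tip_data: np.ndarray,
    tree: Phylogeny,
    species: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Premultiply tip data by C^(-1/2); returns (transformed, transform)."""
    Y = np.atleast_2d(np.asarray(tip_data, float))
    order = species if species is not None else tree.taxa
    if Y.shape[0] != len(order):
        raise TreeError("data rows and species order differ in length")
    T = inverse_sqrt_covariance(tree.covariance(order))
    return T @ Y, T


def gls_fit(Y: np.ndarray, X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """GLS coefficients of Y on X under covariance C (rows = observations)."""
    T = inverse_sqrt_covariance(C)
    beta, *_ = np.linalg.lstsq(T @ X, T @ Y, rcond=None)
    return beta


def allometry_residuals(
    shapes: np.ndarray,
    sizes: np.ndarray,
    tree: Phylogeny,
    species: list[str] | None = None,
    log_size: bool = True,
) -> np.ndarray:
    """Residuals of the phylogenetic regression of shape on (log) size.

    ``shapes`` is (n_species, p) flattened aligned coordinates or PC scores;
    ``sizes`` the per-species centroid sizes.  Residuals are returned in the
    original (untransformed) space and are GLS-orthogonal to size.  With
    (near-)zero size variance the regression is skipped with a warning and
    GLS-centred shapes are returned.
    """
    Y = np.atleast_2d(np.asarray(shapes, float))
    x = np.asarray(sizes, float)
    if log_size:
        if np.any(x <= 0):
            raise TreeError("sizes must be positive for log transformation")
        x = np.log(x)
    order = species if species is not None else tree.taxa
    C = tree.covariance(order)
    ones = np.ones((Y.shape[0], 1))
    if np.std(x) < 1e-12:
        warnings.warn(
            "size has (near-)zero variance: allometry correction skipped, "
            "returning GLS-centred shapes",
            stacklevel=2,
        )
        mu = gls_fit(Y, ones, C)
        return Y - ones @ mu
    X = np.column_stack([np.ones_like(x), x])
    beta = gls_fit(Y, X, C)
    return Y - X @ beta
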