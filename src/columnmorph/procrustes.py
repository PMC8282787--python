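"""Generalized Procrustes alignment with object symmetry, and tangent-space PCA.

All analyses downstream operate on the *symmetric* shape component: each
configuration is superimposed jointly with its relabelled mirror image and
the per-specimen average of the two aligned copies is retained.  This removes
digitisation asymmetry from bilaterally symmetric structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .column_data import LandmarkPairing, VertebraRecord
from .errors import ConfigurationError, DegenerateShapeError, DimensionError

_LABEL_COLS = ["specimen_id", "species", "region", "position"]


@dataclass
class AlignedShapes:
    """Superimposed landmark configurations plus centroid sizes and consensus.

    ``coords`` has shape (N, K, 3); ``centroid_size`` holds the pre-scaling
    centroid sizes; ``labels`` is a DataFrame with one row per configuration
    (specimen_id, species, region, position).
    """

    coords: np.ndarray
    centroid_size: np.ndarray
    consensus: np.ndarray
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """(N, 3K) view of the aligned coordinates."""
        return self.coords.reshape(self.n, -1)

    @property
    def group_labels(self) -> list[tuple]:
        return list(
            zip(self.labels["species"], self.labels["region"], self.labels["position"])
        )

    def row_index(self) -> dict[tuple, int]:
        """Map (species, region, position) -> row; requires unique triples."""
        idx: dict[tuple, int] = {}
        for i, key in enumerate(self.group_labels):
            if key in idx:
                raise ConfigurationError(
                    f"duplicate (species, region, position) {key}; average by "
                    "species before group-level analyses"
                )
            idx[key] = i
        return idx

    def select(self, rows) -> "AlignedShapes":
        rows = np.asarray(rows)
        return AlignedShapes(
            self.coords[rows],
            self.centroid_size[rows],
            self.consensus,
            self.labels.iloc[rows].reset_index(drop=True),
            dict(self.meta),
        )


def _default_labels(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": [f"s{i}" for i in range(n)],
            "species": [f"s{i}" for i in range(n)],
            "region": ["?"] * n,
            "position": [0] * n,
        }
    )


def labels_from_records(records: list[VertebraRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "species": [r.species for r in records],
            "region": [r.region for r in records],
            "position": [r.position for r in records],
        }
    )


def _as_stack(configs) -> np.ndarray:
    if isinstance(configs, np.ndarray) and configs.ndim == 3:
        X = np.array(configs, dtype=float)
    else:
        first = configs[0]
        k = first.coords.shape[0] if isinstance(first, VertebraRecord) else np.shape(first)[0]
        arrs = []
        for c in configs:
            a = c.coords if isinstance(c, VertebraRecord) else np.asarray(c, float)
            if a.shape != (k, 3):
                raise DimensionError(
                    f"all configurations must share shape ({k}, 3); got {a.shape}"
                )
            arrs.append(a)
        X = np.array(arrs, dtype=float)
    if X.shape[0] < 2:
        raise DimensionError("GPA needs at least 2 configurations")
    if not np.all(np.isfinite(X)):
        raise DimensionError("non-finite coordinates in input configurations")
    return X


def optimal_rotation(A: np.ndarray, B: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimising ||A @ R - B|| (proper unless reflection allowed)."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def centroid_sizes(X: np.ndarray) -> np.ndarray:
    """Centroid size of each configuration in an (N, K, 3) stack."""
    centred = X - X.mean(axis=1, keepdims=True)
    return np.sqrt((centred**2).sum(axis=(1, 2)))


def gpa(
    configs,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
    labels: pd.DataFrame | None = None,
    return_history: bool = False,
):
    """Generalized Procrustes superimposition.

    Each configuration is translated to the origin, scaled to unit centroid
    size (if ``scale``), and iteratively rotated onto the running consensus
    by SVD-based orthogonal fits until the consensus changes by less than
    ``tol``.  Rotations are proper (determinant +1) unless
    ``allow_reflection`` is set.  With ``scale=False`` the superimposition is
    partial-Procrustes (sizes retained).
    """
    X = _as_stack(configs)
    n, k, _ = X.shape
    X = X - X.mean(axis=1, keepdims=True)
    cs = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(cs < 1e-12):
        bad = int(np.argmin(cs))
        raise DegenerateShapeError(
            f"configuration {bad} has (near-)zero centroid size"
        )
    if scale:
        X = X / cs[:, None, None]
    ref = X[0] / (np.linalg.norm(X[0]) if scale else 1.0)
    history = []
    for _ in range(max_iter):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(X[i], ref, allow_reflection)
        new_ref = X.mean(axis=0)
        if scale:
            new_ref = new_ref / np.linalg.norm(new_ref)
        history.append(float(((X - new_ref) ** 2).sum()))
        delta = float(np.linalg.norm(new_ref - ref))
        ref = new_ref
        if delta < tol:
            break
    for i in range(n):  # final pass against the converged consensus
        X[i] = X[i] @ optimal_rotation(X[i], ref, allow_reflection)
    consensus = X.mean(axis=0)
    if labels is None:
        labels = _default_labels(n)
    aligned = AlignedShapes(
        X, cs, consensus, labels.reset_index(drop=True),
        meta={"scale": scale, "tol": tol, "iterations": len(history)},
    )
    return (aligned, history) if return_history else aligned


def mirror_relabel(
    X: np.ndarray, pairing: LandmarkPairing, axis: int = 0
) -> np.ndarray:
    """Mirror configurations across one coordinate axis and swap paired landmarks."""
    k = X.shape[-2]
    if max([i for p in pairing.paired for i in p] + pairing.midline, default=-1) >= k:
        raise ConfigurationError("pairing index out of range for K landmarks")
    perm = pairing.swap_permutation(k)
    M = np.array(X, dtype=float)
    M[..., axis] = -M[..., axis]
    return M[..., perm, :]


def symmetric_component(
    configs,
    pairing: LandmarkPairing,
    mirror_axis: int = 0,
    labels: pd.DataFrame | None = None,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Object-symmetry GPA: return the symmetric shape component.

    Each configuration's mirror image (one axis negated, paired landmarks
    relabelled) joins the originals in a single GPA; the symmetric component
    of a specimen is the mean of its aligned original and aligned mirror.
    The mirror copies realign onto the originals through proper rotations,
    so the choice of mirroring axis is immaterial.
    """
    X = _as_stack(configs)
    n = X.shape[0]
    M = mirror_relabel(X, pairing, mirror_axis)
    joint = np.concatenate([X, M], axis=0)
    aligned = gpa(joint, scale=scale, tol=tol, max_iter=max_iter)
    sym = 0.5 * (aligned.coords[:n] + aligned.coords[n:])
    sym = sym - sym.mean(axis=1, keepdims=True)
    if scale:
        # averaging original and mirror shrinks centroid size slightly;
        # restore unit size so the operation is idempotent
        sym = sym / np.sqrt((sym**2).sum(axis=(1, 2)))[:, None, None]
    if labels is None:
        labels = _default_labels(n)
    return AlignedShapes(
        sym,
        aligned.centroid_size[:n],
        sym.mean(axis=0),
        labels.reset_index(drop=True),
        meta={**aligned.meta, "symmetric": True, "mirror_axis": mirror_axis},
    )


def asymmetric_component(configs, pairing: LandmarkPairing, **kwargs) -> np.ndarray:
    """Aligned original minus symmetric component (retained but unused downstream)."""
    X = _as_stack(configs)
    n = X.shape[0]
    M = mirror_relabel(X, pairing, kwargs.pop("mirror_axis", 0))
    aligned = gpa(np.concatenate([X, M], axis=0), **kwargs)
    return 0.5 * (aligned.coords[:n] - aligned.coords[n:])


def average_by_species(aligned: AlignedShapes) -> AlignedShapes:
    """Average aligned configurations (and centroid sizes) within each
    (species, region, position); one configuration per triple remains."""
    keys = aligned.group_labels
    order: list[tuple] = []
    members: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(i)
    coords = np.stack([aligned.coords[members[k]].mean(axis=0) for k in order])
    cs = np.array([aligned.centroid_size[members[k]].mean() for k in order])
    labels = pd.DataFrame(
        {
            "specimen_id": ["+".join(
                sorted(aligned.labels["specimen_id"].iloc[members[k]].astype(str))
            ) for k in order],
            "species": [k[0] for k in order],
            "region": [k[1] for k in order],
            "position": [k[2] for k in order],
        }
    )
    return AlignedShapes(
        coords, cs, coords.mean(axis=0), labels,
        meta={**aligned.meta, "species_averaged": True},
    )


@dataclass
class PCAResult:
    """Tangent-space principal components of aligned shapes."""

    scores: np.ndarray  # (N, D)
    loadings: np.ndarray  # (D, 3K), orthonormal rows
    variance_explained: np.ndarray  # (D,)
    mean_shape: np.ndarray  # (K, 3)

    @property
    def d(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Back-project scores to landmark configurations (..., K, 3)."""
        flat = np.atleast_2d(scores) @ self.loadings + self.mean_shape.reshape(1, -1)
        return flat.reshape(-1, *self.mean_shape.shape)

    def shape_along_pc(self, pc: int, c: float) -> np.ndarray:
        """Model shape at ``mean + c * loading_pc`` (Fig.-style PC extremes)."""
        s = np.zeros(self.d)
        s[pc] = c
        return self.reconstruct(s)[0]


def tangent_pca(aligned: AlignedShapes, n_components: int | None = None) -> PCAResult:
    """PCA of the flattened aligned coordinates (covariance eigendecomposition
    via SVD of the centred data matrix)."""
    if aligned.n < 3:
        raise DimensionError("tangent PCA needs at least 3 configurations")
    Xf = aligned.flat
    mean = Xf.mean(axis=0)
    centred = Xf - mean
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    total = float((s**2).sum())
    if total <= 0:
        raise DegenerateShapeError("no shape variation: PCA undefined")
    keep = s > max(1e-12, 1e-10 * s[0])
    if n_components is not None:
        keep[n_components:] = False
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    return PCAResult(
        scores=U * s,
        loadings=Vt,
        variance_explained=s**2 / total,
        mean_shape=mean.reshape(aligned.k, 3),
    )
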