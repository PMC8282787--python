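"""Per-group morphological disparity (Procrustes variance) along the column.

Disparity of a group is the mean squared Procrustes (aligned-coordinate
Euclidean) distance of its members from the group mean shape, divisor ``n``
(the convention of the standard morphological-disparity implementations; an
unbiased ``n - 1`` divisor is available via ``ddof=1``).  Because each region
carries a different number of digitised landmarks, profiles standardise the
variance by the region's landmark count K so regions are comparable.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .column_data import SeriationScheme
from .errors import ConfigurationError, DimensionError
from .procrustes import AlignedShapes


def procrustes_variance(data, ddof: int = 0) -> float:
    """Mean squared distance from the group mean.

    ``data`` is an (n, p) matrix of flattened aligned coordinates (or PC
    scores: distances are identical).  A single shape has variance 0.
    """
    X = np.asarray(data, float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DimensionError("expected a non-empty (n, p) matrix")
    n = X.shape[0]
    if n == 1:
        return 0.0
    dev = X - X.mean(axis=0)
    return float((dev**2).sum() / (n - ddof))


def group_variance(aligned: AlignedShapes, members, ddof: int = 0) -> tuple[float, int, list]:
    """Variance over the members present in ``aligned``; reports missing ones."""
    idx = aligned.row_index()
    rows, missing = [], []
    for key in members:
        if key in idx:
            rows.append(idx[key])
        else:
            missing.append(key)
    if not rows:
        raise ConfigurationError("group has no members present in the aligned data")
    return procrustes_variance(aligned.flat[rows], ddof=ddof), len(rows), missing


def disparity_profile(
    aligned_by_region: Mapping[str, AlignedShapes] | AlignedShapes,
    scheme: SeriationScheme,
    k_by_region: Mapping[str, int] | None = None,
    ddof: int = 0,
    standardize_by: str = "landmarks",
) -> pd.DataFrame:
    """Disparity table: one row per seriation group, in column order.

    ``standardize_by`` divides the raw Procrustes variance by the region's
    landmark count K (default, matching the reported convention) or by the
    coordinate count 3K (``"coordinates"``).  Groups whose members are
    absent from the aligned data are reported with ``n_missing`` rather than
    silently dropped.
    """
    if isinstance(aligned_by_region, AlignedShapes):
        src = aligned_by_region
        aligned_by_region = {
            region: src.select(np.flatnonzero((src.labels["region"] == region).to_numpy()))
            for region in src.labels["region"].unique()
        }
    rows = []
    for key in scheme.order:
        region = scheme.region_of(key)
        if region not in aligned_by_region:
            raise ConfigurationError(f"no aligned data for region {region!r}")
        aligned = aligned_by_region[region]
        k = (k_by_region or {}).get(region, aligned.k)
        var, n, missing = group_variance(aligned, scheme.groups[key], ddof=ddof)
        divisor = k if standardize_by == "landmarks" else 3 * k
        rows.append(
            {
                "scheme": scheme.name,
                "group": scheme.group_label(key),
                "region": region,
                "n_species": n,
                "n_missing": len(missing),
                "n_landmarks": k,
                "procrustes_variance": var,
                "standardized_disparity": var / divisor,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["ddof"] = ddof
    df.attrs["standardize_by"] = standardize_by
    return df
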