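"""Locomotor-capability coding and (phylogenetic) Procrustes ANOVA with RRPP.

Species are coded for five binary locomotor capabilities (terrestrial,
cursorial, arboreal, aquatic, fossorial) derived from traditional
single-category classifications.  Shape ~ capability associations are
tested with Procrustes ANOVA: sequential (hierarchical) sums of squares on
squared distances among fitted values, significance by residual
randomization in a permutation procedure (RRPP: residuals of the reduced
model are permuted), effect sizes as Z-scores of log F against the
permutation distribution.  A phylogenetic variant premultiplies data and
design by the inverse square root of the Brownian-motion covariance.
Exhaustive subset search over the capabilities picks the admissible model
(all terms p < 0.1) with the highest R^2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, VocabularyError
from .phylo import Phylogeny, inverse_sqrt_covariance

#: canonical capability order; also the sequential term order in designs
CAPABILITIES = ("terrestrial", "cursorial", "arboreal", "aquatic", "fossorial")

#: traditional single-category vocabulary accepted by the encoder
CATEGORY_VOCABULARY = (
    "terrestrial", "cursorial", "scansorial", "arboreal",
    "semi-aquatic", "aquatic", "semi-fossorial", "fossorial",
)

_TERRESTRIAL_CATEGORIES = {
    "terrestrial", "cursorial", "scansorial", "semi-aquatic", "semi-fossorial",
}
_ARBOREAL_CATEGORIES = {"arboreal", "scansorial"}
_AQUATIC_CATEGORIES = {"aquatic", "semi-aquatic"}
_FOSSORIAL_CATEGORIES = {"fossorial", "semi-fossorial"}


def encode_capabilities(
    traditional_category: str, cursorial: bool | None = None
) -> dict[str, int]:
    """Map a traditional locomotor category to the five binary capabilities.

    Terrestrial capability covers every category of species that habitually
    walk on the ground (terrestrial, cursorial, scansorial, semi-aquatic,
    semi-fossorial); arboreal covers arboreal and scansorial; aquatic covers
    aquatic and semi-aquatic (fully aquatic species lack the terrestrial
    capability); fossorial covers fossorial and semi-fossorial.  Cursoriality
    is a behavioural criterion (forelimb used primarily for terrestrial
    locomotion): the ``cursorial`` override marks cursors whose traditional
    category is not "cursorial"; species categorised "cursorial" are cursors
    unless explicitly overridden.
    """
    cat = traditional_category.strip().lower()
    if cat not in CATEGORY_VOCABULARY:
        raise VocabularyError(
            f"unknown locomotor category {traditional_category!r}; expected one "
            f"of {CATEGORY_VOCABULARY}"
        )
    if cursorial is None:
        cursorial = cat == "cursorial"
    vec = {
        "terrestrial": int(cat in _TERRESTRIAL_CATEGORIES),
        "cursorial": int(bool(cursorial)),
        "arboreal": int(cat in _ARBOREAL_CATEGORIES),
        "aquatic": int(cat in _AQUATIC_CATEGORIES),
        "fossorial": int(cat in _FOSSORIAL_CATEGORIES),
    }
    return vec


def build_capability_matrix(
    categories: Mapping[str, str],
    cursorial_overrides: Sequence[str] = (),
) -> pd.DataFrame:
    """Species x capability binary matrix from traditional categories.

    ``cursorial_overrides`` lists species scored cursorial on behavioural
    grounds despite a non-cursorial traditional category (configuration
    data, not code).
    """
    overrides = set(cursorial_overrides)
    rows = {
        sp: encode_capabilities(cat, cursorial=True if sp in overrides else None)
        for sp, cat in categories.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CAPABILITIES))
    df.index.name = "species"
    validate_capability_matrix(df)
    return df


def validate_capability_matrix(df: pd.DataFrame) -> None:
    if not set(CAPABILITIES) <= set(df.columns):
        raise ConfigurationError(f"capability matrix must have columns {CAPABILITIES}")
    vals = df[list(CAPABILITIES)].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ConfigurationError("capability values must be binary 0/1")
    if (vals.sum(axis=1) == 0).any():
        bad = df.index[vals.sum(axis=1) == 0].tolist()
        raise ConfigurationError(f"species with no capability: {bad}")
    viol = df[(df["cursorial"] == 1) & (df["terrestrial"] == 0)]
    if len(viol):
        raise ConfigurationError(
            f"cursorial species must be terrestrial: {viol.index.tolist()}"
        )


# ---------------------------------------------------------------------------
# Procrustes ANOVA

@dataclass
class ANOVAResult:
    """Sequential Procrustes ANOVA table with permutation p and Z effect sizes."""

    table: pd.DataFrame  # index: term names + "Residuals" + "Total"
    coef: dict  # term -> (term df columns, p) coefficient rows (full model)
    n_perm: int
    meta: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t not in ("Residuals", "Total")]

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def rsq(self, term: str | None = None) -> float:
        if term is not None:
            return float(self.table.loc[term, "Rsq"])
        return float(self.table.loc[self.terms, "Rsq"].sum())

    def z(self, term: str) -> float:
        return float(self.table.loc[term, "Z"])


def _term_columns(name, values, n):
    values = np.asarray(values)
    if values.shape[0] != n:
        raise DesignError(f"term {name!r} has {values.shape[0]} rows, data has {n}")
    if values.dtype.kind in "OUS" or values.dtype == bool:
        levels = pd.unique(values)
        if len(levels) < 2:
            raise DesignError(f"factor {name!r} has a single level")
        cols = np.column_stack(
            [(values == lev).astype(float) for lev in levels[1:]]
        )
        return cols, [f"{name}[{lev}]" for lev in levels[1:]]
    cols = values.astype(float).reshape(n, -1)
    if np.ptp(cols, axis=0).min() == 0:
        raise DesignError(f"term {name!r} is constant")
    return cols, [name] if cols.shape[1] == 1 else [
        f"{name}{j}" for j in range(cols.shape[1])
    ]


def _orthonormal_increment(block, Qcum, tol=1e-9):
    """Orthonormal basis of the part of ``block`` outside span(Qcum)."""
    R = block - Qcum @ (Qcum.T @ block)
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    keep = s > tol * max(1.0, s[0] if s.size else 0.0)
    return U[:, keep]


def procrustes_anova(
    Y: np.ndarray,
    terms: Sequence[tuple],
    n_perm: int = 999,
    seed=None,
    tree: Phylogeny | None = None,
    species: Sequence[str] | None = None,
    perms: np.ndarray | None = None,
) -> ANOVAResult:
    """Sequential Procrustes ANOVA with RRPP permutation inference.

    ``Y`` is (n, p) multivariate data (flattened aligned shapes or PC
    scores); ``terms`` is an ordered list of ``(name, values)`` pairs where
    string/bool values denote factors and numeric values covariates.  With
    ``tree`` (and matching ``species`` order) the design and data are
    premultiplied by the inverse square root of the BM covariance, giving
    the phylogenetic version.  ``perms`` allows sharing one permutation
    schedule across model fits; otherwise it is drawn from ``seed``.
    The observed arrangement counts as one permutation; p-values therefore
    have floor 1 / (n_perm + 1).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    n = Y.shape[0]
    if not terms:
        raise DesignError("at least one model term is required")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse", stacklevel=2)
    blocks, names = [], []
    for name, values in terms:
        cols, _ = _term_columns(name, values, n)
        blocks.append(cols)
        names.append(name)
    intercept = np.ones((n, 1))
    if tree is not None:
        order = list(species) if species is not None else tree.taxa
        T = inverse_sqrt_covariance(tree.covariance(order))
        Y = T @ Y
        intercept = T @ intercept
        blocks = [T @ b for b in blocks]

    Q0 = intercept / np.linalg.norm(intercept)
    Qcum = Q0
    Qincs, dfs = [], []
    for b in blocks:
        qb = _orthonormal_increment(b, Qcum)
        if qb.shape[1] == 0:
            raise DesignError(
                f"term {names[len(Qincs)]!r} is collinear with earlier terms"
            )
        Qincs.append(qb)
        dfs.append(qb.shape[1])
        Qcum = np.column_stack([Qcum, qb])

    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise DesignError("no residual degrees of freedom")

    def _ss_parts(Ymat):
        """Per-increment SS, corrected total SS, residual SS."""
        proj0 = Q0.T @ Ymat
        ss_tot = float((Ymat**2).sum() - (proj0**2).sum())
        ss_terms = np.array([float(((q.T @ Ymat) ** 2).sum()) for q in Qincs])
        return ss_terms, ss_tot, ss_tot - ss_terms.sum()

    ss_terms, ss_total, ss_res = _ss_parts(Y)
    if ss_total <= 0:
        raise DesignError("zero total variation in the data")
    ms_res = ss_res / df_res
    F_obs = (ss_terms / np.array(dfs)) / max(ms_res, 1e-300)

    if perms is None:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    else:
        n_perm = perms.shape[0]

    # column ranges of each term's orthonormal increment within Qcum
    # (column 0 is the intercept direction)
    starts, s0 = [], 1
    for d in dfs:
        starts.append((s0, s0 + d))
        s0 += d
    QcumT = np.ascontiguousarray(Qcum.T)
    F_perm = np.empty((n_perm, len(blocks)))
    for i in range(len(blocks)):
        Qred = np.column_stack([Q0] + Qincs[:i]) if i else Q0
        fit_red = Qred @ (Qred.T @ Y)
        resid_red = Y - fit_red
        lo, hi = starts[i]
        chunk = max(1, int(2e7 // max(1, n * Y.shape[1])))
        for start in range(0, n_perm, chunk):
            P = perms[start : start + chunk]
            Ystar = fit_red[None, :, :] + resid_red[P]
            M = QcumT @ Ystar  # (b, r, p) projections onto all fitted directions
            ss_i = (M[:, lo:hi, :] ** 2).sum(axis=(1, 2))
            sse = (Ystar**2).sum(axis=(1, 2)) - (M**2).sum(axis=(1, 2))
            F_perm[start : start + len(P), i] = (ss_i / dfs[i]) / np.maximum(
                sse / df_res, 1e-300
            )
            del Ystar, M

    eps = 1e-12
    p_vals = (1 + (F_perm >= F_obs[None, :] - eps).sum(axis=0)) / (n_perm + 1)
    with np.errstate(divide="ignore"):
        logF = np.log(np.concatenate([F_obs[None, :], F_perm], axis=0))
    logF = np.where(np.isfinite(logF), logF, -700.0)
    sd = logF.std(axis=0, ddof=1)
    Z = (np.log(np.maximum(F_obs, 1e-300)) - logF.mean(axis=0)) / np.where(
        sd > 0, sd, np.inf
    )

    # full-model coefficients (for fitted group means / deviations)
    Xfull = np.column_stack([intercept] + blocks)
    beta, *_ = np.linalg.lstsq(Xfull, Y, rcond=None)
    coef, offset = {}, 1
    for name, b in zip(names, blocks):
        coef[name] = beta[offset : offset + b.shape[1]]
        offset += b.shape[1]

    rows = []
    for i, name in enumerate(names):
        rows.append(
            {
                "Df": dfs[i],
                "SS": ss_terms[i],
                "MS": ss_terms[i] / dfs[i],
                "Rsq": ss_terms[i] / ss_total,
                "F": F_obs[i],
                "Z": Z[i],
                "p": p_vals[i],
            }
        )
    table = pd.DataFrame(rows, index=names)
    table.loc["Residuals"] = {
        "Df": df_res, "SS": ss_res, "MS": ms_res,
        "Rsq": ss_res / ss_total, "F": np.nan, "Z": np.nan, "p": np.nan,
    }
    table.loc["Total"] = {
        "Df": n - 1, "SS": ss_total, "MS": np.nan,
        "Rsq": np.nan, "F": np.nan, "Z": np.nan, "p": np.nan,
    }
    return ANOVAResult(
        table=table,
        coef=coef,
        n_perm=n_perm,
        meta={"phylogenetic": tree is not None, "rrpp": True, "n": n},
    )


def group_deviation(anova: ANOVAResult, capability: str, pca=None):
    """Morphological deviation between fitted mean shapes for capability 1 vs 0.

    The deviation is the Euclidean (Procrustes) distance between the model's
    fitted mean for capability present and absent, i.e. the norm of the
    capability's coefficient row, holding the other terms fixed.  With a
    ``pca`` (:class:`~columnmorph.procrustes.PCAResult`) the displacement is
    also back-projected to landmark space.
    """
    if capability not in anova.coef:
        raise DesignError(f"capability {capability!r} not in the fitted design")
    b = anova.coef[capability]
    if b.shape[0] != 1:
        raise DesignError(f"term {capability!r} is not a single binary column")
    dist = float(np.linalg.norm(b))
    if pca is None:
        return dist
    disp = (b @ pca.loadings).reshape(pca.mean_shape.shape)
    return dist, disp


# ---------------------------------------------------------------------------
# Exhaustive model selection

@dataclass
class ModelSelectionResult:
    """Best admissible capability subset for one vertebral group."""

    chosen: tuple  # capability names; empty if no admissible model
    rsq: float
    term_p: dict
    ledger: pd.DataFrame  # every candidate subset with R^2 and admissibility
    anova: ANOVAResult | None = None

    @property
    def empty(self) -> bool:
        return len(self.chosen) == 0


def select_best_model(
    Y: np.ndarray,
    capabilities: pd.DataFrame,
    tree: Phylogeny | None = None,
    species: Sequence[str] | None = None,
    n_perm: int = 999,
    seed=None,
    alpha: float = 0.1,
) -> ModelSelectionResult:
    """Fit every non-empty capability subset; keep the admissible model
    (all terms p < ``alpha``) with the highest total R^2.

    Terms enter each model in the canonical capability order, which fixes
    the sequential sums of squares.  One permutation schedule (drawn from
    ``seed``) is shared by all candidate models, so the search is
    deterministic given the seed.  When no subset is admissible the result
    is an empty selection, not an error.
    """
    caps = [c for c in CAPABILITIES if c in capabilities.columns]
    order = list(species) if species is not None else list(capabilities.index)
    mat = capabilities.loc[order, caps]
    varying = [c for c in caps if mat[c].nunique() > 1]
    if not varying:
        raise DesignError("no capability varies across the species sample")
    n = len(order)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    records, fits = [], {}
    for size in range(1, len(varying) + 1):
        for subset in itertools.combinations(varying, size):
            terms = [(c, mat[c].to_numpy()) for c in subset]
            try:
                res = procrustes_anova(
                    Y, terms, tree=tree, species=order, perms=perms
                )
            except DesignError:
                records.append(
                    {"subset": "+".join(subset), "rsq": np.nan,
                     "admissible": False, "max_term_p": np.nan}
                )
                continue
            pvals = {c: res.p(c) for c in subset}
            admissible = all(p < alpha for p in pvals.values())
            fits[subset] = (res, pvals, admissible)
            records.append(
                {
                    "subset": "+".join(subset),
                    "rsq": res.rsq(),
                    "admissible": admissible,
                    "max_term_p": max(pvals.values()),
                }
            )
    ledger = pd.DataFrame(records)
    admissible_fits = {s: f for s, f in fits.items() if f[2]}
    if not admissible_fits:
        return ModelSelectionResult((), 0.0, {}, ledger, None)
    best = max(admissible_fits, key=lambda s: admissible_fits[s][0].rsq())
    res, pvals, _ = admissible_fits[best]
    return ModelSelectionResult(best, res.rsq(), pvals, ledger, res)


def significance_stratum(p: float) -> str:
    """Ordinal significance class used in the per-vertebra grids."""
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    if p < 0.1:
        return "p<0.1"
    return "ns"


@dataclass
class EcologicalScan:
    """Per-group model selection plus the capability x vertebra grid."""

    results: dict  # group label -> ModelSelectionResult
    grid_p: pd.DataFrame  # groups x capabilities, marginal permutation p
    grid: pd.DataFrame  # significance strata
    skipped: list


def ecological_scan(
    data_by_group: Mapping[str, tuple],
    capabilities: pd.DataFrame,
    tree: Phylogeny | None = None,
    exclude: Sequence[str] = (),
    n_perm: int = 999,
    seed=None,
    alpha: float = 0.1,
    min_species: int = 3,
) -> EcologicalScan:
    """Run the exhaustive search for every vertebral group.

    ``data_by_group`` maps a group label to ``(Y, species)`` where ``Y`` is
    the group's species-level multivariate shape data (typically
    allometry-corrected PC scores).  ``exclude`` removes species (e.g.
    aquatic taxa) before fitting; capabilities that become constant are
    dropped from the candidate set, and groups reduced below ``min_species``
    are skipped with a log entry.  Marginal grid p-values come from the
    single-capability candidate models of the exhaustive ledger.
    """
    exclude = set(exclude)
    results: dict = {}
    skipped: list = []
    grid_rows: dict = {}
    base_seed = np.random.SeedSequence(seed)
    for gi, (label, (Y, sp)) in enumerate(data_by_group.items()):
        sp = list(sp)
        keep = [i for i, s in enumerate(sp) if s not in exclude]
        if len(keep) < min_species:
            skipped.append((label, f"only {len(keep)} species after exclusion"))
            continue
        Yg = np.atleast_2d(np.asarray(Y, float))[keep]
        spg = [sp[i] for i in keep]
        sub_tree = tree
        if tree is not None and set(spg) != set(tree.taxa):
            sub_tree, _ = tree.prune_to(spg)
        caps_g = capabilities.loc[spg]
        if all(caps_g[c].nunique() < 2 for c in CAPABILITIES if c in caps_g):
            skipped.append((label, "no varying capability"))
            continue
        sub_seed = int(base_seed.generate_state(1)[0] % (2**31)) + gi
        sel = select_best_model(
            Yg, caps_g, tree=sub_tree, species=spg,
            n_perm=n_perm, seed=sub_seed, alpha=alpha,
        )
        results[label] = sel
        row = {}
        for c in CAPABILITIES:
            hit = sel.ledger[sel.ledger["subset"] == c]
            row[c] = float(hit["max_term_p"].iloc[0]) if len(hit) else np.nan
        grid_rows[label] = row
    grid_p = pd.DataFrame.from_dict(grid_rows, orient="index", columns=list(CAPABILITIES))
    grid = grid_p.map(lambda p: "-" if np.isnan(p) else significance_stratum(p))
    return EcologicalScan(results=results, grid_p=grid_p, grid=grid, skipped=skipped)
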