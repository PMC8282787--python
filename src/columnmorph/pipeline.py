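"""End-to-end orchestration of the column analysis workflow.

One call runs, per region: object-symmetry GPA, species averaging and
tangent PCA; then per seriation scheme: disparity profiles, per-group
allometry-corrected DTT/MDI, the exhaustive ecological model search (with
and without aquatic taxa), the within-region position ANOVAs and the three
AR1-GLS metric comparisons.  Every table lands in the output directory as
CSV/JSON with a manifest recording versions, seeds and the numerical
conventions actually used.  The pipeline is a pure function of (inputs,
seed): rerunning with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .column_data import (
    DEFAULT_K,
    build_by_number_groups,
    build_by_position_groups,
    read_dataset_dir,
    read_species_meta,
    validate_dataset,
)
from .disparity import disparity_profile
from .dtt import mdi
from .ecomorph import CAPABILITIES, ecological_scan
from .errors import ConfigurationError, DesignError
from .phylo import Phylogeny, allometry_residuals, read_newick
from .procrustes import (
    average_by_species,
    labels_from_records,
    symmetric_component,
    tangent_pca,
)
from .serial_stats import (
    BY_NUMBER_SERIES,
    BY_POSITION_SERIES,
    compare_metrics,
    gls_ar1,
    position_anova,
)
from .synthetic import build_template, generate_columns, reference_scenario

REGIONS = ("cervical", "thoracic", "lumbar")


def stage_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed fan-out (stable across runs/platforms)."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run."""

    out_dir: str
    seed: int
    scenario: str | None = None  # synthetic scenario name ...
    n_species: int | None = None
    landmarks_dir: str | None = None  # ... or real input paths
    metadata_path: str | None = None
    tree_path: str | None = None
    capabilities_path: str | None = None
    schemes: tuple = ("by_number", "by_position")
    n_perm: int = 999
    n_sim: int = 1000
    exclude: tuple = ()  # extra species exclusions applied everywhere
    run_aquatic_exclusion: bool = True
    min_group_species: int = 8  # groups smaller than this skip MDI/ecology

    def validate(self) -> None:
        has_paths = self.landmarks_dir is not None
        if (self.scenario is None) == (not has_paths):
            raise ConfigurationError(
                "exactly one of a synthetic scenario or input paths is required"
            )
        if has_paths and None in (self.metadata_path, self.tree_path):
            raise ConfigurationError("metadata_path and tree_path are required")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


class StageFailure(ConfigurationError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        cfg = reference_scenario(
            config.scenario, n_species=config.n_species, seed=config.seed
        )
        ds = generate_columns(cfg)
        return ds.records, ds.meta, ds.capabilities, ds.tree, ds.pairings
    records = read_dataset_dir(config.landmarks_dir)
    meta = read_species_meta(config.metadata_path)
    tree = read_newick(config.tree_path)
    species = sorted({r.species for r in records})
    tree, _ = tree.prune_to(species)
    caps = None
    if config.capabilities_path:
        caps = pd.read_csv(config.capabilities_path, index_col=0)
    pairings = {r: build_template(r)[1] for r in REGIONS}
    return records, meta, caps, tree, pairings


def _align_regions(records, pairings):
    """Symmetric-component GPA and species averaging, per region."""
    aligned, pca = {}, {}
    for region in REGIONS:
        recs = [r for r in records if r.region == region]
        if not recs:
            continue
        sym = symmetric_component(
            recs, pairings[region], labels=labels_from_records(recs)
        )
        avg = average_by_species(sym)
        aligned[region] = avg
        pca[region] = tangent_pca(avg)
    return aligned, pca


def _group_scores(aligned, scheme, key, tree, min_species):
    """Species-level allometry-corrected PC scores for one seriation group."""
    region = scheme.region_of(key)
    sub = aligned[region]
    idx = sub.row_index()
    rows, species = [], []
    for member in scheme.groups[key]:
        if member in idx:
            rows.append(idx[member])
            species.append(member[0])
    if len(rows) < min_species:
        return None
    Y = sub.flat[np.array(rows)]
    sizes = sub.centroid_size[np.array(rows)]
    sub_tree = tree
    if set(species) != set(tree.taxa):
        sub_tree, _ = tree.prune_to(species)
    # reorder rows to the pruned tree's taxon order (DTT/BM machinery
    # addresses tips positionally)
    pos = {sp: i for i, sp in enumerate(species)}
    take = np.array([pos[sp] for sp in sub_tree.taxa])
    Y, sizes, species = Y[take], sizes[take], list(sub_tree.taxa)
    resid = allometry_residuals(Y, sizes, sub_tree, species=species)
    centred = resid - resid.mean(axis=0)
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    keep = s > max(1e-12, 1e-10 * s[0])
    return (U[:, keep] * s[keep]), species, sub_tree


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the complete workflow; returns result objects and file paths.

    Any stage failure halts the run with the stage name and cause; tables
    already written remain in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"paths": {}, "timing": {}}
    manifest = {
        "columnmorph_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_sim": config.n_sim,
        "schemes": list(config.schemes),
        "conventions": {
            "disparity_divisor": "n",
            "disparity_standardisation": "per landmark (K)",
            "mdi_center": "mean simulated curve",
            "mdi_integration": "trapezoid over [0, 1] incl. terminal segment",
            "term_order": list(CAPABILITIES),
            "admissibility": "sequential-SS term p < 0.1",
            "size_covariate": "log centroid size",
        },
        "stages": [],
    }

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            raise StageFailure(name, exc) from exc
        dt = time.perf_counter() - t0
        results["timing"][name] = dt
        manifest["stages"].append({"stage": name, "seconds": round(dt, 3)})
        return value

    records, meta, caps, tree, pairings = _stage(
        "load", lambda: _load_inputs(config)
    )
    if config.exclude:
        drop = set(config.exclude)
        records = [r for r in records if r.species not in drop]
        meta = [m for m in meta if m.species not in drop]
        tree, _ = tree.prune_to(sorted({r.species for r in records}))
    _stage("validate", lambda: validate_dataset(records, meta))

    aligned, pca = _stage("align", lambda: _align_regions(records, pairings))
    results["aligned"] = aligned
    results["pca"] = pca
    pca_rows = [
        {"region": rg, "pc": i + 1, "variance_explained": float(v)}
        for rg, p in pca.items()
        for i, v in enumerate(p.variance_explained[:10])
    ]
    pd.DataFrame(pca_rows).to_csv(out / "pca_variance.csv", index=False)
    results["paths"]["pca_variance"] = str(out / "pca_variance.csv")

    schemes = {}
    builders = {"by_number": build_by_number_groups, "by_position": build_by_position_groups}
    for name in config.schemes:
        schemes[name] = _stage(f"scheme:{name}", lambda n=name: builders[n](records, meta))
    results["schemes"] = schemes

    # --- disparity profiles
    disparity_tables = {}
    for name, scheme in schemes.items():
        table = _stage(
            f"disparity:{name}", lambda s=scheme: disparity_profile(aligned, s)
        )
        path = out / f"disparity_{name}.csv"
        table.to_csv(path, index=False)
        disparity_tables[name] = table
        results["paths"][f"disparity_{name}"] = str(path)
    results["disparity"] = disparity_tables

    # --- per-group DTT / MDI on allometry-corrected scores
    mdi_tables, curve_rows = {}, []
    for name, scheme in schemes.items():
        def _run_mdi(scheme=scheme, name=name):
            rows = []
            for key in scheme.order:
                label = scheme.group_label(key)
                prepared = _group_scores(
                    aligned, scheme, key, tree, config.min_group_species
                )
                if prepared is None:
                    continue
                scores, species, sub_tree = prepared
                res = mdi(
                    sub_tree, scores, n_sim=config.n_sim,
                    seed=stage_seed(config.seed, f"mdi:{name}:{label}"),
                )
                rows.append(
                    {"scheme": name, "group": label,
                     "region": scheme.region_of(key),
                     "n_species": len(species), "mdi": res.mdi}
                )
                for t, o in zip(res.times, res.observed):
                    curve_rows.append(
                        {"scheme": name, "group": label,
                         "rel_time": float(t), "observed": float(o)}
                    )
            return pd.DataFrame(rows)

        mdi_tables[name] = _stage(f"mdi:{name}", _run_mdi)
        path = out / f"mdi_{name}.csv"
        mdi_tables[name].to_csv(path, index=False)
        results["paths"][f"mdi_{name}"] = str(path)
    pd.DataFrame(curve_rows).to_csv(out / "dtt_curves.csv", index=False)
    results["paths"]["dtt_curves"] = str(out / "dtt_curves.csv")
    results["mdi"] = mdi_tables

    # --- ecological scans (with and without aquatic taxa)
    scans: dict = {}
    if caps is not None:
        aquatic_species = tuple(caps.index[caps["aquatic"] == 1])
        variants = {"all": ()}
        if config.run_aquatic_exclusion and aquatic_species:
            variants["no_aquatic"] = aquatic_species
        for name, scheme in schemes.items():
            data_by_group = {}
            for key in scheme.order:
                prepared = _group_scores(
                    aligned, scheme, key, tree, config.min_group_species
                )
                if prepared is not None:
                    data_by_group[scheme.group_label(key)] = (
                        prepared[0], prepared[1]
                    )
            for variant, excluded in variants.items():
                scan = _stage(
                    f"ecology:{name}:{variant}",
                    lambda d=data_by_group, e=excluded, n=name, v=variant: ecological_scan(
                        d, caps, tree=tree, exclude=e,
                        n_perm=config.n_perm,
                        seed=stage_seed(config.seed, f"ecology:{n}:{v}"),
                    ),
                )
                scans[(name, variant)] = scan
                scan.grid.to_csv(out / f"ecology_grid_{name}_{variant}.csv")
                best = pd.DataFrame(
                    [
                        {"group": g, "model": "+".join(r.chosen), "rsq": r.rsq,
                         "max_term_p": max(r.term_p.values()) if r.term_p else np.nan}
                        for g, r in scan.results.items()
                    ]
                )
                best.to_csv(out / f"ecology_best_{name}_{variant}.csv", index=False)
                results["paths"][f"ecology_{name}_{variant}"] = str(
                    out / f"ecology_best_{name}_{variant}.csv"
                )
    results["ecology"] = scans

    # --- within-region position ANOVAs
    anova_frames = []
    results["position_anova"] = {}
    for region in aligned:
        res = _stage(
            f"position_anova:{region}",
            lambda r=region: position_anova(
                aligned[r], r, n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"anova:{r}"),
            ),
        )
        results["position_anova"][region] = res
        frame = res.table.reset_index(names="term")
        frame.insert(0, "region", region)
        anova_frames.append(frame)
    pd.concat(anova_frames).to_csv(out / "position_anova.csv", index=False)
    results["paths"]["position_anova"] = str(out / "position_anova.csv")

    # --- AR1-GLS comparisons among the per-position metrics
    series_orders = {"by_number": BY_NUMBER_SERIES, "by_position": BY_POSITION_SERIES}
    gls_rows = []
    results["serial_gls"] = {}
    for name in schemes:
        disp = disparity_tables[name].set_index("group")["standardized_disparity"]
        mdi_s = mdi_tables[name].set_index("group")["mdi"]
        scan = scans.get((name, "all"))
        if scan is None:
            continue
        rsq = pd.Series(
            {g: r.rsq for g, r in scan.results.items()}, dtype=float
        )
        order = [
            k for k in series_orders[name]
            if k in disp.index and k in mdi_s.index and k in rsq.index
        ]
        if len(order) < 4:
            continue
        def _fit_serial(d=disp, m=mdi_s, r=rsq, o=order):
            try:
                return compare_metrics(d, m, r, o)
            except DesignError:
                # a degenerate series (e.g. every group without ecological
                # signal, R^2 identically 0) makes some regressions
                # unfittable; keep the ones that are
                fits = {}
                for pair, (yy, xx) in {
                    "disparity_vs_mdi": (d, m),
                    "disparity_vs_ecology_rsq": (d, r),
                    "mdi_vs_ecology_rsq": (m, r),
                }.items():
                    try:
                        fits[pair] = gls_ar1(yy, xx, order=o)
                    except DesignError:
                        pass
                return fits

        fits = _stage(f"serial_gls:{name}", _fit_serial)
        results["serial_gls"][name] = fits
        for pair, fit in fits.items():
            gls_rows.append({"scheme": name, "comparison": pair, **fit.summary()})
    pd.DataFrame(gls_rows).to_csv(out / "serial_gls.csv", index=False)
    results["paths"]["serial_gls"] = str(out / "serial_gls.csv")

    manifest["outputs"] = sorted(results["paths"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["paths"]["manifest"] = str(out / "manifest.json")
    return results
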