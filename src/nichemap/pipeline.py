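"""End-to-end pipeline orchestration from a single YAML-style config.

Stages: simulate (or load) -> phenotype -> spatial features -> imputation ->
PERMANOVA (+ pairwise Holm contrasts) -> sPLS-DA -> paired permutation tests
on the leading discriminative features -> proximity bands.  Every stage's
seed derives deterministically from the run seed, so identical configs give
byte-identical reports.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .errors import ConfigError
from .io_tables import (
    read_cell_table,
    read_region_metadata,
    validate_dataset,
    write_cell_table,
    write_feature_matrix,
    write_region_metadata,
)
from .phenotyping import GateSpec, apply_gates, knn_density_cluster
from .proximity import band_counts, bands_long_format, compare_band_occupancy
from .simulate import NicheConfig, SimConfig, simulate_cohort, simulate_null_cohort
from .spatial import assemble_features
from .stats import (
    Permanova,
    SparsePLSDA,
    impute_missing,
    paired_permutation_test,
    pairwise_permanova,
    pca_contributions,
)
from .util import child_seed

PHENOTYPING_MODES = ("ground_truth", "cluster", "gates")


def sim_config_from_dict(doc: Mapping, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a (YAML) mapping; unknown keys are rejected."""
    doc = dict(doc or {})
    niche_doc = doc.pop("niche", {})
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown sim config keys: {sorted(unknown)}")
    niche_known = {f.name for f in dataclasses.fields(NicheConfig)}
    bad = set(niche_doc) - niche_known
    if bad:
        raise ConfigError(f"unknown niche config keys: {sorted(bad)}")
    kwargs = dict(doc)
    if "regions" in kwargs:
        kwargs["regions"] = tuple(kwargs["regions"])
    if niche_doc:
        kwargs["niche"] = NicheConfig(**niche_doc)
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config or {})


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the full analysis described by ``config`` and write artifacts.

    Returns the machine-readable run report (also written as
    ``stats_report.json``).  ``seed`` overrides the config's seed.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)

    report: dict = {"nichemap_version": __version__, "seed": seed, "stages": {}}

    # ------------------------------------------------------------------ input
    has_sim = "sim" in cfg
    has_input = "input" in cfg
    if has_sim == has_input:
        raise ConfigError("config needs exactly one of 'sim' or 'input'")
    truth = None
    if has_sim:
        sim_doc = dict(cfg["sim"] or {})
        null = bool(sim_doc.pop("null", False))
        sim_cfg = sim_config_from_dict(sim_doc, seed=child_seed(seed, "simulate"))
        cells, meta, truth = (
            simulate_null_cohort(sim_cfg) if null else simulate_cohort(sim_cfg)
        )
        write_cell_table(cells, out / "cells.csv")
        write_region_metadata(meta, out / "metadata.csv")
        truth.to_csv(out / "ground_truth.csv")
        report["stages"]["simulate"] = {
            "null": null,
            "n_cells": cells.n_cells,
            "n_images": meta.n_images,
            "designated_pairs": [list(p) for p in truth.designated_pairs],
        }
    else:
        cells = read_cell_table(cfg["input"]["cells"])
        meta = read_region_metadata(cfg["input"]["metadata"])

    vrep = validate_dataset(cells, meta)
    report["stages"]["validate"] = {
        "errors": vrep.errors,
        "warnings": vrep.warnings[:20],
        "n_cells": vrep.n_cells,
        "n_images": vrep.n_images,
        "n_patients": vrep.n_patients,
    }
    if not vrep.ok:
        raise ConfigError(f"dataset validation failed: {vrep.errors[:3]}")

    # ------------------------------------------------------------- phenotyping
    phen_cfg = dict(cfg.get("phenotyping", {"mode": "ground_truth"}))
    mode = phen_cfg.get("mode", "ground_truth")
    if mode not in PHENOTYPING_MODES:
        raise ConfigError(f"phenotyping mode must be one of {PHENOTYPING_MODES}")
    if mode == "ground_truth":
        if not cells.has_phenotype:
            raise ConfigError("ground_truth mode needs a phenotype column")
    elif mode == "cluster":
        k = int(phen_cfg.get("k_neighbors", 30))
        assign = knn_density_cluster(
            cells.expression(), k, cell_ids=cells.data["cell_id"]
        )
        cells = cells.with_phenotype([f"c{l:02d}" for l in assign.labels])
        report["stages"]["phenotyping"] = {"mode": mode, "K": assign.K, "k_neighbors": k}
    else:  # gates
        spec = GateSpec.from_yaml(phen_cfg["gates"])
        cells = apply_gates(cells, spec)
    report["stages"].setdefault("phenotyping", {"mode": mode})

    # ---------------------------------------------------------------- features
    feat_cfg = dict(cfg.get("features", {}))
    radius = float(feat_cfg.get("radius", 20.0))
    pooling = feat_cfg.get("pooling", "pool_cells")
    fm = assemble_features(cells, meta, radius=radius, pooling=pooling)
    write_feature_matrix(fm.data, out / "feature_matrix.csv")
    fm_complete = impute_missing(fm, distance_ceiling_um=float(
        feat_cfg.get("distance_ceiling_um", 1000.0)
    ))
    report["stages"]["features"] = {
        "radius_um": radius,
        "pooling": pooling,
        "K": len(fm.clusters),
        "n_samples": len(fm.data),
        "n_features": fm.data.shape[1],
        "feature_slots_per_patient": fm.n_feature_slots_per_patient,
    }

    # ------------------------------------------------------------------- stats
    stats_cfg = dict(cfg.get("stats", {}))
    n_perm = int(stats_cfg.get("n_permutations", 999))
    keep_x = int(stats_cfg.get("keepx", 25))
    n_comp = int(stats_cfg.get("n_components", 2))
    regions = fm_complete.region_labels().to_numpy(dtype=object)
    patients = fm_complete.patient_labels().to_numpy(dtype=object)

    perm_res = Permanova(fm_complete, regions, strata=patients).fit(
        permutations=n_perm, seed=child_seed(seed, "permanova")
    )
    pw = pairwise_permanova(
        fm_complete.data, regions, strata=patients,
        n_permutations=n_perm, seed=child_seed(seed, "pairwise"),
    )
    report["stages"]["permanova"] = {
        "pseudo_F": perm_res.pseudo_F,
        "R2": perm_res.R2,
        "p_value": perm_res.p_value,
        "n_permutations": n_perm,
        "pairwise": [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "pseudo_F": c.pseudo_F,
                "raw_p": c.raw_p,
                "holm_p": c.holm_p,
            }
            for c in pw
        ],
    }

    pca = pca_contributions(fm_complete, n_components=2)
    report["stages"]["pca"] = {
        "equal_contribution_reference_pct": pca.reference,
        "top_contributors_pc1": {
            k: float(v) for k, v in pca.top(1, 5).items()
        },
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
    }

    spls = SparsePLSDA(fm_complete, regions, n_components=n_comp, keep_x=keep_x).fit()
    spls.x_weights.to_csv(out / "loadings.csv", index_label="feature")
    report["stages"]["splsda"] = {
        "keepX": spls.keep_x,
        "selected": {f"comp{c+1}": spls.selected[c] for c in range(spls.n_components)},
    }

    # paired contrasts on the strongest component-1 features
    region_a = stats_cfg.get("region_a", "tumor")
    region_b = stats_cfg.get("region_b", "nontumor")
    top = list(spls.top_features(1, int(stats_cfg.get("n_paired_features", 5))).index)
    paired = []
    wide_ok = {region_a, region_b} <= set(regions)
    for feat in top:
        if not wide_ok:
            break
        col = fm_complete.data[feat].unstack("region_class")
        res = paired_permutation_test(
            col[region_a].to_numpy(float),
            col[region_b].to_numpy(float),
            n_permutations=n_perm,
            seed=child_seed(seed, f"paired:{feat}"),
        )
        paired.append(
            {
                "feature": feat,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "mean_difference": res.mean_difference,
                "exact": res.exact,
            }
        )
    report["stages"]["paired_tests"] = {
        "region_a": region_a, "region_b": region_b, "tests": paired,
    }

    # flagged designated pairs: selected on component 1 AND paired p <= 0.05
    if truth is not None and truth.designated_pairs and wide_ok:
        flagged = []
        for member, pvm in truth.designated_pairs:
            feat = f"neigh_{member}_{pvm}"
            if feat not in fm_complete.data.columns:
                continue
            if feat not in spls.selected[0]:
                continue
            col = fm_complete.data[feat].unstack("region_class")
            res = paired_permutation_test(
                col[region_a].to_numpy(float),
                col[region_b].to_numpy(float),
                n_permutations=n_perm,
                seed=child_seed(seed, f"flag:{feat}"),
            )
            if res.p_value <= 0.05:
                flagged.append(feat)
        report["stages"]["flagged_designated_pairs"] = flagged

    # ------------------------------------------------------------------- bands
    bands_cfg = dict(cfg.get("bands", {}))
    phen_values = set(cells.data["phenotype"])
    reference = bands_cfg.get("reference")
    query = bands_cfg.get("query")
    if reference is None and truth is not None:
        roles = {}
        # infer default reference/query from simulated roles when available
        sim_phens = sim_cfg.phenotypes if has_sim else []
        for p in sim_phens:
            roles.setdefault(p.role, p.name)
        reference = roles.get("endothelial")
        query = query or roles.get("perivascular_macrophage")
    if reference and query and reference in phen_values and query in phen_values:
        width = float(bands_cfg.get("width", 20.0))
        max_d = float(bands_cfg.get("max", 100.0))
        table = band_counts(cells, reference, query, band_width=width, max_dist=max_d)
        bands_long_format(table).to_csv(out / "bands.csv", index=False)
        profile = table.total_profile()
        cmp_res = compare_band_occupancy(
            table,
            band_a=(0.0, width),
            band_b=(2 * width, 3 * width),
            n_permutations=n_perm,
            seed=child_seed(seed, "bands"),
        )
        report["stages"]["bands"] = {
            "reference": reference,
            "query": query,
            "profile": {k: int(v) for k, v in profile.items()},
            "peak_band": str(profile.idxmax()) if profile.sum() else None,
            "band_comparison": {
                "band_a": f"0-{width:g}",
                "band_b": f"{2*width:g}-{3*width:g}",
                "statistic": cmp_res.statistic,
                "p_value": cmp_res.p_value,
            },
        }

    report_path = out / "stats_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
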