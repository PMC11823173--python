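"""End-to-end orchestration: config validation, staged run, manifest.

The pipeline runs, per cohort split: low-expression filtering, soft-power
selection, signed network + TOM module detection, anchor-module extraction,
(optional) preservation against a second cohort, %G.A.M.E. stratification,
gene-set overlap enrichment, differential set activity, (optional)
deconvolution, and survival models for each requested signal variable.
Every output table is written as TSV and checksummed into a JSON run
manifest; identical (config, seed) pairs produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import game as game_mod
from . import io as cio
from .celltype import correlate_fractions_with_game, impute_fractions
from .network import (NetworkConfig, detect_modules, extract_anchor_module,
                      select_soft_power, signed_adjacency, topological_overlap)
from .preprocess import (filter_low_expression_counts, filter_low_expression_rsem,
                         filter_low_intensity)
from .preservation import z_summary
from .setstats import activity_screen, bh_adjust, enrichment_screen
from .survival import fit_coxph, km_estimate

logger = logging.getLogger("colxnet")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

KNOWN_KEYS = {
    "expression_path", "expression_unit", "clinical_path", "gene_set_paths",
    "test_expression_path", "test_expression_unit", "signature_path",
    "anchor_gene", "network", "preservation", "low_intensity_threshold",
    "survival_outcomes", "survival_signals", "split_by", "seed", "output_dir",
    "game_classes", "cohort_label",
}
NETWORK_KEYS = {"candidate_powers", "fit_r2_target", "min_module_size",
                "deep_split_level", "correlation", "max_genes"}
PRESERVATION_KEYS = {"n_permutations"}


@dataclass
class RunConfig:
    expression_path: str
    clinical_path: str | None = None
    expression_unit: str = "rsem"
    gene_set_paths: dict[str, str] = field(default_factory=dict)
    test_expression_path: str | None = None
    test_expression_unit: str = "rsem"
    signature_path: str | None = None
    anchor_gene: str = "COL10A1"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    n_permutations: int = 200
    low_intensity_threshold: float | None = None
    survival_outcomes: tuple[str, ...] = ("os",)
    survival_signals: tuple[str, ...] = ("anchor_gene", "me", "game")
    split_by: str | None = None          # e.g. "gender"
    game_classes: int = 3
    seed: int = 0
    output_dir: str = "colxnet_results"
    cohort_label: str = "cohort"


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config, aggregating all problems."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    errors: list[str] = []
    unknown = set(raw) - KNOWN_KEYS
    for k in sorted(unknown):
        errors.append(f"unknown key {k!r}")
    if "expression_path" not in raw:
        errors.append("missing required key 'expression_path'")
    net_raw = raw.pop("network", {}) or {}
    unknown_net = set(net_raw) - NETWORK_KEYS
    for k in sorted(unknown_net):
        errors.append(f"unknown network key {k!r}")
    pres_raw = raw.pop("preservation", {}) or {}
    unknown_p = set(pres_raw) - PRESERVATION_KEYS
    for k in sorted(unknown_p):
        errors.append(f"unknown preservation key {k!r}")
    for pkey in ("expression_path", "clinical_path", "test_expression_path",
                 "signature_path"):
        p = raw.get(pkey)
        if p is not None and not Path(p).exists():
            errors.append(f"{pkey}: file not found: {p}")
    for name, p in (raw.get("gene_set_paths") or {}).items():
        if not Path(p).exists():
            errors.append(f"gene_set_paths[{name}]: file not found: {p}")
    if errors:
        raise ValueError(f"{path}: invalid config:\n  " + "\n  ".join(errors))
    raw = {k: v for k, v in raw.items() if k in KNOWN_KEYS}
    if "candidate_powers" in net_raw:
        net_raw["candidate_powers"] = tuple(net_raw["candidate_powers"])
    cfg = RunConfig(network=NetworkConfig(**net_raw),
                    n_permutations=int(pres_raw.get("n_permutations", 200)),
                    **raw)
    cfg.survival_outcomes = tuple(cfg.survival_outcomes)
    cfg.survival_signals = tuple(cfg.survival_signals)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _filter_expression(X: cio.ExpressionMatrix, config: RunConfig):
    if X.unit == cio.Unit.RSEM:
        return filter_low_expression_rsem(X)
    if X.unit == cio.Unit.COUNTS:
        return filter_low_expression_counts(X)
    if X.unit == cio.Unit.LOG_INTENSITY:
        if config.low_intensity_threshold is None:
            raise ValueError("low_intensity_threshold is required for "
                             "log-intensity matrices and has no default")
        return filter_low_intensity(X, config.low_intensity_threshold)
    return X, None


def _analyze_cohort(X: cio.ExpressionMatrix, clinical: cio.ClinicalTable | None,
                    config: RunConfig, out: Path, tag: str,
                    X_test: cio.ExpressionMatrix | None,
                    collections: dict[str, cio.GeneSetCollection],
                    signature: pd.DataFrame | None) -> dict:
    stage: dict = {"cohort": tag, "n_genes_in": X.n_genes, "n_samples": X.n_samples}
    X_f, report = _filter_expression(X, config)
    if report is not None:
        stage["filter"] = {"rule": report.rule, "removed": len(report.genes_removed),
                           "kept": report.genes_kept_count}
        if config.anchor_gene in report.genes_removed:
            raise ValueError(
                f"anchor gene {config.anchor_gene!r} was removed by the "
                f"{report.rule} filter; it cannot seed a module")
    if config.anchor_gene not in set(X_f.gene_ids):
        raise ValueError(f"anchor gene {config.anchor_gene!r} absent after filtering")
    if X_f.unit == cio.Unit.COUNTS:
        from .preprocess import log_transform, median_of_ratios_normalize
        X_f, _ = median_of_ratios_normalize(X_f)
        X_f = log_transform(X_f)

    beta, fit_table = select_soft_power(X_f, config.network)
    stage["soft_power"] = {"beta": beta,
                           "fit_r2_target": config.network.fit_r2_target,
                           "reached_target": bool(
                               (fit_table["sft_r2"] >= config.network.fit_r2_target).any())}
    fit_table.to_csv(out / f"{tag}_soft_power.tsv", sep="\t", index=False)

    tom = topological_overlap(signed_adjacency(X_f, beta,
                                               config.network.correlation))
    partition = detect_modules(tom, X_f, config.network)
    mid, module_genes, status = extract_anchor_module(partition,
                                                      config.anchor_gene, X_f)
    stage["anchor_module"] = {"id": mid, "size": len(module_genes),
                              "status": status}
    pd.Series(partition.labels, name="module").rename_axis("gene").to_frame() \
        .to_csv(out / f"{tag}_modules.tsv", sep="\t")
    partition.eigengenes.rename_axis("sample_id") \
        .to_csv(out / f"{tag}_eigengenes.tsv", sep="\t")
    if status == "unassigned":
        return stage

    if X_test is not None:
        pres = z_summary(module_genes, X_f, X_test, beta,
                         n_perm=config.n_permutations, seed=config.seed)
        stage["preservation"] = {"z_summary": pres.z_summary,
                                 "z_density": pres.z_density,
                                 "z_connectivity": pres.z_connectivity,
                                 "n_permutations": pres.n_permutations}
        (out / f"{tag}_preservation.json").write_text(json.dumps({
            "observed": pres.observed, "z_scores": pres.z_scores,
            "z_density": pres.z_density, "z_connectivity": pres.z_connectivity,
            "z_summary": pres.z_summary}, indent=2))

    strata = game_mod.stratify_samples(X_f, module_genes, k=config.game_classes)
    strata.table.rename_axis("sample_id").to_csv(out / f"{tag}_game.tsv", sep="\t")
    (out / f"{tag}_game_breaks.json").write_text(
        json.dumps({"breaks": list(strata.breaks)}))
    stage["game"] = {"breaks": list(strata.breaks),
                     "group_sizes": strata.table["group"].value_counts().to_dict()}

    universe = list(X_f.gene_ids)
    groups = {
        "high": [s for s, l in zip(strata.table.index, strata.table["km_label"]) if l == "high"],
        "low": [s for s, l in zip(strata.table.index, strata.table["km_label"]) if l == "low"],
    }
    for cname, coll in collections.items():
        enr = enrichment_screen(coll, module_genes, universe, mode="standard")
        pd.DataFrame([{
            "set": r.set_name, "overlap": r.overlap, "odds_ratio": r.odds_ratio,
            "p": r.p, "p_adj": r.p_adj, "significant": r.significant,
        } for r in enr]).to_csv(out / f"{tag}_enrichment_{cname}.tsv",
                                sep="\t", index=False)
        try:
            act = activity_screen(coll, X_f, groups, module_genes, universe)
        except ValueError as exc:
            logger.warning("activity screen for %s skipped: %s", cname, exc)
            continue
        pd.DataFrame([{
            "set": r.set_name, "enrichment": r.enrichment, "vif": r.vif,
            "p": r.p, "p_adj": r.p_adj, "significant": r.significant,
            "reference_activity": r.reference_activity,
        } for r in act]).to_csv(out / f"{tag}_activity_{cname}.tsv",
                                sep="\t", index=False)

    if signature is not None:
        fracs = impute_fractions(signature, X_f)
        fracs.rename_axis("sample_id").to_csv(out / f"{tag}_fractions.tsv", sep="\t")
        for rel in (False, True):
            corr = correlate_fractions_with_game(fracs, strata.game, relative=rel)
            corr.to_csv(out / f"{tag}_fraction_game_corr_"
                              f"{'rel' if rel else 'abs'}.tsv", sep="\t", index=False)

    if clinical is not None:
        me, _ = partition.eigengenes[f"ME{mid}"], None
        signals = {}
        if "anchor_gene" in config.survival_signals:
            idx = X_f.gene_ids.index(config.anchor_gene)
            signals[config.anchor_gene] = pd.Series(X_f.values[idx], index=X_f.sample_ids)
        if "me" in config.survival_signals:
            signals["ME"] = pd.Series(me.to_numpy(), index=X_f.sample_ids)
        if "game" in config.survival_signals:
            signals["GAME"] = strata.game
        cox_rows = []
        for outcome in config.survival_outcomes:
            fam = []
            for sname, svec in signals.items():
                try:
                    fit = fit_coxph(clinical, svec, outcome=outcome,
                                    signal_name=sname)
                except (ValueError, RuntimeError) as exc:
                    logger.warning("Cox %s/%s skipped: %s", outcome, sname, exc)
                    continue
                row = fit.summary.loc["signal"]
                fam.append({
                    "outcome": outcome, "signal": sname,
                    "beta": row["beta"], "se": row["se"], "p": row["p"],
                    "hazard_pct": row["hazard_pct"], "n": fit.n,
                    "n_events": fit.n_events,
                    "ph_p": (float(fit.ph_test.loc["signal", "p"])
                             if fit.ph_test is not None else np.nan),
                    "dropped": ",".join(fit.dropped_covariates),
                })
            if fam:
                padj = bh_adjust([r["p"] for r in fam])
                for r, pa in zip(fam, padj):
                    r["p_adj"] = float(pa)
                cox_rows.extend(fam)
            # Kaplan-Meier low vs all-other on this outcome
            tcol, ecol = f"{outcome}_time", f"{outcome}_event"
            cdf = clinical.data.dropna(subset=[tcol, ecol])
            cdf = cdf[cdf["sample_id"].isin(strata.table.index)]
            labels = strata.table.loc[cdf["sample_id"], "km_label"].to_numpy()
            try:
                km = km_estimate(cdf[tcol], cdf[ecol], labels)
                stage.setdefault("km", {})[outcome] = {
                    "logrank_p": km.logrank_p, "medians": km.medians,
                    "group_sizes": km.group_sizes}
                pd.concat([c.assign(group=g) for g, c in km.curves.items()]) \
                    .to_csv(out / f"{tag}_km_{outcome}.tsv", sep="\t", index=False)
            except ValueError as exc:
                logger.warning("KM for %s skipped: %s", outcome, exc)
        if cox_rows:
            pd.DataFrame(cox_rows).to_csv(out / f"{tag}_cox.tsv", sep="\t",
                                          index=False)
            stage["cox"] = cox_rows
    return stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write results plus a checksummed JSON manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = cio.read_expression_matrix(config.expression_path, config.expression_unit,
                                   cohort_label=config.cohort_label)
    clinical = (cio.read_clinical_table(config.clinical_path)
                if config.clinical_path else None)
    X_test = (cio.read_expression_matrix(config.test_expression_path,
                                         config.test_expression_unit)
              if config.test_expression_path else None)
    collections = {name: cio.read_gene_sets_gmt(p)
                   for name, p in config.gene_set_paths.items()}
    signature = (pd.read_csv(config.signature_path, sep="\t", index_col=0)
                 if config.signature_path else None)

    splits: dict[str, list[str]] = {"all": list(X.sample_ids)}
    if config.split_by and clinical is not None:
        col = config.split_by
        for val, sub in clinical.data.groupby(col):
            ids = [s for s in sub["sample_id"] if s in set(X.sample_ids)]
            if len(ids) >= 30:
                splits[f"{col}_{val}"] = ids
            else:
                logger.warning("split %s=%s has %d samples; skipped", col, val, len(ids))

    stages = []
    for tag, ids in splits.items():
        Xs = X.subset_samples(ids)
        stages.append(_analyze_cohort(Xs, clinical, config, out, tag, X_test,
                                      collections, signature))
    # overlap of anchor modules across splits
    if len(splits) > 2:
        members = {}
        for st in stages:
            tag = st["cohort"]
            mod = pd.read_csv(out / f"{tag}_modules.tsv", sep="\t", index_col=0)
            mid = st.get("anchor_module", {}).get("id")
            if mid:
                members[tag] = set(mod.index[mod["module"] == mid])
        tags = [t for t in members if t != "all"]
        if len(tags) == 2:
            a, b = tags
            stages.append({"cohort": "split_overlap", "splits": tags,
                           "overlap": len(members[a] & members[b]),
                           "sizes": {a: len(members[a]), b: len(members[b])}})

    net = asdict(config.network)
    manifest = {
        "config": {**{k: v for k, v in asdict(config).items() if k != "network"},
                   "network": net},
        "seed": config.seed,
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.suffix in (".tsv", ".json") and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
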