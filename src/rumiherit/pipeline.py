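"""Configuration-driven end-to-end run.

Stages: simulate (or load) -> prevalence filter -> diversity -> per-ASV
heritability screen -> per-cohort co-occurrence networks -> trait/fermentation
associations -> growth-trait prediction -> aggregated JSON report.  A single
master seed is fanned out deterministically per stage, so identical configs
produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import heritability as her
from . import network as net
from . import predict as pred
from . import synthio, tables

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage thresholds plus simulation settings and the master seed."""

    synth: synthio.SynthParams = field(default_factory=synthio.SynthParams)
    input_dir: str | None = None           # load instead of simulate
    prevalence_min: float = 0.05
    rarefaction_depth: int = 10_000
    rarefy: bool = True
    pseudocount: float = 1e-6
    h2_min: float = 0.2
    h2_p_max: float = 0.05
    sparcc_r: float = 0.5
    sparcc_p: float = 0.01
    sparcc_prevalence: float = 0.20
    sparcc_boot: int = 100
    assoc_prevalence: float = 0.5
    assoc_alpha: float = 0.05
    group_fraction: float = 0.25
    cv_folds: int = 7
    train_fraction: float = 0.7
    predict_traits: tuple = ("WW",)
    predict_sources: tuple = ("dam", "both")
    run_network: bool = True
    run_assoc: bool = True
    run_predict: bool = True
    rfc_small_grid: bool = True
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 < self.prevalence_min <= 1, "prevalence_min in (0,1]"),
            (self.rarefaction_depth >= 1, "rarefaction_depth >= 1"),
            (0 <= self.h2_min < 1, "h2_min in [0,1)"),
            (0 < self.h2_p_max <= 1, "h2_p_max in (0,1]"),
            (0 <= self.sparcc_r <= 1, "sparcc_r in [0,1]"),
            (0 < self.sparcc_p <= 1, "sparcc_p in (0,1]"),
            (0 <= self.sparcc_prevalence < 1, "sparcc_prevalence in [0,1)"),
            (0 < self.assoc_prevalence <= 1, "assoc_prevalence in (0,1]"),
            (0 < self.assoc_alpha <= 1, "assoc_alpha in (0,1]"),
            (0 < self.group_fraction <= 0.5, "group_fraction in (0,0.5]"),
            (self.cv_folds >= 2, "cv_folds >= 2"),
            (0 < self.train_fraction < 1, "train_fraction in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")


def _stage_seeds(master: int, n: int = 12) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute all stages and return (and optionally write) the run report."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"schema_version": 1, "seed": config.seed, "stages": {}}

    # --- stage 1: data -----------------------------------------------------
    if config.input_dir is None:
        params = dataclasses.replace(config.synth, seed=seeds[0])
        pop = synthio.simulate_population(params)
        report["stages"]["data"] = {"mode": "simulated",
                                    "n_dams": params.n_dams,
                                    "n_asvs": params.n_asvs}
    else:
        d = Path(config.input_dir)
        table = tables.read_asv_table(d / "asv_table.tsv", d / "taxonomy.tsv")
        meta = pd.read_csv(d / "metadata.tsv", sep="\t", index_col=0)
        ped = her.load_pedigree(d / "pedigree.csv")
        pop = {"table": table, "metadata": meta, "pedigree": ped,
               "causal_asvs": []}
        report["stages"]["data"] = {"mode": "loaded", "input_dir": str(d)}
    table: tables.AsvTable = pop["table"]
    meta: pd.DataFrame = pop["metadata"]
    ped: her.Pedigree = pop["pedigree"]
    report["stages"]["data"]["n_samples"] = table.shape[0]

    # --- stage 2: filter / diversity ---------------------------------------
    if config.rarefy:
        table = tables.rarefy(table, config.rarefaction_depth, seed=seeds[1])
        meta = meta.loc[table.sample_ids]
    filtered = tables.filter_prevalence(table, config.prevalence_min)
    alpha = tables.alpha_diversity(filtered)
    groups = meta["group"]
    bc = tables.beta_dissimilarity(filtered, "bray_curtis")
    f_stat, perm_p = tables.permanova(bc, groups.to_numpy(), n_perm=999,
                                      seed=seeds[2])
    venn = tables.group_presence_summary(filtered, groups)
    report["stages"]["tables"] = {
        "n_prevalent_asvs": filtered.shape[1],
        "alpha_mean": {g: {m: float(alpha.loc[groups == g, m].mean())
                           for m in ("chao1", "shannon", "evenness")}
                       for g in sorted(groups.unique())},
        "permanova": {"pseudo_F": float(f_stat), "p": float(perm_p)},
        "venn": venn,
    }
    if out is not None:
        tables.write_asv_table(filtered, out / "filtered_table.tsv")
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")

    # --- stage 3: heritability ---------------------------------------------
    props = tables.relative_abundance(filtered)
    log_abund = tables.log_transform(props, config.pseudocount)
    results = her.fit_asv_heritability(log_abund, meta, ped,
                                       config.h2_min, config.h2_p_max)
    screen = her.screen_heritable(results, filtered, meta,
                                  config.h2_min, config.h2_p_max)
    heritable = screen["heritable_asvs"]
    report["stages"]["heritability"] = {
        k: v for k, v in screen.items() if k != "heritable_asvs"}
    report["stages"]["heritability"]["h2_range_heritable"] = (
        [float(results.loc[heritable, "h2"].min()),
         float(results.loc[heritable, "h2"].max())] if heritable else None)
    if config.input_dir is None:
        # recovery of the planted heritable set (simulation mode only)
        truth_h2 = dict(zip([f"ASV{j+1}" for j in range(config.synth.n_asvs)],
                            _true_h2(config.synth)))
        planted = {a for a in filtered.asv_ids if truth_h2.get(a, 0) > config.h2_min}
        nulls = {a for a in filtered.asv_ids if truth_h2.get(a, 0) <= config.h2_min}
        hset = set(heritable)
        report["stages"]["heritability"]["planted_recovery"] = {
            "n_planted": len(planted),
            "sensitivity": (len(planted & hset) / len(planted)) if planted else None,
            "false_positive_rate": (len(nulls & hset) / len(nulls)) if nulls else None,
        }
    if out is not None:
        results.to_csv(out / "heritability.tsv", sep="\t")

    # --- stage 4: networks --------------------------------------------------
    if config.run_network:
        nets = {}
        for g in sorted(groups.unique()):
            sub = filtered.subset_samples(meta.index[groups == g])
            prev = (sub.counts > 0).mean(axis=0)
            eligible = prev.index[prev > config.sparcc_prevalence]
            if len(eligible) < 3:
                nets[g] = {"skipped": "fewer than 3 eligible ASVs"}
                continue
            sub = sub.subset_asvs(eligible)
            sp = net.sparcc(sub)
            net.sparcc_pvalues(sub, sp, n_boot=config.sparcc_boot, seed=seeds[3])
            node_meta = pd.DataFrame({
                "abundance": tables.relative_abundance(sub).mean(axis=0),
                "family": [_family(sub.taxonomy.get(a, "")) for a in sub.asv_ids],
                "heritable": [a in set(heritable) for a in sub.asv_ids]})
            graph = net.build_network(sp, node_meta,
                                      prevalence=prev,
                                      r_threshold=config.sparcc_r,
                                      p_threshold=config.sparcc_p,
                                      prevalence_min=config.sparcc_prevalence)
            if graph.number_of_nodes() == 0:
                nets[g] = {"n_nodes": 0, "n_edges": 0}
                continue
            stats = net.network_stats(graph)
            clusters = net.mcode(graph)
            nets[g] = {
                "n_nodes": stats.n_nodes, "n_edges": stats.n_edges,
                "clustering_coefficient": stats.clustering_coefficient,
                "average_degree": stats.average_degree,
                "density": stats.density,
                "hubs": stats.hubs, "keystones": stats.keystones,
                "n_clusters": len(clusters),
                "top_cluster_score": clusters[0].score if clusters else None,
            }
            if out is not None:
                net.export_graphml(graph, out / f"network_{g}.graphml")
        report["stages"]["network"] = nets

    # --- stage 5: associations ----------------------------------------------
    if config.run_assoc:
        asvs = assoc_mod.select_assoc_asvs(filtered, meta,
                                           config.assoc_prevalence)
        edges = assoc_mod.spearman_matrix(log_abund, meta, asvs=asvs)
        sig = assoc_mod.adjust_edges(edges, alpha=config.assoc_alpha)
        summary = assoc_mod.assoc_summary(sig, heritable_asvs=heritable)
        report["stages"]["assoc"] = {
            "n_candidate_asvs": len(asvs),
            "n_tests": len(edges),
            "n_significant": len(sig),
            "summary": summary,
        }
        if out is not None and sig:
            assoc_mod.edges_to_frame(sig, heritable).to_csv(
                out / "associations.tsv", sep="\t", index=False)

    # --- stage 6: prediction --------------------------------------------------
    if config.run_predict:
        cfg = (pred.small_rfc_config(seeds[4]) if config.rfc_small_grid
               else pred.RfcConfig(seed=seeds[4]))
        cfg.n_folds = config.cv_folds
        predictions = {}
        for trait in config.predict_traits:
            labels = pred.make_groups(meta, trait, config.group_fraction)
            for source in config.predict_sources:
                X, y = pred.build_features(log_abund, meta, labels, source)
                if y.nunique() < 2:
                    continue
                model = pred.train_rfc(X, y, cfg)
                rep = pred.evaluate(model, X, y, seed=seeds[5], trait=trait,
                                    source=source,
                                    test_size=1 - config.train_fraction)
                predictions[f"{trait}/{source}"] = {
                    "cv_accuracy": rep.cv_accuracy, "auc": rep.auc,
                    "n_labeled": rep.n_samples,
                    "hyperparameters": rep.hyperparameters,
                    "cohort_importance": rep.cohort_importance,
                }
        report["stages"]["predict"] = predictions

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
    return report


def _true_h2(params: synthio.SynthParams) -> np.ndarray:
    sa2, sm2, se2 = params.variance_arrays()
    tot = sa2 + sm2 + se2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, sa2 / tot, 0.0)


def _family(lineage: str) -> str:
    parts = [t.strip() for t in lineage.split(";")]
    return parts[4] if len(parts) > 4 and parts[4] else "unclassified"
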