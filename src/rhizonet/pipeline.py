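"""End-to-end orchestration of the analysis chain.

``run_pipeline`` takes an :class:`AnalysisConfig`, loads (or simulates)
community table + sample frame + phylogeny, and emits every report of the
chain per plant-by-year group: alpha diversity, PCoA, PERMANOVA/MRPP,
shared/unique taxon partitions, co-occurrence networks with topology and
rewired-null comparisons, robustness/vulnerability, Levins Bcom, pNST, AVD,
Mantel tests and the stochasticity regressions. A manifest records package
version, every stage's seed, design-decision flags and per-stage status;
a stage failure preserves partial results and marks the stage failed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import CommunityTable, SOIL_VARS, group_labels
from . import assembly, covariates, diversity, io, network, stability, synthetic

log = logging.getLogger("rhizonet")


@dataclass
class AnalysisConfig:
    """Every knob of the pipeline, JSON round-trippable.

    With ``table_path`` unset the synthetic generator supplies the inputs
    using the design fields below.
    """

    output_dir: str = "results/pipeline"
    # input files (optional; synthetic design used when absent)
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    # synthetic design
    n_taxa: int = 200
    reads_per_sample: int = 5000
    regime_mode: str = "neutral"
    filter_strength: float = 0.0
    dispersal: float = 0.01
    # analysis knobs
    group_by: tuple[str, ...] = ("plant", "year")
    correlation_threshold: float | str = 0.90
    min_prevalence: float = 0.5
    n_null_networks: int = 100
    rewires_per_edge: int = 10
    n_nst_nulls: int = 100
    n_permutations: int = 999
    removal_fraction: float = 0.5
    robustness_replicates: int = 100
    seed: int = 0
    # stages to run (None = all); "inputs" always runs
    stages: tuple[str, ...] | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        if "group_by" in data:
            data["group_by"] = tuple(data["group_by"])
        if data.get("stages") is not None:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "network_null", "robustness", "pnst", "permutation", "bootstrap"]
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31 - 1)) for n, s in zip(names, ss)}


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full chain; returns the manifest dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "design_decisions": {
            "shannon_log_base": "e",
            "faith_pd": "rooted (includes root-to-subtree path)",
            "gd_scope": "connected pairs only",
            "modularity_algorithm": "greedy (Clauset-Newman-Moore)",
            "robustness_definition": "fraction of surviving nodes with degree >= 1",
            "betamntd_abundance_weighted": True,
            "nst_null_model": "taxa_shuffle",
            "avd_denominator": "taxa with positive within-group sd",
            "correlation_input": "relative abundances, no rarefaction",
        },
        "stages": {},
    }

    def _json_default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    enabled = set(config.stages) if config.stages is not None else None

    def stage(name):
        def deco(fn):
            if name != "inputs" and enabled is not None and name not in enabled:
                manifest["stages"][name] = {"status": "skipped"}
                return
            try:
                fn()
                manifest["stages"][name] = {"status": "ok"}
            except Exception as exc:  # preserve partial results
                log.error("stage %s failed: %s", name, exc)
                manifest["stages"][name] = {
                    "status": "failed",
                    "error": f"{type(exc).__name__}: {exc}",
                    "traceback": traceback.format_exc(),
                }
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=_json_default)
            )
        return deco

    state: dict = {}

    @stage("inputs")
    def _inputs():
        if config.table_path:
            table, soil, tree = io.read_inputs(
                config.table_path, config.metadata_path, config.tree_path
            )
        else:
            regime = synthetic.AssemblyRegime(
                mode=config.regime_mode,
                filter_strength=config.filter_strength,
                dispersal=config.dispersal,
            )
            table, soil, tree, _meta = synthetic.simulate_dataset(
                n_taxa=config.n_taxa,
                reads_per_sample=config.reads_per_sample,
                regime=regime,
                seed=seeds["simulate"],
            )
            io.write_community_tsv(table, out / "community.tsv")
            io.write_sample_frame(soil, out / "samples.csv")
            io.write_tree(tree, out / "tree.nwk")
        state.update(table=table, soil=soil, tree=tree)
        state["groups"] = group_labels(soil, by=config.group_by)

    if "table" not in state:
        return manifest
    table, soil, tree, groups = state["table"], state["soil"], state["tree"], state["groups"]

    @stage("diversity")
    def _diversity():
        alpha = diversity.alpha_diversity(table, tree)
        alpha.to_csv(out / "alpha_diversity.csv", index_label="sample_id")
        bc = diversity.bray_curtis(table)
        io.write_distance_matrix(bc, out / "bray_curtis.tsv")
        ord_res = diversity.pcoa(bc)
        coords = ord_res.coordinates.copy()
        coords.to_csv(out / "pcoa_coordinates.csv", index_label="sample_id")
        pd.DataFrame(
            {"proportion_explained": ord_res.proportion_explained}
        ).to_csv(out / "pcoa_proportion_explained.csv", index_label="axis")
        rows = []
        for factor in ("plant", "year", "group"):
            labels = groups if factor == "group" else soil[factor].astype(str)
            labels.index = labels.index.astype(str)
            for name, fn in (("permanova", diversity.permanova), ("mrpp", diversity.mrpp)):
                res = fn(bc, labels, n_perm=config.n_permutations, seed=seeds["permutation"])
                rows.append(
                    {
                        "factor": factor,
                        "test": name,
                        "statistic": res.statistic,
                        "effect_A": res.effect,
                        "p_value": res.p_value,
                        "permutations": res.permutations,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "group_tests.csv", index=False)
        state["bray_curtis"] = bc

    @stage("venn")
    def _venn():
        rows = []
        ternary = []
        for plant in soil["plant"].unique():
            sub_ids = soil.index[soil["plant"] == plant]
            sub = table.subset_samples(sub_ids).drop_empty_taxa()
            years = soil.loc[sub_ids, "year"].astype(str).rename("year")
            part = diversity.shared_unique_otus(sub, years)
            for combo, count in sorted(part.counts.items(), key=lambda kv: sorted(kv[0])):
                rows.append(
                    {"plant": plant, "groups": "+".join(sorted(combo)), "n_taxa": count}
                )
            prop = part.proportions.copy()
            prop.insert(0, "plant", plant)
            ternary.append(prop)
        pd.DataFrame(rows).to_csv(out / "venn_counts.csv", index=False)
        pd.concat(ternary).to_csv(out / "ternary_proportions.csv", index_label="taxon_id")

    @stage("networks")
    def _networks():
        rows = []
        robust_rows = []
        vuln_rows = []
        for g in groups.unique():
            sub = table.subset_samples(groups[groups == g].index).drop_empty_taxa()
            corr = network.spearman_matrix(sub, min_prevalence=config.min_prevalence)
            net = network.build_network(corr, threshold=config.correlation_threshold)
            if net.is_empty:
                rows.append({"group": g, "status": "empty", "threshold": net.threshold})
                continue
            io.write_network(
                net, out / "networks" / f"{g}_edges.tsv", out / "networks" / f"{g}.graphml"
            )
            topo = network.topology(net, seed=seeds["network_null"])
            row = {
                "group": g,
                "status": "ok",
                "threshold": net.threshold,
                "n_nodes": topo.n_nodes,
                "n_links": topo.n_links,
                "avgK": topo.avg_k,
                "avgCC": topo.avg_cc,
                "GD": topo.gd,
                "modularity": topo.modularity,
                "module_count": topo.module_count,
            }
            try:
                ens = network.rewire_null(
                    net,
                    n_networks=config.n_null_networks,
                    rewires_per_edge=config.rewires_per_edge,
                    seed=seeds["network_null"],
                )
                comp = network.compare_to_null(topo, ens).set_index("metric")
                for m in ("avg_cc", "gd", "modularity"):
                    row[f"null_mean_{m}"] = comp.loc[m, "null_mean"]
                    row[f"null_p_{m}"] = comp.loc[m, "p_value"]
            except network.CannotRewireError as exc:
                log.warning("group %s: null model unavailable (%s)", g, exc)
                row["status"] = "ok_no_null"
            rows.append(row)
            if topo.n_nodes >= 4:
                rob = stability.robustness(
                    net,
                    removal_fraction=config.removal_fraction,
                    replicates=config.robustness_replicates,
                    seed=seeds["robustness"],
                )
                for k, v in enumerate(rob.values):
                    robust_rows.append({"group": g, "replicate": k, "robustness": v})
            if topo.n_nodes < 3 or topo.n_links < 2:
                log.warning("group %s: too small for vulnerability", g)
                continue
            vuln = stability.vulnerability(net)
            for node, v in vuln.node_vulnerability.items():
                vuln_rows.append(
                    {
                        "group": g,
                        "node": node,
                        "vulnerability": v,
                        "global_efficiency": vuln.global_efficiency,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "network_topology.csv", index=False)
        rob_df = pd.DataFrame(robust_rows)
        rob_df.to_csv(out / "robustness.csv", index=False)
        if len(rob_df):
            summary = (
                rob_df.groupby("group")["robustness"].agg(["mean", "std"]).reset_index()
            )
            summary.to_json(out / "robustness_summary.json", orient="records", indent=2)
        pd.DataFrame(vuln_rows).to_csv(out / "vulnerability.csv", index=False)

    @stage("assembly")
    def _assembly():
        nb = assembly.levins_breadth(table, groups)
        pd.DataFrame(
            [
                {"group": g, "bcom": r.bcom, "n_samples": r.n_samples, "n_taxa": len(r.b_values)}
                for g, r in nb.items()
            ]
        ).to_csv(out / "niche_breadth.csv", index=False)
        nst = assembly.pnst(
            table, tree, groups, n_nulls=config.n_nst_nulls, seed=seeds["pnst"]
        )
        pd.concat(
            [r.pairs.assign(group=g) for g, r in nst.items()], ignore_index=True
        ).to_csv(out / "pnst_pairs.csv", index=False)
        pd.DataFrame(
            [
                {
                    "group": g,
                    "pnst": r.pnst,
                    "pnst_percent": r.pnst_percent,
                    "n_nulls": r.n_nulls,
                    "null_model": r.null_model,
                }
                for g, r in nst.items()
            ]
        ).to_csv(out / "pnst_summary.csv", index=False)
        state["nst"] = nst

    @stage("covariates")
    def _covariates():
        avd_reports = covariates.avd(table, groups)
        pd.concat(
            [
                r.per_sample.rename("avd").to_frame().assign(group=g)
                for g, r in avd_reports.items()
            ]
        ).to_csv(out / "avd.csv", index_label="sample_id")
        # year-1 vs final-year Welch comparisons within each plant
        years = sorted(soil["year"].unique())
        comp_rows = []
        for plant in soil["plant"].unique():
            g1, g4 = f"{plant}_y{years[0]}", f"{plant}_y{years[-1]}"
            if g1 in avd_reports and g4 in avd_reports:
                d = covariates.avd_difference(avd_reports[g1], avd_reports[g4])
                comp_rows.append({"plant": plant, "group_a": g1, "group_b": g4, **d})
        pd.DataFrame(comp_rows).to_csv(out / "avd_comparisons.csv", index=False)

        nutrient = covariates.nutrient_distance(soil, variables=SOIL_VARS)
        io.write_distance_matrix(nutrient, out / "nutrient_distance.tsv")
        mantel_rows = []
        if "bray_curtis" in state:
            m = covariates.mantel(
                state["bray_curtis"], nutrient, n_perm=config.n_permutations,
                seed=seeds["permutation"],
            )
            mantel_rows.append(
                {"pair": "bray_curtis~nutrients", "r": m.r, "p_value": m.p_value,
                 "n_perm": m.n_perm, "flavor": m.flavor}
            )
        per_sample_avd = pd.concat([r.per_sample for r in avd_reports.values()])
        per_sample_avd = per_sample_avd.loc[[s for s in table.sample_ids]]
        from skbio import DistanceMatrix as _DM

        avd_dist = _DM(
            np.abs(per_sample_avd.to_numpy()[:, None] - per_sample_avd.to_numpy()[None, :]),
            ids=list(per_sample_avd.index),
        )
        m = covariates.mantel(
            avd_dist, nutrient, n_perm=config.n_permutations, seed=seeds["permutation"]
        )
        mantel_rows.append(
            {"pair": "avd~nutrients", "r": m.r, "p_value": m.p_value,
             "n_perm": m.n_perm, "flavor": m.flavor}
        )
        pd.DataFrame(mantel_rows).to_csv(out / "mantel.csv", index=False)

        regressions = {}
        if "nst" in state:
            try:
                fit = covariates.pnst_nutrient_regression(state["nst"], nutrient)
                regressions["pnst_vs_nutrient_distance"] = {
                    "slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n,
                    "notes": fit.notes,
                }
            except Exception as exc:
                regressions["pnst_vs_nutrient_distance"] = {"error": str(exc)}
            try:
                fit = covariates.pnst_avd_regression(state["nst"], avd_reports)
                regressions["pnst_vs_avd_difference"] = {
                    "slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n,
                    "notes": fit.notes,
                }
            except Exception as exc:
                regressions["pnst_vs_avd_difference"] = {"error": str(exc)}
        (out / "regressions.json").write_text(json.dumps(regressions, indent=2))

    config.to_json(out / "config.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return manifest
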