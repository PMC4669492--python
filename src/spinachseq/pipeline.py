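"""End-to-end pipeline: simulate -> strand filter -> SNP calling -> tree ->
expression -> differential expression -> report.

Because the pipeline runs on its own synthetic scenario it can score every stage
against the retained ground truth; the run directory receives each stage's outputs
(TSV/FASTA/VCF/newick), a manifest with checksums, the effective configuration,
and a plain-text report. Accessions that break their nominal group's monophyly in
BOTH the SNP tree and the expression dendrogram are flagged as probable
documentation errors and excluded from the diversity counts and the DE
comparisons, mirroring how a mislabeled accession is handled in practice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import diffexpr, expression, genotyping, phylogeny, reporting, strand_filter
from . import synthetic_data as sd

__all__ = ["PipelineResult", "run_pipeline", "flag_misplaced"]

log = logging.getLogger("spinachseq")


@dataclass
class PipelineResult:
    out_dir: Path
    files: dict[str, str]  # relative path -> sha256
    metrics: dict[str, object]
    flagged_accessions: list[str]


def flag_misplaced(contains, groups) -> list[str]:
    """Accessions whose removal restores their nominal group's monophyly.

    ``contains(subset)`` must report whether the accession subset forms a clade /
    cluster. A group that is already monophyletic flags nobody; in a broken group
    of three or more, any member whose remaining co-members do form a clade is
    flagged.
    """
    flagged = []
    for _, members in groups.items():
        members = set(members)
        if contains(members):
            continue
        if len(members) < 3:
            continue
        for acc in sorted(members):
            if contains(members - {acc}):
                flagged.append(acc)
    return sorted(set(flagged))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config: Union[None, str, Path, dict]) -> dict:
    if config is None:
        return {}
    if isinstance(config, dict):
        return dict(config)
    with open(config, "rb") as fh:
        return tomllib.load(fh)


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(
    config: Union[None, str, Path, dict] = None,
    out_dir: Union[str, Path, None] = None,
    seed: Optional[int] = None,
    strict: bool = False,
) -> PipelineResult:
    """Run the full synthetic-scenario pipeline and write all outputs.

    ``config`` is a TOML path or dict with optional sections ``simulation``
    (SimulationConfig fields), ``scenario`` (``mislabel`` bool or full
    SpeciesScenario fields), ``genotyping``, ``phylogeny``, ``expression`` and
    ``de``; ``seed`` overrides the simulation seed. Any stage failure raises with
    the stage name.
    """
    cfg = _load_config(config)
    sim_kwargs = dict(cfg.get("simulation", {}))
    if seed is not None:
        sim_kwargs["seed"] = int(seed)
    if "length_distribution" in sim_kwargs:
        sim_kwargs["length_distribution"] = tuple(sim_kwargs["length_distribution"])
    if "depth_distribution" in sim_kwargs:
        sim_kwargs["depth_distribution"] = tuple(sim_kwargs["depth_distribution"])
    sim = sd.SimulationConfig(**sim_kwargs)

    scen_cfg = dict(cfg.get("scenario", {}))
    if set(scen_cfg) <= {"mislabel"}:
        scenario = sd.default_scenario(mislabel=bool(scen_cfg.get("mislabel", True)))
    else:
        for key in ("species_labels", "accessions_per_species"):
            if key in scen_cfg:
                scen_cfg[key] = tuple(scen_cfg[key])
        if "accession_names" in scen_cfg:
            scen_cfg["accession_names"] = tuple(
                tuple(g) for g in scen_cfg["accession_names"]
            )
        if "mislabel" in scen_cfg and scen_cfg["mislabel"] is not None:
            scen_cfg["mislabel"] = tuple(scen_cfg["mislabel"])
        scenario = sd.SpeciesScenario(**scen_cfg)

    geno_cfg = cfg.get("genotyping", {})
    min_reads = int(geno_cfg.get("min_reads", 3))
    min_freq = float(geno_cfg.get("min_freq", 0.75))
    tree_reps = int(cfg.get("phylogeny", {}).get("replicates", 200))
    expr_cfg = cfg.get("expression", {})
    expr_reps = int(expr_cfg.get("replicates", 200))
    log_transform = bool(expr_cfg.get("log_transform", True))
    de_cfg = cfg.get("de", {})
    fold = float(de_cfg.get("fold", 5.0))
    min_rpkm = float(de_cfg.get("min_rpkm", 5.0))
    alpha = float(de_cfg.get("alpha", 0.05))

    out = Path(out_dir) if out_dir is not None else Path(cfg.get("out_dir", "spinachseq_run"))
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict[str, object] = {}

    # --- simulate ---------------------------------------------------------
    t0 = _stage("simulate")
    catalog = sd.generate_unigenes(sim)
    truth = sd.plant_genotypes(catalog, scenario, sim)
    records, observations = sd.simulate_pileups(truth, sim)
    counts, lib_factors = sd.simulate_counts(truth, scenario, sim)
    strand = sd.simulate_strand_counts(catalog, sim)
    sd.write_fasta(catalog, out / "unigenes.fasta")
    sd.write_truth(truth, out)
    genotyping.write_pileup_tsv(observations, out / "pileup.tsv")
    counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
    log.info("simulate done in %.1fs (%d reads, %d pileup rows)",
             time.perf_counter() - t0, len(records), len(observations))

    # --- strand filter ----------------------------------------------------
    t0 = _stage("filter-strand")
    strand_filter.write_strand_tsv(
        strand[["contig_id", "sense_reads", "antisense_reads"]], out / "strand_counts.tsv"
    )
    kept, discarded = strand_filter.filter_antisense(
        strand[["contig_id", "sense_reads", "antisense_reads"]]
    )
    planted_artifacts = set(strand.loc[strand["is_artifact"], "contig_id"])
    metrics["strand_n_kept"] = len(kept)
    metrics["strand_n_discarded"] = len(discarded)
    metrics["strand_filter_exact"] = discarded == planted_artifacts
    log.info("filter-strand done in %.1fs (%d kept / %d discarded)",
             time.perf_counter() - t0, len(kept), len(discarded))

    # --- SNP calling ------------------------------------------------------
    t0 = _stage("call-snps")
    calls = genotyping.call_genotypes(observations, min_reads=min_reads, min_freq=min_freq)
    snp_table = genotyping.identify_snp_sites(calls)
    genotyping.write_genotype_tsv(snp_table, out / "genotypes.tsv")
    genotyping.write_vcf(snp_table, out / "snps.vcf")

    planted = set(truth.planted_sites)
    identified = set(snp_table.index)
    covered = set(map(tuple, observations[["contig", "pos"]].drop_duplicates().itertuples(index=False)))
    negatives = covered - planted
    metrics["snp_n_identified"] = len(identified)
    metrics["snp_sensitivity"] = len(identified & planted) / len(planted)
    metrics["snp_specificity"] = (
        1.0 - len(identified - planted) / len(negatives) if negatives else 1.0
    )
    log.info("call-snps done in %.1fs (%d SNP sites)",
             time.perf_counter() - t0, len(identified))

    # --- phylogeny --------------------------------------------------------
    t0 = _stage("tree")
    complete_all = genotyping.filter_complete(snp_table, list(scenario.accession_ids))
    metrics["snp_n_complete"] = len(complete_all)
    distances = phylogeny.p_distance_matrix(complete_all)
    phylogeny.write_distance_tsv(distances, out / "distances.tsv")
    tree = phylogeny.bootstrap_tree(complete_all, replicates=tree_reps, seed=sim.seed)
    phylogeny.write_newick(tree, out / "snp_tree.nwk")
    nominal = {sp: set(a) for sp, a in scenario.groups().items()}
    flagged_tree = flag_misplaced(tree.has_clade, nominal)
    log.info("tree done in %.1fs", time.perf_counter() - t0)

    # --- expression -------------------------------------------------------
    t0 = _stage("express")
    gene_lengths = pd.Series(catalog.lengths).reindex(counts.index)
    rpkm_mat = expression.rpkm(counts, gene_lengths)
    rpkm_mat.rename_axis("gene").to_csv(out / "rpkm.tsv", sep="\t")
    corr = expression.pearson_matrix(rpkm_mat, log_transform=log_transform)
    corr.to_csv(out / "correlation.tsv", sep="\t")
    dendro = expression.bootstrap_clusters(
        rpkm_mat, replicates=expr_reps, seed=sim.seed, log_transform=log_transform
    )
    (out / "expression_dendrogram.nwk").write_text(dendro.newick() + "\n")
    flagged_expr = flag_misplaced(dendro.has_cluster, nominal)
    log.info("express done in %.1fs", time.perf_counter() - t0)

    flagged = sorted(set(flagged_tree) & set(flagged_expr))
    metrics["flagged_in_snp_tree"] = flagged_tree
    metrics["flagged_in_dendrogram"] = flagged_expr
    metrics["flagged_accessions"] = flagged

    # --- diversity counts after exclusion ---------------------------------
    retained = [a for a in scenario.accession_ids if a not in flagged]
    complete_retained = genotyping.filter_complete(snp_table, retained)
    groups_retained = {
        sp: [a for a in accs if a not in flagged]
        for sp, accs in scenario.groups().items()
    }
    unions = {
        f"{a}+{b}": (a, b)
        for a, b in itertools.combinations(scenario.species_labels, 2)
    }
    unions["all"] = tuple(scenario.species_labels)
    group_counts = genotyping.count_group_snps(complete_retained, groups_retained, unions)
    group_counts.rename_axis("group").to_csv(out / "group_snp_counts.tsv", sep="\t")
    metrics["group_snp_counts"] = {str(k): int(v) for k, v in group_counts.items()}

    # --- differential expression ------------------------------------------
    t0 = _stage("de")
    dispersion = diffexpr.estimate_common_dispersion(
        counts[retained], {sp: a for sp, a in groups_retained.items() if a}
    )
    metrics["dispersion_estimate"] = dispersion
    comparisons = [
        diffexpr.ComparisonSpec(
            name=f"{a}_vs_{b}",
            group_a=tuple(groups_retained[a]),
            group_b=tuple(groups_retained[b]),
        )
        for a, b in itertools.combinations(scenario.species_labels, 2)
        if groups_retained[a] and groups_retained[b]
    ]
    de_frames = []
    higher_sets: dict[str, set] = {}
    lower_sets: dict[str, set] = {}
    for comp in comparisons:
        table = diffexpr.de_table(counts, comp, dispersion=dispersion)
        classified = diffexpr.classify_highly_de(
            rpkm_mat, table["fdr_q"], comp, fold=fold, min_rpkm=min_rpkm, alpha=alpha
        )
        classified["p_value"] = table["p_value"]
        de_frames.append(classified.reset_index(names="gene"))
        higher_sets[comp.name] = set(
            classified.index[classified["direction"] == "higher_in_A"]
        )
        lower_sets[comp.name] = set(
            classified.index[classified["direction"] == "lower_in_A"]
        )
    de_all = pd.concat(de_frames, ignore_index=True)
    de_all.to_csv(out / "de_results.tsv", sep="\t", index=False)
    metrics["de_higher_counts"] = {k: len(v) for k, v in higher_sets.items()}
    metrics["de_lower_counts"] = {k: len(v) for k, v in lower_sets.items()}

    # --- truth-recovery metrics (available because the scenario is synthetic) --
    true_groups = scenario.groups(true=True)
    supports = {}
    for sp, members in true_groups.items():
        side = tree.canonical_side(frozenset(members))
        if 2 <= len(side) <= len(scenario.accession_ids) - 2:
            supports[sp] = tree.supports.get(side, 0.0)
    metrics["true_group_supports"] = supports
    metrics["true_groups_are_clades_tree"] = all(
        tree.has_clade(set(m)) for m in true_groups.values()
    )
    metrics["true_groups_are_clusters_dendrogram"] = all(
        dendro.has_cluster(set(m)) for m in true_groups.values()
    )
    if scenario.mislabel is not None:
        acc, true_sp = scenario.mislabel
        metrics["mislabel_in_true_clade_tree"] = tree.has_clade(set(true_groups[true_sp]))
        metrics["mislabel_in_true_cluster_dendrogram"] = dendro.has_cluster(
            set(true_groups[true_sp])
        )
        metrics["mislabel_detected"] = acc in flagged

    if truth.planted_de_genes is not None and comparisons:
        comp_species = {
            c.name: tuple(c.name.split("_vs_")) for c in comparisons
        }
        planted_dir: dict[str, set[str]] = {}
        for gene, row in truth.planted_de_genes.iterrows():
            sp, up = row["species"], row["direction"] == "up"
            for cname, (a, b) in comp_species.items():
                if sp == a:
                    planted_dir.setdefault(gene, set()).add(
                        (cname, "higher_in_A" if up else "lower_in_A")
                    )
                elif sp == b:
                    planted_dir.setdefault(gene, set()).add(
                        (cname, "lower_in_A" if up else "higher_in_A")
                    )
        observed: dict[str, set] = {}
        for cname, genes in higher_sets.items():
            for g in genes:
                observed.setdefault(g, set()).add((cname, "higher_in_A"))
        for cname, genes in lower_sets.items():
            for g in genes:
                observed.setdefault(g, set()).add((cname, "lower_in_A"))
        planted_genes = set(planted_dir)
        recovered = sum(
            1
            for g in planted_genes
            if observed.get(g, set()) & planted_dir[g]
        )
        null_genes = set(counts.index) - planted_genes
        false_flagged = sum(1 for g in null_genes if observed.get(g))
        metrics["de_sensitivity"] = recovered / len(planted_genes) if planted_genes else 1.0
        metrics["de_false_flag_rate"] = (
            false_flagged / len(null_genes) if null_genes else 0.0
        )

    venn_rows = []
    for label, sets in (("higher", higher_sets), ("lower", lower_sets)):
        for region, count in diffexpr.venn_counts(sets).items():
            venn_rows.append(
                {"direction": label, "region": "&".join(sorted(region)), "count": count}
            )
    pd.DataFrame(venn_rows).to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    log.info("de done in %.1fs", time.perf_counter() - t0)

    # --- report ------------------------------------------------------------
    t0 = _stage("report")
    accounting = reporting.accounting_table(reporting.load_sequencing_summary(), strict=strict)
    stats = reporting.assembly_stats(out / "unigenes.fasta")
    report_lines = _render_report(
        accounting, stats, group_counts, flagged, metrics, scenario
    )
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")

    effective = {
        "simulation": dataclasses.asdict(sim),
        "scenario": dataclasses.asdict(scenario),
        "genotyping": {"min_reads": min_reads, "min_freq": min_freq},
        "phylogeny": {"replicates": tree_reps},
        "expression": {"replicates": expr_reps, "log_transform": log_transform},
        "de": {"fold": fold, "min_rpkm": min_rpkm, "alpha": alpha},
    }
    (out / "effective_config.json").write_text(json.dumps(effective, indent=2, default=str))

    files = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps({"files": files}, indent=2))
    log.info("report done in %.1fs", time.perf_counter() - t0)

    return PipelineResult(
        out_dir=out, files=files, metrics=metrics, flagged_accessions=flagged
    )


def _render_report(accounting, stats, group_counts, flagged, metrics, scenario):
    def fmt(n):
        return f"{n:,}"

    lines = ["SEQUENCING SUMMARY", ""]
    for _, row in accounting.iterrows():
        lines.append(
            f"  {row['sample_id']:<8} {row['species']:<16} "
            f"raw {fmt(row['raw_reads']):>12}  cleaned {fmt(row['final_cleaned_reads']):>12}"
            + ("" if row["consistent"] else "  [INCONSISTENT]")
        )
    lines += [
        "",
        "ASSEMBLY",
        f"  sequences: {fmt(stats.n_sequences)}   total: {fmt(stats.total_bp)} bp",
        f"  mean length: {round(stats.mean_length_bp)} bp   N50: {fmt(stats.n50_bp)} bp"
        f"   GC: {stats.gc_percent:.1f}%",
        "",
        "STRAND FILTER",
        f"  kept: {fmt(metrics['strand_n_kept'])}   discarded: {fmt(metrics['strand_n_discarded'])}",
        "",
        "SNPS",
        f"  identified: {fmt(metrics['snp_n_identified'])}   "
        f"complete in all accessions: {fmt(metrics['snp_n_complete'])}",
        "  group polymorphism counts (after exclusions):",
    ]
    for name, value in group_counts.items():
        lines.append(f"    {name:<28} {fmt(int(value))}")
    lines += ["", "ACCESSION PLACEMENT"]
    if flagged:
        for acc in flagged:
            lines.append(
                f"  {acc} (nominal {scenario.nominal_species[acc]}) clusters outside its "
                "nominal group in both the SNP tree and the expression dendrogram; "
                "excluded from diversity and DE summaries."
            )
    else:
        lines.append("  all accessions cluster within their nominal species groups")
    lines += ["", "HIGHLY DIFFERENTIALLY EXPRESSED GENES"]
    for comp, n in metrics["de_higher_counts"].items():
        lines.append(f"  {comp}: {n} higher, {metrics['de_lower_counts'][comp]} lower")
    return lines
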