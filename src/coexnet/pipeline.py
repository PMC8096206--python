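"""End-to-end two-phenotype run driven by a single YAML config.

Stages: simulate (or load) inputs -> per-group network inference -> cis
fraction curves and score histograms -> community detection and profiles ->
differential expression -> term and CNA-peak overrepresentation -> regulon /
CTCF genomic context -> summary report plus a manifest of artifact hashes.
Every stage draws from seeds recorded in the manifest, and a rerun with the
same config produces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communities as comm_mod
from . import context as ctx_mod
from . import diffexpr, enrichment, inference, io, simulate
from .datatypes import CoexpressionNetwork, ExpressionStudy, IntervalTrack, PromoterWindow, RegulonMap

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "groups": {"ref": "healthy", "alt": "tumor"},
    "inference": {"measure": "mi", "top_k": 5000, "p_cut": None, "n_permutations": 0},
    "communities": {"algorithm": "louvain", "all_algorithms": False},
    "de": {"moderated": True, "lfc_cut": 0.5, "p_cut": 0.05},
    "enrichment": {"alpha": 0.005, "min_term": 10, "min_community": 5, "cna_alpha": 0.05},
    "context": {"ctcf_flank": 50_000, "ctcf_promoter": [1000, 500]},
    "curves": {"k_grid": [1000, 5000, 10000]},
    "histogram_bins": 50,
}


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_inputs(cfg: dict, outdir: Path) -> dict:
    """Generate the full synthetic input bundle and write it under inputs/."""
    sim = cfg.get("simulate") or {}
    seed = int(cfg["seed"])
    genome = simulate.default_genome(n_genes=int(sim.get("n_genes", 600)))
    annotation, study_cfg = simulate.loss_of_trans_configs(
        genome=genome,
        seed=seed,
        n_modules=int(sim.get("n_modules", 8)),
        genes_per_module=int(sim.get("genes_per_module", 15)),
        strong=float(sim.get("strong", 0.9)),
        weak=float(sim.get("weak", 0.25)),
        noise_sd=float(sim.get("noise_sd", 0.3)),
        n_samples_per_group=sim.get("n_samples", {"healthy": 113, "tumor": 217}),
    )
    study = simulate.generate_expression(study_cfg, annotation)

    tumor_modules = study_cfg.modules["tumor"]
    cis_mods = [m for m in tumor_modules if m.kind == "cis"]
    trans_mods = [m for m in tumor_modules if m.kind == "trans"]
    terms = simulate.generate_term_sets(
        annotation,
        tumor_modules,
        n_terms=int(sim.get("n_terms", 24)),
        seed=seed + 10,
    )
    regulons, _ = simulate.generate_regulons(
        annotation,
        trans_mods,
        n_tfs=int(sim.get("n_tfs", 3)),
        targets_per_tf=int(sim.get("targets_per_tf", 10)),
        seed=seed + 11,
    )
    cis_spans = []
    ann_ix = annotation.set_index("gene")
    for m in cis_mods:
        sub = ann_ix.loc[list(m.gene_ids)]
        cis_spans.append((sub["chrom"].iloc[0], int(sub["start"].min()), int(sub["end"].max())))
    ctcf = simulate.generate_peak_track(
        annotation, int(sim.get("n_ctcf_peaks", 400)), "uniform", seed=seed + 12
    )
    del_targets = [g for m in cis_mods[: max(1, len(cis_mods) // 2)] for g in m.gene_ids]
    deletions = simulate.generate_peak_track(
        annotation, len(del_targets), "gene_spanning", seed=seed + 13, target_genes=del_targets
    )
    amp_targets = [g for m in trans_mods[:1] for g in m.gene_ids[:5]]
    amplifications = simulate.generate_peak_track(
        annotation, len(amp_targets), "gene_spanning", seed=seed + 14, target_genes=amp_targets
    )

    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    io.write_expression(study, inputs_dir / "expression.tsv")
    io.write_phenotype(study, inputs_dir / "phenotype.tsv")
    io.write_annotation(annotation, inputs_dir / "annotation.tsv")
    io.write_gmt(terms, inputs_dir / "terms.gmt")
    io.write_regulons(regulons, inputs_dir / "regulons.tsv")
    io.write_bed(ctcf, inputs_dir / "ctcf.bed")
    io.write_bed(deletions, inputs_dir / "deletion_peaks.bed")
    io.write_bed(amplifications, inputs_dir / "amplification_peaks.bed")
    return {
        "study": study,
        "annotation": annotation,
        "terms": terms,
        "regulons": regulons,
        "ctcf": ctcf,
        "deletions": deletions,
        "amplifications": amplifications,
    }


def _load_inputs(cfg: dict) -> dict:
    paths = cfg["inputs"]
    study = io.read_expression(paths["expression"], paths["phenotype"])
    annotation = io.read_annotation(paths["annotation"])
    out = {"study": study, "annotation": annotation}
    out["terms"] = io.read_gmt(paths["terms"]) if "terms" in paths else {}
    out["regulons"] = (
        io.read_regulons(paths["regulons"]) if "regulons" in paths else RegulonMap()
    )
    for key, name in (
        ("ctcf", "ctcf_peaks"),
        ("deletions", "deletion_peaks"),
        ("amplifications", "amplification_peaks"),
    ):
        out[key] = io.read_bed(paths[name]) if name in paths else IntervalTrack(
            pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        )
    return out


def run_pipeline(cfg: dict, outdir: str | os.PathLike) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    cfg = merge_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    data = _load_inputs(cfg) if "inputs" in cfg else _simulate_inputs(cfg, outdir)
    study: ExpressionStudy = data["study"]
    annotation = data["annotation"]
    ref, alt = cfg["groups"]["ref"], cfg["groups"]["alt"]

    inf_cfg = cfg["inference"]
    micfg = inference.MIEstimatorConfig(seed=seed)
    report: dict = {"groups": {"ref": ref, "alt": alt}, "per_group": {}}
    networks: dict[str, CoexpressionNetwork] = {}
    full_networks: dict[str, CoexpressionNetwork] = {}
    for group in (ref, alt):
        full = inference.build_network(
            study,
            group,
            annotation=annotation,
            measure=inf_cfg["measure"],
            cfg=micfg,
            p_cut=inf_cfg.get("p_cut"),
            n_permutations=inf_cfg.get("n_permutations") or None,
        )
        full_networks[group] = full
        k_grid = [k for k in cfg["curves"]["k_grid"] if k <= len(full)] or [len(full)]
        curve = inference.cis_fraction_curve(full, k_grid)
        curve.to_csv(outdir / f"cis_fraction_{group}.tsv", sep="\t", index=False)
        top_k = inf_cfg.get("top_k")
        net = inference.select_top_edges(full, min(top_k, len(full))) if top_k else full
        networks[group] = net
        io.write_network(net, outdir / f"network_{group}.tsv")
        report["per_group"][group] = {
            "n_candidate_edges": len(full),
            "n_edges": len(net),
            "cis_fraction": net.cis_fraction(),
            "cis_fraction_curve": {int(r.k): float(r.cis_fraction) for r in curve.itertuples()},
        }

    for stratum in ("all", "cis", "trans"):
        hist = inference.score_histograms(
            networks[ref], networks[alt], stratify=stratum, n_bins=int(cfg["histogram_bins"])
        )
        hist.to_csv(outdir / f"score_histogram_{stratum}.tsv", sep="\t", index=False)

    de = diffexpr.differential_expression(
        study,
        ref,
        alt,
        moderated=bool(cfg["de"]["moderated"]),
        lfc_cut=float(cfg["de"]["lfc_cut"]),
        p_cut=float(cfg["de"]["p_cut"]),
    )
    de.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)
    report["de"] = {
        "n_over": int((de["call"] == "over").sum()),
        "n_under": int((de["call"] == "under").sum()),
    }

    universe = set(study.gene_ids)
    ecfg = cfg["enrichment"]
    ccfg = cfg["context"]
    algo = cfg["communities"]["algorithm"]
    for group in (ref, alt):
        partition = comm_mod.detect_communities(networks[group], algorithm=algo, seed=seed)
        profiles = comm_mod.community_profiles(partition, networks[group], annotation, de)
        profiles.to_csv(outdir / f"community_profiles_{group}.tsv", sep="\t", index=False)
        io.write_membership(
            comm_mod.membership_table(partition, profiles), outdir / f"communities_{group}.tsv"
        )
        comm_sets = partition.communities()
        enr = enrichment.enrich_communities(
            comm_sets,
            data["terms"],
            universe,
            min_community=int(ecfg["min_community"]),
            min_term=int(ecfg["min_term"]),
            alpha=float(ecfg["alpha"]),
        )
        enr.to_csv(outdir / f"enrichment_{group}.tsv", sep="\t", index=False)
        alluvial = make_alluvial_table(profiles, enr)
        alluvial.to_csv(outdir / f"alluvial_{group}.tsv", sep="\t", index=False)

        with_edges = profiles[profiles["n_internal_edges"] > 0]
        big = profiles[profiles["size"] >= int(ecfg["min_community"])]
        enriched_ids = set(enr.loc[enr["significant"], "community_id"])
        cis_ids = set(profiles.loc[profiles["is_cis"], "community_id"])
        ass = profiles["ass_chr"].dropna()
        g = report["per_group"][group]
        g.update(
            {
                "algorithm": algo,
                "modularity": partition.modularity,
                "n_communities": len(comm_sets),
                "n_communities_cis": int(profiles["is_cis"].sum()),
                "n_communities_trans": int(len(with_edges) - profiles["is_cis"].sum()),
                "n_communities_ge5_cis": int(big["is_cis"].sum()),
                "n_communities_ge5_trans": int((~big["is_cis"]).sum()),
                "n_enriched_cis": len(enriched_ids & cis_ids),
                "n_enriched_trans": len(enriched_ids - cis_ids),
                "ass_chr_mean": float(ass.mean()) if len(ass) else None,
                "ass_dge_mean": float(profiles["ass_dge"].dropna().mean())
                if profiles["ass_dge"].notna().any()
                else None,
            }
        )

        if group == alt:
            peak_sets = {}
            if len(data["amplifications"]):
                peak_sets["amplification"] = ctx_mod.peak_gene_sets(
                    data["amplifications"], annotation
                )
            if len(data["deletions"]):
                peak_sets["deletion"] = ctx_mod.peak_gene_sets(data["deletions"], annotation)
            if peak_sets:
                cna = enrichment.enrich_cna_peaks(
                    comm_sets, peak_sets, universe, alpha=float(ecfg["cna_alpha"])
                )
                cna.to_csv(outdir / "cna_enrichment.tsv", sep="\t", index=False)
                report["cna"] = {
                    "n_significant": int(cna["significant"].sum()) if len(cna) else 0
                }

            reg_rows = []
            for cid, genes in sorted(comm_sets.items()):
                tbl = ctx_mod.annotate_regulatory_edges(genes, networks[group], data["regulons"])
                if len(tbl):
                    tbl.insert(0, "community_id", cid)
                    reg_rows.append(tbl)
            reg = (
                pd.concat(reg_rows, ignore_index=True)
                if reg_rows
                else pd.DataFrame(
                    columns=[
                        "community_id", "tf", "total_degree",
                        "regulatory_degree", "regulated_targets",
                    ]
                )
            )
            reg.to_csv(outdir / "regulatory_edges.tsv", sep="\t", index=False)

            if len(data["ctcf"]):
                up, down = ccfg["ctcf_promoter"]
                counts, _ = ctx_mod.classify_ctcf_sites(
                    data["ctcf"], annotation, PromoterWindow(int(up), int(down))
                )
                cis_profiles = {
                    int(r.community_id): comm_sets[int(r.community_id)]
                    for r in profiles.itertuples()
                    if r.is_cis
                }
                boundary = ctx_mod.ctcf_boundary_analysis(
                    cis_profiles, data["ctcf"], annotation, flank=int(ccfg["ctcf_flank"])
                )
                boundary.to_csv(outdir / "ctcf_boundaries.tsv", sep="\t", index=False)
                with_peaks = boundary[boundary["has_peaks"]] if len(boundary) else boundary
                report["ctcf"] = {
                    "site_classes": counts,
                    "n_cis_communities": len(boundary),
                    "n_with_peaks": int(len(with_peaks)),
                    "n_boundary_excess": int(with_peaks["boundary_excess"].sum())
                    if len(with_peaks)
                    else 0,
                }

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    manifest = {
        "seed": seed,
        "config": cfg,
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def make_alluvial_table(profiles: pd.DataFrame, enrichment_records: pd.DataFrame) -> pd.DataFrame:
    """Community -> (cis/trans type, significant term count) backing table."""
    sig = enrichment_records[enrichment_records["significant"]] if len(enrichment_records) else enrichment_records
    counts = sig.groupby("community_id").size() if len(sig) else pd.Series(dtype=int)
    rows = []
    for r in profiles.itertuples():
        rows.append(
            {
                "community_id": r.community_id,
                "name": r.name,
                "type": "cis" if r.is_cis else "trans",
                "size": r.size,
                "n_significant_terms": int(counts.get(r.community_id, 0)),
            }
        )
    return pd.DataFrame(rows)
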