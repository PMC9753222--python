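"""End-to-end orchestration of the analysis stages over a study bundle.

`run_all` drives every stage in order — identification, classification,
differential expression, clustering, neighbor pairs, ceRNA discovery and
the duplex screen — and writes one TSV per stage plus the effective
configuration. All outputs are deterministically ordered, so a fixed seed
reproduces the bundle and every downstream file byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import cerna, classify, duplex, dynamics, identify, pairs
from .io_formats import write_gtf, write_table
from .synthetic import SimBundle, SimulationConfig, simulate_bundle, write_bundle

__all__ = ["PipelineConfig", "run_all", "load_bundle_dir",
           "simulate_and_run"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds; defaults are the reference operating points."""

    window_bp: int = 1000
    min_length_nt: int = 150
    min_tpmmax: float = 1.0
    rrs_threshold: float = 0.9
    ribo_min_coverage: float = 1.0
    log2fc_min: float = 1.0
    padj_max: float = 0.05
    n_clusters: int = 6
    cluster_seed: int = 0
    alp_pcc_threshold: float = 0.7
    n_random_pairs: int = 100
    cerna_p_max: float = 0.05
    cerna_pcc_min: float = 0.7
    duplex_pcc_min: float = 0.9

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_all(bundle: SimBundle, outdir, config: PipelineConfig | None = None,
            seed: int = 0) -> dict:
    """Run every analysis stage on a bundle; returns a summary dict."""
    cfg = config or PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)

    with open(j("config_used.yaml"), "w") as fh:
        yaml.safe_dump({"seed": seed, **asdict(cfg)}, fh, sort_keys=True)

    ann = bundle.annotation
    truth = bundle.truth
    expr = bundle.expr
    reference = ann.subset([
        t for t in sorted(ann.transcripts)
        if ann.transcripts[t].biotype != "novel"
    ])

    # 1. identification
    lncrnas, report = identify.run_identification(
        ann, reference, expr, bundle.sequences
    )
    write_gtf(lncrnas, j("lncrnas.gtf"))
    rep_rows = [{"rule": r, "n_removed": report.n_removed_by[r]}
                for r in identify.RULE_ORDER]
    rep_rows.append({"rule": "retained", "n_removed": len(report.retained)})
    write_table(pd.DataFrame(rep_rows), j("filter_report.tsv"))

    lnc_ids = [t for t in report.retained
               if ann.transcripts[t].biotype != "protein_coding"]

    # 2. classification
    cls_rows = []
    for tid in sorted(lnc_ids):
        loc = classify.classify_genomic_location(
            ann.transcripts[tid], ann, cfg.window_bp)
        prof = classify.RiboProfile(tid, bundle.ribo_profiles[tid]) \
            if tid in bundle.ribo_profiles else None
        srna = bundle.srna_counts.get(tid)
        fun = classify.classify_functional(
            tid, prof, srna, bundle.sequences[tid],
            ribo_min=cfg.ribo_min_coverage,
            rrs_threshold=cfg.rrs_threshold)
        cls_rows.append({
            "transcript_id": tid,
            "location": loc.primary,
            "flags": ",".join(sorted(loc.flags)),
            "functional": "+".join(fun.labels),
            "sorf_encoding": fun.sorf_encoding,
            "best_rrs": fun.best_rrs if fun.best_rrs is not None else np.nan,
        })
    classification = pd.DataFrame(cls_rows)
    write_table(classification, j("classification.tsv"))

    # 3. differential expression + AR calling
    de_results, ar_ids, de_summary = dynamics.call_ar_lncrnas(expr, lnc_ids)
    de_df = pd.DataFrame([{
        "transcript_id": r.transcript_id, "contrast": r.contrast,
        "log2fc": r.log2fc, "p": r.p, "p_adj": r.p_adj, "is_AR": r.is_ar,
    } for r in de_results])
    write_table(de_df, j("de_results.tsv"))

    # 4. clustering of AR lncRNAs
    tids, profiles = dynamics.log2fc_profiles(expr, ar_ids)
    if len(tids) >= cfg.n_clusters:
        assignments = dynamics.kmeans_clusters(
            profiles, tids, k=cfg.n_clusters, seed=cfg.cluster_seed)
        clus_df = pd.DataFrame([
            {"transcript_id": a.transcript_id, "cluster": a.cluster}
            for a in assignments
        ])
    else:
        clus_df = pd.DataFrame(columns=["transcript_id", "cluster"])
    write_table(clus_df, j("clusters.tsv"))

    # 5. localization + stress overlap (from the simulated fractions)
    nuc = {t: 100.0 * 2.0 ** lr / (1 + 2.0 ** lr)
           for t, lr in truth.nuclear_logratio.items()}
    cyt = {t: 100.0 - v for t, v in nuc.items()}
    loc_calls = dynamics.localization_enrichment(nuc, cyt)
    loc_ar = {t: c for t, c in loc_calls.items() if t in set(ar_ids)}
    write_table(pd.DataFrame(
        [{"transcript_id": t, "fraction": c}
         for t, c in sorted(loc_ar.items())]
    ), j("localization.tsv"))
    stress = dynamics.stress_overlap(ar_ids, truth.stress_sets)
    write_table(pd.DataFrame(stress), j("stress_overlap.tsv"))

    # 6. neighbor pairs
    all_pairs = pairs.enumerate_pairs(
        ann, ar_ids, expr, window=cfg.window_bp,
        n_random=cfg.n_random_pairs, seed=seed)
    pair_df = pd.DataFrame([{
        "a_id": p.a_id, "b_id": p.b_id, "category": p.category,
        "pcc": p.pcc if p.pcc is not None else np.nan,
    } for p in all_pairs])
    write_table(pair_df, j("pairs.tsv"))
    cat_summary, cat_comp = pairs.compare_categories(all_pairs)
    write_table(cat_summary, j("category_stats.tsv"))
    write_table(cat_comp, j("category_tests.tsv"))
    correlated_alp = pairs.select_correlated_antisense(
        all_pairs, cfg.alp_pcc_threshold)

    # 7. ceRNA sets and network
    sets = cerna.find_cerna_sets(
        bundle.targets, expr, p_max=cfg.cerna_p_max,
        pcc_min=cfg.cerna_pcc_min)
    sets_df = pd.DataFrame([{
        "lncRNA_id": s.lncrna_id, "mRNA_id": s.mrna_id,
        "junction_mirnas": ",".join(sorted(s.junction_mirnas)),
        "p_value": s.p, "pcc": s.pcc,
    } for s in sets])
    write_table(sets_df, j("cerna_sets.tsv"))
    edges, degrees, node_counts = cerna.build_network(sets)
    write_table(edges, j("network_edges.tsv"))
    write_table(degrees, j("network_degrees.tsv"))

    # 8. duplex screen: AR lncRNAs against every coding transcript
    mrna_ids = sorted(
        t.transcript_id for t in ann.by_biotype("protein_coding")
    )
    calls = duplex.screen_and_filter(
        ar_ids, mrna_ids, bundle.sequences, expr,
        pcc_min=cfg.duplex_pcc_min)
    dup_df = pd.DataFrame([{
        "lncRNA_id": c.hit.lnc_id, "mRNA_id": c.hit.mrna_id,
        "lnc_start": c.hit.lnc_interval[0], "lnc_end": c.hit.lnc_interval[1],
        "mrna_start": c.hit.mrna_interval[0],
        "mrna_end": c.hit.mrna_interval[1],
        "paired_length": c.hit.paired_length,
        "energy": c.hit.energy, "pcc": c.pcc,
    } for c in calls])
    write_table(dup_df, j("duplex_hits.tsv"))

    n_nuclear = sum(1 for c in loc_ar.values() if c == "nuclear")
    summary = {
        "n_transcripts": len(ann),
        "n_lncrnas": len(lnc_ids),
        "n_ar_lncrnas": len(ar_ids),
        "n_clustered": int((clus_df["cluster"] != "unclustered").sum())
        if len(clus_df) else 0,
        "n_correlated_alp": len(correlated_alp),
        "n_cerna_sets": len(sets),
        "n_cerna_lncrnas": node_counts["lncRNA"],
        "n_cerna_mirnas": node_counts["miRNA"],
        "n_cerna_mrnas": node_counts["mRNA"],
        "n_duplex_calls": len(calls),
        "n_ar_nuclear": n_nuclear,
        "n_ar_localized": len(loc_ar),
    }
    write_table(pd.DataFrame([summary]), j("summary.tsv"))
    return summary


def load_bundle_dir(path) -> SimBundle:
    """Reconstruct a study bundle from the files `write_bundle` produced."""
    from .cerna import TargetTable
    from .io_formats import read_expression, read_fasta, read_gtf
    from .synthetic import GroundTruth

    j = lambda name: os.path.join(path, name)
    ann = read_gtf(j("annotation.gtf"))
    seqs = read_fasta(j("transcripts.fa"))
    expr = read_expression(j("counts.tsv"), ann)
    truth = GroundTruth()
    tdf = pd.read_csv(j("truth.tsv"), sep="\t")
    for r in tdf.itertuples():
        truth.location_category[r.transcript_id] = r.location_category
        truth.functional_category[r.transcript_id] = r.functional_category
        truth.archetype[r.transcript_id] = r.archetype
        if r.is_ar:
            truth.ar_lncrnas.add(r.transcript_id)
    fdf = pd.read_csv(j("fractions.tsv"), sep="\t")
    for r in fdf.itertuples():
        ratio = max(r.nuclear_tpm, 1e-9) / max(r.cytosolic_tpm, 1e-9)
        truth.nuclear_logratio[r.transcript_id] = float(np.log2(ratio))
    sdf = pd.read_csv(j("stress_sets.tsv"), sep="\t")
    for cond, grp in sdf.groupby("condition"):
        truth.stress_sets[cond] = set(grp.transcript_id)
    truth.sequences = seqs
    rdf = pd.read_csv(j("ribo.tsv"), sep="\t")
    ribo = {
        tid: grp.sort_values("position")["coverage"].to_numpy()
        for tid, grp in rdf.groupby("transcript_id")
    }
    ndf = pd.read_csv(j("srna.tsv"), sep="\t")
    srna = {
        tid: dict(zip(grp.read_length, grp.reads))
        for tid, grp in ndf.groupby("transcript_id")
    }
    targets = TargetTable.from_frame(pd.read_csv(j("targets.tsv"), sep="\t"))
    from .synthetic import SimulationConfig
    return SimBundle(SimulationConfig(), ann, truth, expr, seqs, ribo,
                     srna, targets)


def simulate_and_run(seed: int, outdir,
                     sim_config: SimulationConfig | None = None,
                     config: PipelineConfig | None = None) -> dict:
    """Generate a bundle with *seed*, write it and run the full analysis."""
    bundle = simulate_bundle(sim_config, seed=seed)
    bundle_dir = os.path.join(outdir, "bundle")
    write_bundle(bundle, bundle_dir)
    return run_all(bundle, outdir, config=config, seed=seed)
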