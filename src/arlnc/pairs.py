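"""Neighbor co-expression analysis.

Eight gene-pair categories are enumerated from the annotation geometry —
four protein/protein baselines (APP overlapping, IPP nearest
non-overlapping neighbor, DPP divergent, CPP convergent) and four
AR-lncRNA/protein analogues (ALP antisense host, ILP nearest neighbor of
an intergenic lncRNA, DLP divergent, CLP convergent) — plus seeded random
lncRNA–gene pairs. Each pair carries the Pearson correlation of the two
members' replicate-mean TPM profiles over the whole lifespan, and the
category distributions are compared with two-tailed Mann–Whitney tests.

Pairs are formed at the gene level: a gene's profile is the sum of its
isoforms' replicate-mean TPM, and its span covers all isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import (
    exonic_overlap_bp,
    gap_between,
    is_convergent,
    is_divergent,
    span_overlap_bp,
)
from .io_formats import ExpressionMatrix, GenomeAnnotation, TranscriptModel

__all__ = [
    "NeighborPair",
    "pearson_cc",
    "enumerate_pairs",
    "compare_categories",
    "select_correlated_antisense",
]

CATEGORIES = ("APP", "IPP", "DPP", "CPP", "ALP", "ILP", "DLP", "CLP", "Random")
DEFAULT_WINDOW_BP = 1000


@dataclass(frozen=True)
class NeighborPair:
    a_id: str   # lncRNA (or first gene) id
    b_id: str   # partner gene id
    category: str
    pcc: float | None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown pair category {self.category!r}")


def pearson_cc(x, y) -> float | None:
    """Product-moment correlation; None when either profile is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _gene_units(annotation: GenomeAnnotation, biotype: str):
    """One synthetic 'unit transcript' per gene (merged span, exon union)."""
    units = {}
    for gene_id, tids in sorted(annotation.genes.items()):
        members = [annotation.transcripts[t] for t in tids]
        members = [t for t in members if t.biotype == biotype]
        if not members:
            continue
        exons = sorted({e for t in members for e in t.exons})
        merged = []
        for a, b in exons:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        units[gene_id] = TranscriptModel(
            transcript_id=gene_id, gene_id=gene_id,
            chrom=members[0].chrom, strand=members[0].strand,
            exons=tuple(merged), biotype=biotype,
        )
    return units


def _gene_profile(annotation: GenomeAnnotation, gene_id: str,
                  expr: ExpressionMatrix) -> np.ndarray | None:
    tids = [t for t in annotation.genes.get(gene_id, [])
            if t in expr._index]
    if not tids:
        return None
    return np.sum([expr.mean_tpm_profile(t) for t in tids], axis=0)


def _nearest_neighbor(unit, others):
    """Nearest non-overlapping unit by gap distance; ties break toward the
    smaller start coordinate."""
    best = None
    for other in others:
        if other.transcript_id == unit.transcript_id:
            continue
        gap = gap_between(unit, other)
        if gap is None:
            continue
        key = (gap, other.start, other.transcript_id)
        if best is None or key < best[0]:
            best = (key, other)
    return best[1] if best else None


def enumerate_pairs(annotation: GenomeAnnotation, ar_lncrna_ids,
                    expr: ExpressionMatrix,
                    window: int = DEFAULT_WINDOW_BP,
                    n_random: int = 100, seed: int = 0) -> list[NeighborPair]:
    """Enumerate all category pairs plus seeded random lncRNA–gene pairs.

    A pair appears once per qualifying category (categories are not
    exclusive). Geometry is evaluated on per-gene merged units.
    """
    coding = _gene_units(annotation, "protein_coding")
    lnc_all = {
        tid: annotation.transcripts[tid]
        for tid in sorted(annotation.transcripts)
        if annotation.transcripts[tid].biotype != "protein_coding"
    }
    ar_lnc = {tid: lnc_all[tid] for tid in sorted(ar_lncrna_ids)
              if tid in lnc_all}

    coding_list = [coding[g] for g in sorted(coding)]
    pairs: list[NeighborPair] = []

    def pcc_genes(ga: str, gb: str):
        pa = _gene_profile(annotation, ga, expr)
        pb = _gene_profile(annotation, gb, expr)
        if pa is None or pb is None:
            return None
        return pearson_cc(pa, pb)

    def pcc_lnc_gene(tid: str, gene: str):
        if tid not in expr._index:
            return None
        pb = _gene_profile(annotation, gene, expr)
        if pb is None:
            return None
        return pearson_cc(expr.mean_tpm_profile(tid), pb)

    # protein/protein categories
    seen_app = set()
    for i, ga in enumerate(coding_list):
        for gb in coding_list[i + 1:]:
            if ga.strand != gb.strand and span_overlap_bp(ga, gb) > 0:
                key = (ga.transcript_id, gb.transcript_id)
                if key not in seen_app:
                    seen_app.add(key)
                    pairs.append(NeighborPair(
                        ga.transcript_id, gb.transcript_id, "APP",
                        pcc_genes(ga.transcript_id, gb.transcript_id)))
            if is_divergent(ga, gb, window):
                pairs.append(NeighborPair(
                    ga.transcript_id, gb.transcript_id, "DPP",
                    pcc_genes(ga.transcript_id, gb.transcript_id)))
            if is_convergent(ga, gb, window):
                pairs.append(NeighborPair(
                    ga.transcript_id, gb.transcript_id, "CPP",
                    pcc_genes(ga.transcript_id, gb.transcript_id)))
    seen_ipp = set()
    for ga in coding_list:
        nb = _nearest_neighbor(ga, coding_list)
        if nb is None:
            continue
        key = tuple(sorted((ga.transcript_id, nb.transcript_id)))
        if key in seen_ipp:
            continue
        seen_ipp.add(key)
        pairs.append(NeighborPair(
            key[0], key[1], "IPP", pcc_genes(key[0], key[1])))

    # lncRNA/protein categories (AR-lncRNAs only)
    from .classify import classify_genomic_location

    for tid, lnc in ar_lnc.items():
        label = classify_genomic_location(lnc, annotation, window)
        if label.primary == "antisense":
            for gu in coding_list:
                if gu.strand != lnc.strand and exonic_overlap_bp(lnc, gu) > 0:
                    pairs.append(NeighborPair(
                        tid, gu.transcript_id, "ALP",
                        pcc_lnc_gene(tid, gu.transcript_id)))
        if label.primary == "intergenic":
            nb = _nearest_neighbor(lnc, coding_list)
            if nb is not None:
                pairs.append(NeighborPair(
                    tid, nb.transcript_id, "ILP",
                    pcc_lnc_gene(tid, nb.transcript_id)))
        for gu in coding_list:
            if is_divergent(lnc, gu, window):
                pairs.append(NeighborPair(
                    tid, gu.transcript_id, "DLP",
                    pcc_lnc_gene(tid, gu.transcript_id)))
            if is_convergent(lnc, gu, window):
                pairs.append(NeighborPair(
                    tid, gu.transcript_id, "CLP",
                    pcc_lnc_gene(tid, gu.transcript_id)))

    # random lncRNA-gene pairs (seeded); qualifying-category pairs are not
    # excluded from the random draw
    rng = np.random.default_rng(seed)
    lnc_ids = sorted(lnc_all)
    gene_ids = sorted(coding)
    if lnc_ids and gene_ids:
        for _ in range(n_random):
            tid = lnc_ids[rng.integers(len(lnc_ids))]
            gene = gene_ids[rng.integers(len(gene_ids))]
            pairs.append(NeighborPair(
                tid, gene, "Random", pcc_lnc_gene(tid, gene)))
    return pairs


DEFAULT_COMPARISONS = (
    ("ALP", "APP"), ("ILP", "IPP"), ("DLP", "DPP"), ("CLP", "CPP"),
    ("ALP", "Random"), ("ILP", "Random"), ("DLP", "Random"),
    ("CLP", "Random"), ("APP", "Random"), ("IPP", "Random"),
    ("DPP", "Random"), ("CPP", "Random"),
)


def compare_categories(pairs: list[NeighborPair],
                       comparisons=DEFAULT_COMPARISONS, min_n: int = 3):
    """Category PCC summaries plus pairwise Mann–Whitney two-tailed tests.

    Returns (summary DataFrame, comparison DataFrame). Comparisons with
    fewer than *min_n* pairs on either side are skipped with a warning.
    """
    import warnings

    import pandas as pd

    from .classify import mann_whitney_u

    by_cat: dict[str, list[float]] = {}
    for p in pairs:
        if p.pcc is not None:
            by_cat.setdefault(p.category, []).append(p.pcc)

    summary_rows = []
    for cat in CATEGORIES:
        vals = by_cat.get(cat, [])
        if not vals:
            continue
        q = np.percentile(vals, [25, 50, 75])
        summary_rows.append({
            "category": cat, "n": len(vals),
            "median_pcc": q[1], "q25": q[0], "q75": q[2],
            "mean_pcc": float(np.mean(vals)),
        })
    comp_rows = []
    for a, b in comparisons:
        va, vb = by_cat.get(a, []), by_cat.get(b, [])
        if len(va) < min_n or len(vb) < min_n:
            warnings.warn(f"comparison {a} vs {b} skipped (undersized)")
            continue
        u, pv = mann_whitney_u(va, vb)
        comp_rows.append({
            "category": a, "baseline": b,
            "n_a": len(va), "n_b": len(vb), "U": u, "p_value": pv,
        })
    return pd.DataFrame(summary_rows), pd.DataFrame(comp_rows)


def select_correlated_antisense(pairs: list[NeighborPair],
                                threshold: float = 0.7) -> list[NeighborPair]:
    """ALP pairs with PCC strictly above the threshold, best first."""
    hits = [
        p for p in pairs
        if p.category == "ALP" and p.pcc is not None and p.pcc > threshold
    ]
    return sorted(hits, key=lambda p: (-p.pcc, p.a_id, p.b_id))
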