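"""Synthetic leaf-aging study generator with planted ground truth.

Emulates the study design the pipeline is built for: a compact plant-like
genome annotation with multi-exon protein-coding genes and lncRNA loci of
every genomic-location category; a 4–30 day leaf time course sampled every
two days with two replicates; negative-binomial RNA-seq counts driven by
six temporal archetypes (three up, three down) plus flat background;
ribosome-footprint and small-RNA coverage with planted translated sORFs
and 21–22-nt sRNA precursors; miRNA target tables with planted ceRNA
triplets over a hypergeometric-null background; and transcript sequences
with planted reverse-complementary duplex segments. Every planted signal
is labelled in a :class:`GroundTruth` object so each downstream stage can
be scored against construction.

Distributional choices: counts are negative binomial with a shared
dispersion (default 0.02, a biological CV of ~14% typical of controlled
replicate plant time courses) — the same variance structure the endpoint
Wald test assumes — and the six archetypes are fixed piecewise-linear log2
fold-change trajectories relative to day 4, since no parametric form of
the real expression distributions is available. Nuclear/cytosolic
localization is a two-component log-ratio mixture; stress-responsive sets
partially overlap the planted age-related set.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .identify import compute_tpm
from .io_formats import (
    ExpressionMatrix,
    GenomeAnnotation,
    TranscriptModel,
    reverse_complement,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimBundle",
    "ARCHETYPES",
    "archetype_log2fc",
    "simulate_annotation",
    "simulate_expression",
    "simulate_sequences",
    "simulate_ribo_and_srna",
    "simulate_target_tables",
    "simulate_bundle",
    "write_bundle",
    "identification_fixture",
]

ARCHETYPES = ("U1", "U2", "U3", "D1", "D2", "D3")
LOCATION_CATEGORIES = ("intergenic", "antisense", "intronic",
                       "divergent", "convergent")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 2_000_000
    n_coding_genes: int = 110
    n_coding_pair_blocks: dict = field(default_factory=lambda: {
        "APP": 5, "DPP": 5, "CPP": 5,   # coding/coding baseline pairs
    })
    n_lncrnas_per_category: dict = field(default_factory=lambda: {
        "intergenic": 16, "antisense": 14, "intronic": 8,
        "divergent": 8, "convergent": 8,
    })
    timepoints: tuple = tuple(range(4, 31, 2))
    replicates: int = 2
    archetype_amplitude: float = 3.0   # terminal |log2FC| of planted AR loci
    ar_fraction: float = 0.65          # fraction of lncRNAs planted as AR
    coding_ar_fraction: float = 0.2    # extra coding genes given archetypes
    dispersion: float = 0.02
    library_size_sigma: float = 0.1
    baseline_log_mean: float = np.log(120.0)
    baseline_log_sigma: float = 0.7
    n_mirnas: int = 100
    n_planted_cerna_triplets: int = 8
    junction_size: int = 4
    n_planted_duplex_pairs: int = 6
    duplex_segment_len: int = 20
    n_planted_sorf_lncrnas: int = 8
    n_planted_srna_precursors: int = 8
    n_dual_function: int = 2           # both sORF and sRNA precursor
    novel_fraction: float = 0.6        # lncRNAs reported as unannotated
    nuclear_fraction: float = 0.735    # nuclear-biased mixture weight
    stress_conditions: tuple = ("ABA", "drought", "cold")
    stress_set_size: int = 30
    stress_ar_fraction: float = 0.6

    def validate(self) -> None:
        if any(v < 0 for v in self.n_lncrnas_per_category.values()):
            raise ValueError("lncRNA counts must be >= 0")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        if self.duplex_segment_len < 15:
            raise ValueError(
                "duplex_segment_len below the 15-nt reportable length"
            )
        need = (self.n_lncrnas_per_category.get("divergent", 0)
                + self.n_lncrnas_per_category.get("convergent", 0)
                + self.n_lncrnas_per_category.get("antisense", 0)
                + self.n_lncrnas_per_category.get("intronic", 0)
                + 2 * sum(self.n_coding_pair_blocks.values()))
        if self.n_coding_genes < need:
            raise ValueError(
                f"n_coding_genes={self.n_coding_genes} cannot host "
                f"{need} attached lncRNAs and gene-pair blocks"
            )
        if self.n_mirnas < 5 * self.junction_size:
            raise ValueError("n_mirnas must be >= 5x the junction size")


@dataclass
class GroundTruth:
    """Planted labels; the scoring surface for every downstream stage."""

    location_category: dict = field(default_factory=dict)   # lnc tid -> category
    functional_category: dict = field(default_factory=dict)  # lnc tid -> label
    archetype: dict = field(default_factory=dict)           # tid -> archetype/flat
    ar_lncrnas: set = field(default_factory=set)
    nuclear_logratio: dict = field(default_factory=dict)
    cerna_triplets: list = field(default_factory=list)      # (lnc, junction, mrna)
    duplex_pairs: list = field(default_factory=list)        # dicts with segments
    sorf_coords: dict = field(default_factory=dict)         # tid -> (start, stop)
    stress_sets: dict = field(default_factory=dict)
    sequences: dict = field(default_factory=dict)

    def nuclear_label(self, tid: str) -> str:
        return "nuclear" if self.nuclear_logratio[tid] > 0 else "cytosolic"


@dataclass
class SimBundle:
    """Everything one simulated study produces, in memory."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: GroundTruth
    expr: ExpressionMatrix
    sequences: dict
    ribo_profiles: dict      # lnc tid -> np.ndarray coverage
    srna_counts: dict        # lnc tid -> {length: reads}
    targets: "object"        # cerna.TargetTable

    @property
    def lncrna_ids(self) -> list[str]:
        return sorted(self.truth.location_category)

    @property
    def coding_ids(self) -> list[str]:
        return sorted(
            t.transcript_id
            for t in self.annotation.by_biotype("protein_coding")
        )


# ---------------------------------------------------------------------------
# Archetypes

def archetype_log2fc(name: str, day: float, amplitude: float = 3.0,
                     t0: float = 4.0, t1: float = 30.0) -> float:
    """Piecewise-linear log2FC trajectory relative to the first timepoint.

    U1/D1 change early (complete by ~day 10), U2/D2 ramp through
    maturation (complete by day 18), U3/D3 change late (start ~day 16).
    """
    if name == "flat":
        return 0.0
    direction = 1.0 if name.startswith("U") else -1.0
    phase = name[1]
    if phase == "1":
        a, b = t0, 10.0
    elif phase == "2":
        a, b = t0, 18.0
    else:
        a, b = 16.0, t1
    frac = np.clip((day - a) / (b - a), 0.0, 1.0)
    return float(direction * amplitude * frac)


# ---------------------------------------------------------------------------
# Annotation

def _make_gene(gene_id: str, chrom: str, strand: str, start: int,
               rng: np.random.Generator, n_isoforms: int = 1,
               big_intron: bool = False) -> list[TranscriptModel]:
    """A multi-exon coding gene laid out from *start*; returns isoforms."""
    n_exons = int(rng.integers(2, 6))
    exons = []
    pos = start
    for i in range(n_exons):
        width = int(rng.integers(150, 400))
        exons.append((pos, pos + width))
        pos += width
        if i < n_exons - 1:
            intron = int(rng.integers(700, 1200)) if big_intron and i == 0 \
                else int(rng.integers(200, 800))
            pos += intron
    isoforms = [TranscriptModel(
        f"{gene_id}.1", gene_id, chrom, strand, tuple(exons),
        "protein_coding")]
    if n_isoforms > 1 and n_exons >= 3:
        isoforms.append(TranscriptModel(
            f"{gene_id}.2", gene_id, chrom, strand, tuple(exons[1:]),
            "protein_coding"))
    return isoforms


def simulate_annotation(config: SimulationConfig
                        ) -> tuple[GenomeAnnotation, GroundTruth]:
    """Lay out coding genes and lncRNA loci satisfying each category.

    Placement is block-sequential with generous margins so no arrangement
    arises by accident; every lncRNA placement is post-validated with the
    production classifier and redrawn (bounded retries) if it does not
    recover exactly its intended category.
    """
    from .classify import classify_genomic_location

    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = GenomeAnnotation(
        transcripts={},
        chrom_lengths={
            f"chr{i + 1}": config.chromosome_length
            for i in range(config.n_chromosomes)
        },
    )
    truth = GroundTruth()

    counts = dict(config.n_lncrnas_per_category)
    n_lnc_total = sum(counts.values())
    novel_flags = np.zeros(n_lnc_total, dtype=bool)
    novel_flags[: int(round(config.novel_fraction * n_lnc_total))] = True
    rng.shuffle(novel_flags)

    lnc_serial = 0
    annot_serial = 0

    def lnc_ids():
        nonlocal lnc_serial, annot_serial
        if novel_flags[lnc_serial]:
            tid = f"XLOC_{lnc_serial + 1:06d}"
            biotype = "novel"
        else:
            annot_serial += 1
            tid = f"ATLNC{annot_serial:05d}"
            biotype = "annotated_noncoding"
        lnc_serial += 1
        return tid, f"LOC_{tid}", biotype

    # build placement tasks: attached categories first, then standalone
    tasks = []
    for _ in range(counts.get("divergent", 0)):
        tasks.append("divergent")
    for _ in range(counts.get("convergent", 0)):
        tasks.append("convergent")
    for _ in range(counts.get("antisense", 0)):
        tasks.append("antisense")
    for _ in range(counts.get("intronic", 0)):
        tasks.append("intronic")
    n_attached_genes = len(tasks)
    for kind, n in sorted(config.n_coding_pair_blocks.items()):
        for _ in range(n):
            tasks.append(f"pair_{kind}")
            n_attached_genes += 2
    for _ in range(config.n_coding_genes - n_attached_genes):
        tasks.append("gene_only")
    for _ in range(counts.get("intergenic", 0)):
        tasks.append("intergenic")
    order = rng.permutation(len(tasks))
    tasks = [tasks[i] for i in order]

    cursors = {c: 10_000 for c in ann.chrom_lengths}
    chroms = sorted(ann.chrom_lengths)
    gene_serial = 0
    alternate = ["+", "-"]
    pending_check = []  # (tid, category)

    def place_block(task: str, chrom: str, at: int) -> int:
        nonlocal gene_serial
        if task.startswith("pair_"):
            # two coding genes in a fixed arrangement (APP/DPP/CPP baseline)
            kind = task.split("_", 1)[1]
            gene_serial += 1
            g1 = f"GENE{gene_serial:04d}"
            gene_serial += 1
            g2 = f"GENE{gene_serial:04d}"
            if kind == "APP":
                iso1 = _make_gene(g1, chrom, "+", at, rng)
                span = max(t.end for t in iso1) - at
                iso2 = _make_gene(g2, chrom, "-", at + span // 2, rng)
            elif kind == "DPP":
                iso1 = _make_gene(g1, chrom, "-", at, rng)
                gap = int(rng.integers(100, 800))
                iso2 = _make_gene(g2, chrom, "+",
                                  max(t.end for t in iso1) + gap, rng)
            else:  # CPP
                iso1 = _make_gene(g1, chrom, "+", at, rng)
                gap = int(rng.integers(100, 800))
                iso2 = _make_gene(g2, chrom, "-",
                                  max(t.end for t in iso1) + gap, rng)
            for t in iso1 + iso2:
                ann.add(t)
            return max(t.end for t in iso1 + iso2)

        if task == "intergenic":
            tid, gid, biotype = lnc_ids()
            length = int(rng.integers(200, 600))
            strand = alternate[int(rng.integers(2))]
            t = TranscriptModel(tid, gid, chrom, strand,
                                ((at, at + length),), biotype)
            ann.add(t)
            truth.location_category[tid] = "intergenic"
            pending_check.append((tid, "intergenic"))
            return at + length

        gene_serial += 1
        gid = f"GENE{gene_serial:04d}"
        if task == "divergent":
            gstrand = "-"
        elif task == "convergent":
            gstrand = "+"
        else:
            gstrand = alternate[gene_serial % 2]
        n_iso = 2 if (task == "gene_only" and rng.random() < 0.25) else 1
        isoforms = _make_gene(gid, chrom, gstrand, at, rng, n_iso,
                              big_intron=(task == "intronic"))
        for t in isoforms:
            ann.add(t)
        host = isoforms[0]
        end = max(t.end for t in isoforms)

        if task == "gene_only":
            return end

        tid, lgid, biotype = lnc_ids()
        length = int(rng.integers(200, 500))
        if task == "antisense":
            exon = host.exons[len(host.exons) // 2]
            start = exon[0] + int(rng.integers(0, max(1, exon[1] - exon[0] - 50)))
            lstrand = "-" if host.strand == "+" else "+"
            t = TranscriptModel(tid, lgid, chrom, lstrand,
                                ((start, start + length),), biotype)
            ann.add(t)
            truth.location_category[tid] = "antisense"
            pending_check.append((tid, "antisense"))
            return max(end, start + length)
        if task == "intronic":
            intron = max(host.introns, key=lambda iv: iv[1] - iv[0])
            margin = 15
            avail = intron[1] - intron[0] - 2 * margin
            ilen = min(length, max(60, avail))
            start = intron[0] + margin
            lstrand = alternate[int(rng.integers(2))]
            t = TranscriptModel(tid, lgid, chrom, lstrand,
                                ((start, start + ilen),), biotype)
            ann.add(t)
            truth.location_category[tid] = "intronic"
            pending_check.append((tid, "intronic"))
            return end
        # divergent / convergent: lncRNA downstream of the gene block
        gap = int(rng.integers(100, 800))
        start = end + gap
        lstrand = "+" if task == "divergent" else "-"
        t = TranscriptModel(tid, lgid, chrom, lstrand,
                            ((start, start + length),), biotype)
        ann.add(t)
        truth.location_category[tid] = task
        pending_check.append((tid, task))
        return start + length

    for i, task in enumerate(tasks):
        chrom = chroms[i % len(chroms)]
        at = cursors[chrom]
        end = place_block(task, chrom, at)
        cursors[chrom] = end + int(rng.integers(3000, 6000))
        if cursors[chrom] > ann.chrom_lengths[chrom]:
            raise ValueError(
                "chromosome capacity exceeded; increase chromosome_length"
            )

    # post-validate every planted category against the production classifier
    expected_of = {
        "intergenic": ("intergenic", frozenset()),
        "antisense": ("antisense", None),        # flags unconstrained
        "intronic": ("intronic", frozenset()),
        "divergent": ("intergenic", frozenset({"divergent"})),
        "convergent": ("intergenic", frozenset({"convergent"})),
    }
    for tid, category in pending_check:
        label = classify_genomic_location(ann.transcripts[tid], ann)
        want_primary, want_flags = expected_of[category]
        ok = label.primary == want_primary and (
            want_flags is None or label.flags == want_flags
        )
        if not ok:
            raise AssertionError(
                f"planted {category} lncRNA {tid} classified as "
                f"{label.primary}/{sorted(label.flags)}"
            )

    _assign_archetypes_and_plants(ann, truth, config, rng)
    return ann, truth


def _assign_archetypes_and_plants(ann: GenomeAnnotation, truth: GroundTruth,
                                  config: SimulationConfig,
                                  rng: np.random.Generator) -> None:
    """Choose AR lncRNAs, temporal archetypes, hosts and planted pairs."""
    from .intervals import exonic_overlap_bp

    lnc_ids = sorted(truth.location_category)
    n_ar = int(round(config.ar_fraction * len(lnc_ids)))
    ar = sorted(rng.choice(lnc_ids, size=n_ar, replace=False))
    truth.ar_lncrnas = set(ar)
    for i, tid in enumerate(ar):
        truth.archetype[tid] = ARCHETYPES[i % len(ARCHETYPES)]
    for tid in lnc_ids:
        truth.archetype.setdefault(tid, "flat")

    coding = ann.by_biotype("protein_coding")
    coding_ids = sorted({t.transcript_id for t in coding})
    # antisense hosts co-express with their lncRNA (cis-pair signal)
    for tid in ar:
        if truth.location_category[tid] != "antisense":
            continue
        lnc = ann.transcripts[tid]
        for t in coding:
            if (t.chrom == lnc.chrom and t.strand != lnc.strand
                    and exonic_overlap_bp(lnc, t) > 0):
                truth.archetype[t.transcript_id] = truth.archetype[tid]
    # a slice of free coding genes gets archetypes too
    free = [c for c in coding_ids if c not in truth.archetype]
    n_extra = int(round(config.coding_ar_fraction * len(free)))
    extra = sorted(rng.choice(free, size=n_extra, replace=False))
    for i, cid in enumerate(extra):
        truth.archetype[cid] = ARCHETYPES[i % len(ARCHETYPES)]

    # ceRNA triplets and duplex pairs share archetypes with their partner;
    # partners come from coding genes that are still flat
    ar_pool = list(ar)
    coding_pool = [c for c in coding_ids
                   if c.endswith(".1") and c not in truth.archetype]
    rng.shuffle(coding_pool)
    triplet_lncs = ar_pool[: config.n_planted_cerna_triplets]
    used = 0
    for tid in triplet_lncs:
        mrna = coding_pool[used]
        used += 1
        truth.archetype[mrna] = truth.archetype[tid]
        truth.cerna_triplets.append({"lncrna": tid, "mrna": mrna})
    duplex_lncs = ar_pool[
        config.n_planted_cerna_triplets:
        config.n_planted_cerna_triplets + config.n_planted_duplex_pairs
    ]
    for tid in duplex_lncs:
        mrna = coding_pool[used]
        used += 1
        truth.archetype[mrna] = truth.archetype[tid]
        truth.duplex_pairs.append({"lncrna": tid, "mrna": mrna})
    for cid in coding_ids:
        truth.archetype.setdefault(cid, "flat")

    # functional labels: sORF set and sRNA-precursor set with a small overlap
    pool = [t for t in lnc_ids]
    rng.shuffle(pool)
    n_sorf = config.n_planted_sorf_lncrnas
    n_srna = config.n_planted_srna_precursors
    n_dual = min(config.n_dual_function, n_sorf, n_srna)
    sorf_set = set(pool[:n_sorf])
    srna_set = set(pool[n_sorf - n_dual: n_sorf - n_dual + n_srna])
    for tid in lnc_ids:
        s, r = tid in sorf_set, tid in srna_set
        if s and r:
            truth.functional_category[tid] = "sorf+srna"
        elif s:
            truth.functional_category[tid] = "sorf"
        elif r:
            truth.functional_category[tid] = "srna"
        else:
            truth.functional_category[tid] = "canonical"

    # nuclear/cytosolic mixture over lncRNAs
    for tid in lnc_ids:
        if rng.random() < config.nuclear_fraction:
            truth.nuclear_logratio[tid] = float(rng.normal(2.0, 0.5))
        else:
            truth.nuclear_logratio[tid] = float(rng.normal(-2.0, 0.5))

    # stress sets overlap the AR set
    non_ar = [t for t in lnc_ids if t not in truth.ar_lncrnas]
    for cond in config.stress_conditions:
        size = min(config.stress_set_size, len(lnc_ids))
        n_from_ar = min(int(round(config.stress_ar_fraction * size)), len(ar))
        chosen = set(rng.choice(ar, size=n_from_ar, replace=False))
        n_rest = min(size - n_from_ar, len(non_ar))
        chosen |= set(rng.choice(non_ar, size=n_rest, replace=False))
        truth.stress_sets[cond] = chosen


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(annotation: GenomeAnnotation, truth: GroundTruth,
                        config: SimulationConfig) -> ExpressionMatrix:
    """Negative-binomial counts from archetype-driven means.

    mean(transcript, sample) = baseline * 2^log2FC(archetype, day) *
    library size. Counts are NB with the shared dispersion; TPM is
    recomputed per sample from counts and spliced lengths.
    """
    rng = np.random.default_rng(config.seed + 1)
    tids = sorted(annotation.transcripts)
    samples = [(d, r + 1) for d in config.timepoints
               for r in range(config.replicates)]
    lib = np.exp(rng.normal(0.0, config.library_size_sigma, len(samples)))
    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sigma, len(tids)))
    counts = np.zeros((len(tids), len(samples)), dtype=np.int64)
    alpha = config.dispersion
    for i, tid in enumerate(tids):
        arch = truth.archetype.get(tid, "flat")
        for j, (day, _) in enumerate(samples):
            mu = baseline[i] * 2.0 ** archetype_log2fc(
                arch, day, config.archetype_amplitude,
                config.timepoints[0], config.timepoints[-1],
            ) * lib[j]
            if alpha < 1e-6:
                counts[i, j] = rng.poisson(mu)
            else:
                counts[i, j] = rng.negative_binomial(
                    1.0 / alpha, 1.0 / (1.0 + alpha * mu)
                )
    lengths = np.array([annotation.transcripts[t].length for t in tids])
    tpm = np.column_stack([
        compute_tpm(counts[:, j], lengths) for j in range(len(samples))
    ])
    return ExpressionMatrix(tids, samples, counts, tpm)


# ---------------------------------------------------------------------------
# Sequences, ribosome footprints, sRNA

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def simulate_sequences(annotation: GenomeAnnotation, truth: GroundTruth,
                       config: SimulationConfig) -> dict[str, str]:
    """I.i.d. uniform transcript sequences with planted sORFs and
    reverse-complementary duplex segments (GC fraction >= 0.5)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    nts = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for tid in sorted(annotation.transcripts):
        length = annotation.transcripts[tid].length
        seqs[tid] = "".join(rng.choice(nts, size=length))

    # translated sORFs: ATG + 24 sense codons + TAA, placed in the 5' part
    # of the transcript so the release-score window fits downstream (the
    # shortest generated lncRNA still leaves > 90 nt after the stop)
    sorf_tids = sorted(
        t for t, lab in truth.functional_category.items()
        if lab.startswith("sorf")
    )
    for tid in sorf_tids:
        seq = seqs[tid]
        orf = "ATG" + "".join(
            _NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))]
            for _ in range(24)
        ) + "TAA"
        start = max(3, (len(seq) - len(orf) - 20) // 4)
        start = min(start, len(seq) - len(orf) - 13)
        seq = seq[:start] + orf + seq[start + len(orf):]
        seqs[tid] = seq
        truth.sorf_coords[tid] = (start, start + len(orf) - 3)

    # duplex segments: GC-rich (>= 50%) exact reverse complements
    for pair in truth.duplex_pairs:
        L = config.duplex_segment_len
        while True:
            seg = "".join(rng.choice(
                nts, size=L, p=[0.18, 0.32, 0.32, 0.18]))
            gc = (seg.count("G") + seg.count("C")) / L
            if gc >= 0.5:
                break
        lnc, mrna = pair["lncrna"], pair["mrna"]
        ls, ms = seqs[lnc], seqs[mrna]
        a = int(rng.integers(10, max(11, len(ls) - L - 10)))
        b = int(rng.integers(10, max(11, len(ms) - L - 10)))
        seqs[lnc] = ls[:a] + seg + ls[a + L:]
        seqs[mrna] = ms[:b] + reverse_complement(seg) + ms[b + L:]
        pair["lnc_segment"] = (a, a + L)
        pair["mrna_segment"] = (b, b + L)
        pair["segment"] = seg

    truth.sequences = seqs
    return seqs


def simulate_ribo_and_srna(annotation: GenomeAnnotation, truth: GroundTruth,
                           config: SimulationConfig
                           ) -> tuple[dict, dict]:
    """Footprint coverage and sRNA length histograms for every lncRNA.

    Translated sORFs get ORF footprint density >= 10x the downstream
    density; everything else gets uniform low coverage. Planted precursors
    concentrate >= 50% of their sRNA reads at 21–22 nt over a deep
    library; the rest get shallow length-uniform noise.
    """
    if not truth.sequences:
        raise ValueError("simulate_sequences must run first")
    rng = np.random.default_rng(config.seed + 3)
    ribo: dict[str, np.ndarray] = {}
    srna: dict[str, dict[int, int]] = {}
    for tid in sorted(truth.location_category):
        seq = truth.sequences[tid]
        n = len(seq)
        label = truth.functional_category[tid]
        cov = rng.poisson(0.2, size=n).astype(float)
        if label.startswith("sorf"):
            start, stop = truth.sorf_coords[tid]
            cov[start:stop] += rng.poisson(12.0, size=stop - start)
        ribo[tid] = cov
        if label in ("srna", "sorf+srna"):
            total = 200
            hist = {k: 0 for k in range(18, 27)}
            for k, v in zip((21, 22), (80, 80)):
                hist[k] = v
            rest = total - 160
            for i, k in enumerate(sorted(set(range(18, 27)) - {21, 22})):
                hist[k] = rest // 7 + (1 if i < rest % 7 else 0)
        else:
            depth = int(rng.poisson(9))
            lengths = rng.integers(18, 27, size=depth)
            hist = {k: int((lengths == k).sum()) for k in range(18, 27)}
        srna[tid] = hist
    return ribo, srna


# ---------------------------------------------------------------------------
# Target tables

def simulate_target_tables(truth: GroundTruth, config: SimulationConfig):
    """miRNA target tables with planted junctions over a uniform background.

    Planted triplets share ``junction_size`` miRNAs between their lncRNA
    and mRNA; background targets are drawn uniformly at random so that
    background sharing follows the hypergeometric null by construction.
    """
    from .cerna import TargetTable

    rng = np.random.default_rng(config.seed + 4)
    mirnas = [f"miR{i + 1:04d}" for i in range(config.n_mirnas)]
    edges = set()

    planted_pairs = {(p["lncrna"], p["mrna"]) for p in truth.cerna_triplets}
    for pair in truth.cerna_triplets:
        junction = sorted(
            rng.choice(mirnas, size=config.junction_size, replace=False)
        )
        pair["junction"] = frozenset(junction)
        extra_l = rng.choice(mirnas, size=2, replace=False)
        extra_m = rng.choice(mirnas, size=3, replace=False)
        for m in junction:
            edges.add((m, pair["lncrna"], "lncRNA"))
            edges.add((m, pair["mrna"], "mRNA"))
        for m in extra_l:
            edges.add((m, pair["lncrna"], "lncRNA"))
        for m in extra_m:
            edges.add((m, pair["mrna"], "mRNA"))

    # background: uniform random targets for other lncRNAs / a slice of mRNAs
    lnc_bg = [t for t in sorted(truth.location_category)
              if all(t != a for a, _ in planted_pairs)]
    for tid in lnc_bg:
        k = int(rng.integers(1, 6))
        for m in rng.choice(mirnas, size=k, replace=False):
            edges.add((m, tid, "lncRNA"))
    mrna_bg = sorted({c for c in truth.archetype if c.startswith("GENE")})
    mrna_bg = [m for m in mrna_bg
               if all(m != b for _, b in planted_pairs)][:60]
    for tid in mrna_bg:
        k = int(rng.integers(1, 9))
        for m in rng.choice(mirnas, size=k, replace=False):
            edges.add((m, tid, "mRNA"))
    # make sure the whole universe is represented
    for m in mirnas:
        if not any(e[0] == m for e in edges):
            edges.add((m, mrna_bg[0] if mrna_bg else "GENE0001.1", "mRNA"))
    return TargetTable(edges=edges)


# ---------------------------------------------------------------------------
# Bundles

def simulate_bundle(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SimBundle:
    """Run every generator stage in order and return the full study."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    ann, truth = simulate_annotation(config)
    seqs = simulate_sequences(ann, truth, config)
    expr = simulate_expression(ann, truth, config)
    ribo, srna = simulate_ribo_and_srna(ann, truth, config)
    targets = simulate_target_tables(truth, config)
    return SimBundle(config, ann, truth, expr, seqs, ribo, srna, targets)


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write the complete fixture bundle as plain-text files."""
    import os

    from .io_formats import write_expression, write_fasta, write_gtf

    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    write_gtf(bundle.annotation, j("annotation.gtf"))
    write_fasta(bundle.sequences, j("transcripts.fa"))
    write_expression(bundle.expr, j("counts.tsv"))
    ribo_rows = [
        {"transcript_id": tid, "position": i, "coverage": float(c)}
        for tid in sorted(bundle.ribo_profiles)
        for i, c in enumerate(bundle.ribo_profiles[tid])
    ]
    pd.DataFrame(ribo_rows).to_csv(j("ribo.tsv"), sep="\t", index=False)
    srna_rows = [
        {"transcript_id": tid, "read_length": k, "reads": v}
        for tid in sorted(bundle.srna_counts)
        for k, v in sorted(bundle.srna_counts[tid].items())
    ]
    pd.DataFrame(srna_rows).to_csv(j("srna.tsv"), sep="\t", index=False)
    bundle.targets.to_frame().to_csv(j("targets.tsv"), sep="\t", index=False)
    truth = bundle.truth
    frac_rows = []
    for tid in sorted(truth.nuclear_logratio):
        lr = truth.nuclear_logratio[tid]
        total = 100.0
        nuc = total * 2.0 ** lr / (1.0 + 2.0 ** lr)
        frac_rows.append({
            "transcript_id": tid,
            "nuclear_tpm": nuc,
            "cytosolic_tpm": total - nuc,
        })
    pd.DataFrame(frac_rows).to_csv(j("fractions.tsv"), sep="\t", index=False,
                                   float_format="%.10g")
    stress_rows = [
        {"condition": cond, "transcript_id": tid}
        for cond in sorted(truth.stress_sets)
        for tid in sorted(truth.stress_sets[cond])
    ]
    pd.DataFrame(stress_rows).to_csv(j("stress_sets.tsv"), sep="\t",
                                     index=False)
    truth_rows = []
    for tid in sorted(truth.location_category):
        truth_rows.append({
            "transcript_id": tid,
            "location_category": truth.location_category[tid],
            "functional_category": truth.functional_category[tid],
            "archetype": truth.archetype[tid],
            "is_ar": tid in truth.ar_lncrnas,
            "localization": truth.nuclear_label(tid),
        })
    pd.DataFrame(truth_rows).to_csv(j("truth.tsv"), sep="\t", index=False)
    cer_rows = [
        {"lncrna_id": p["lncrna"], "mrna_id": p["mrna"],
         "junction_mirnas": ",".join(sorted(p["junction"]))}
        for p in bundle.truth.cerna_triplets
    ]
    pd.DataFrame(cer_rows).to_csv(j("truth_cerna.tsv"), sep="\t", index=False)
    dup_rows = [
        {"lncrna_id": p["lncrna"], "mrna_id": p["mrna"],
         "lnc_start": p["lnc_segment"][0], "lnc_end": p["lnc_segment"][1],
         "mrna_start": p["mrna_segment"][0], "mrna_end": p["mrna_segment"][1]}
        for p in bundle.truth.duplex_pairs
    ]
    pd.DataFrame(dup_rows).to_csv(j("truth_duplex.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Identification demo fixture

def identification_fixture():
    """A deterministic 20-candidate identification fixture.

    Engineered so the cascade removes exactly 3 (annotated coding),
    4 (class code), 2 (short), 2 (low abundance) and 1 (coding potential)
    and retains 8 lncRNAs (3 annotated + 5 novel). Returns
    (candidates, reference, expr, sequences).
    """
    rng = np.random.default_rng(42)
    nts = np.array(list("ACGT"))
    chrom_len = 500_000
    reference = GenomeAnnotation(transcripts={},
                                 chrom_lengths={"chr1": chrom_len})
    candidates = GenomeAnnotation(transcripts={},
                                  chrom_lengths={"chr1": chrom_len})

    # reference genes: coding (multi-exon) and annotated noncoding
    ref_coding = []
    pos = 5_000
    for i in range(6):
        exons = ((pos, pos + 300), (pos + 800, pos + 1_100),
                 (pos + 1_600, pos + 2_000))
        t = TranscriptModel(f"AT1G{i:05d}.1", f"AT1G{i:05d}", "chr1",
                            "+" if i % 2 == 0 else "-", exons,
                            "protein_coding")
        reference.add(t)
        ref_coding.append(t)
        pos += 10_000
    ref_nc = []
    for i in range(3):
        t = TranscriptModel(f"ATNC{i:05d}.1", f"ATNC{i:05d}", "chr1", "+",
                            ((pos, pos + 400),), "annotated_noncoding")
        reference.add(t)
        ref_nc.append(t)
        pos += 10_000

    seqs: dict[str, str] = {}
    tpmmax_low: set[str] = set()

    def rand_seq(n):
        # engineered-noncoding: redraw the rare random sequence that the
        # coding-potential stand-in would flag
        from .identify import coding_potential_score

        while True:
            s = "".join(rng.choice(nts, size=n))
            if not coding_potential_score(s)[1]:
                return s

    def add(tid, exons, strand="+", seq=None, low=False):
        t = TranscriptModel(tid, f"L_{tid}", "chr1", strand, exons, "novel")
        candidates.add(t)
        seqs[tid] = seq if seq is not None else rand_seq(t.length)
        if low:
            tpmmax_low.add(tid)

    # 3 removed as annotated coding (identical intron chains)
    for i in range(3):
        host = ref_coding[i]
        add(f"XLOC_K{i}", host.exons, host.strand)
    # 3 retained annotated lncRNAs (reciprocal >=50% overlap, single exon)
    for i, t in enumerate(ref_nc):
        a = t.exons[0][0] + 50
        tid = f"XLOC_A{i}"
        tt = TranscriptModel(tid, f"L_{tid}", "chr1", "+",
                             ((a, a + 350),), "novel")
        candidates.add(tt)
        seqs[tid] = rand_seq(tt.length)
    # 4 removed by class code: same-strand exonic overlap with coding genes
    for i in range(4):
        host = ref_coding[i]
        e = host.exons[0]
        add(f"XLOC_C{i}", ((e[0] + 20, e[0] + 220),), host.strand)
    # 2 removed as short (<150 nt), placed intergenic (code u)
    free = 200_000
    add("XLOC_S0", ((free, free + 149),))
    add("XLOC_S1", ((free + 5_000, free + 5_120),))
    # 2 removed as low abundance (code u, long enough)
    add("XLOC_L0", ((free + 10_000, free + 10_400),), low=True)
    add("XLOC_L1", ((free + 15_000, free + 15_400),), low=True)
    # 1 removed by coding potential: a 120-codon biased ORF spanning ~90%
    orf = "ATG" + "".join(
        _NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))]
        for _ in range(119)
    ) + "TAA"
    seq = rand_seq(20) + orf + rand_seq(20)
    add("XLOC_P0", ((free + 20_000, free + 20_000 + len(seq)),), seq=seq)
    # 5 retained novel lncRNAs: u, x and i placements
    add("XLOC_N0", ((free + 30_000, free + 30_400),))
    add("XLOC_N1", ((free + 35_000, free + 35_300),))
    e = ref_coding[4].exons[1]
    add("XLOC_N2", ((e[0] + 10, e[0] + 310),),
        "-" if ref_coding[4].strand == "+" else "+")
    intron = ref_coding[5].introns[0]
    add("XLOC_N3", ((intron[0] + 20, intron[0] + 220),))
    add("XLOC_N4", ((free + 40_000, free + 40_350),))

    tids = sorted(candidates.transcripts)
    samples = [(4, 1), (4, 2), (30, 1), (30, 2)]
    counts = np.zeros((len(tids), len(samples)), dtype=np.int64)
    for i, tid in enumerate(tids):
        # unexpressed rows have TPMmax 0 < 1 (the low-abundance removals)
        counts[i] = 0 if tid in tpmmax_low else 500
    lengths = np.array([candidates.transcripts[t].length for t in tids])
    tpm = np.column_stack([
        compute_tpm(counts[:, k], lengths) for k in range(len(samples))
    ])
    expr = ExpressionMatrix(tids, samples, counts, tpm)
    return candidates, reference, expr, seqs
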