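"""The lncRNA identification cascade.

Novel transcripts from a reconstructed transcriptome are reduced to a
lncRNA set by a fixed sequence of filters: transcripts matching an
annotated model are split into annotated lncRNAs (kept) and annotated
coding transcripts (dropped); remaining novel transcripts must carry class
code 'u' (intergenic), 'x' (exonic overlap with an annotated gene on the
opposite strand) or 'i' (entirely within an intron); short transcripts
(< 150 nt spliced) and low-abundance transcripts (TPMmax < 1 over all
samples) are removed; and transcripts with protein-coding potential are
removed. Each removed transcript is attributed to the first rule that
triggered, so the filter report is conservative: input = retained + sum of
removals.

Coding potential is scored by an in-package stand-in for reference
coding-potential classifiers: a transcript is called coding when its
longest ATG→stop ORF reaches 100 codons, or when that ORF covers at least
half of the transcript and its in-frame hexamer composition scores closer
to a coding training set than to a noncoding one (log-odds > 0). The
hexamer tables are trained once, deterministically, on a packaged synthetic
fixture of codon-biased coding-like and uniform noncoding sequences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .intervals import (
    contained_in_single_intron,
    exonic_overlap_bp,
    intervals_overlap_bp,
    span_overlap_bp,
)
from .io_formats import ExpressionMatrix, GenomeAnnotation, TranscriptModel

__all__ = [
    "ClassCode",
    "FilterReport",
    "compute_tpm",
    "assign_class_code",
    "matches_annotated",
    "coding_potential_score",
    "run_identification",
    "MIN_LENGTH_NT",
    "MIN_TPMMAX",
]

MIN_LENGTH_NT = 150   # short-transcript filter
MIN_TPMMAX = 1.0      # low-abundance filter
NOVEL_PREFIX = "XLOC_"

RULE_ORDER = ("annotated_known", "class_code", "short",
              "low_abundance", "coding_potential")


@dataclass(frozen=True)
class ClassCode:
    """A Cufflinks-style class code relative to the reference annotation."""

    code: str                 # 'u', 'x', 'i' or 'other'
    evidence: str | None = None  # reference gene id for x/i


@dataclass
class FilterReport:
    n_input: int
    n_removed_by: dict[str, int]
    retained: list[str]
    removal_reason: dict[str, str] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.n_input == len(self.retained) + sum(
            self.n_removed_by.values()
        )


def compute_tpm(counts, lengths) -> np.ndarray:
    """Transcripts-per-million for one sample.

    tpm_t = (count_t / length_t) / sum_s (count_s / length_s) * 1e6.
    An all-zero sample yields all-zero TPM with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths < 1).any():
        raise ValueError("transcript lengths must be >= 1")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        warnings.warn("all-zero sample: TPM set to zero")
        return np.zeros_like(rates)
    return rates / total * 1e6


# ---------------------------------------------------------------------------
# Class codes

def assign_class_code(transcript: TranscriptModel,
                      reference: GenomeAnnotation) -> ClassCode:
    """Class code of a novel transcript against the reference annotation.

    'x' requires >= 1 bp exonic overlap on the opposite strand; 'i' full
    containment within one intron of any reference isoform (either strand);
    'u' zero overlap with any reference gene span. Same-strand exonic
    overlap, or partial gene-span overlap matching none of the above, gives
    'other' (such transcripts are candidates for known-transcript matching
    and are removed from the novel path).
    """
    same_exonic = None
    opposite_exonic = None
    intronic_host = None
    any_span = False
    for tid in sorted(reference.transcripts):
        ref = reference.transcripts[tid]
        if ref.chrom != transcript.chrom:
            continue
        if span_overlap_bp(transcript, ref) > 0:
            any_span = True
        if exonic_overlap_bp(transcript, ref) > 0:
            if ref.strand == transcript.strand:
                same_exonic = same_exonic or ref.gene_id
            else:
                opposite_exonic = opposite_exonic or ref.gene_id
        elif contained_in_single_intron(transcript, ref):
            intronic_host = intronic_host or ref.gene_id
    if same_exonic is not None:
        return ClassCode("other", same_exonic)
    if opposite_exonic is not None:
        return ClassCode("x", opposite_exonic)
    if intronic_host is not None:
        return ClassCode("i", intronic_host)
    if any_span:
        return ClassCode("other", None)
    return ClassCode("u", None)


def matches_annotated(transcript: TranscriptModel,
                      reference: GenomeAnnotation) -> TranscriptModel | None:
    """The annotated transcript this candidate reproduces, if any.

    Match = same chromosome and strand with an identical intron chain;
    single-exon candidates instead require reciprocal exonic overlap >= 50%
    with a single-exon annotated transcript.
    """
    for tid in sorted(reference.transcripts):
        ref = reference.transcripts[tid]
        if ref.chrom != transcript.chrom or ref.strand != transcript.strand:
            continue
        if len(transcript.exons) > 1:
            if (ref.intron_chain == transcript.intron_chain
                    and span_overlap_bp(transcript, ref) > 0):
                return ref
        else:
            if len(ref.exons) != 1:
                continue
            ov = intervals_overlap_bp(transcript.exons[0], ref.exons[0])
            if (ov >= 0.5 * transcript.length and ov >= 0.5 * ref.length):
                return ref
    return None


# ---------------------------------------------------------------------------
# Coding potential

_STOPS = ("TAA", "TAG", "TGA")


def _orfs(seq: str):
    """(start, stop_end, n_codons) for every ATG→stop ORF, longest per stop."""
    seq = seq.upper().replace("U", "T")
    best_start_for_stop: dict[int, int] = {}
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon == "ATG" and start is None:
                start = pos
            elif codon in _STOPS and start is not None:
                stop_end = pos + 3
                # 5'-most ATG per stop
                if stop_end not in best_start_for_stop:
                    best_start_for_stop[stop_end] = start
                start = None
    return [
        (s, e, (e - s) // 3 - 1)  # codons excluding the stop
        for e, s in sorted(best_start_for_stop.items())
    ]


def _longest_orf(seq: str):
    orfs = _orfs(seq)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o[2], -o[0]))


# position-specific nucleotide weights used to emit codon-biased coding-like
# training sequences; any consistent bias away from uniform works, strong
# bias keeps the score of random ORFs clearly negative
_CODON_POS_WEIGHTS = (
    {"A": 0.34, "G": 0.36, "C": 0.18, "T": 0.12},
    {"A": 0.38, "T": 0.30, "C": 0.22, "G": 0.10},
    {"A": 0.14, "T": 0.42, "C": 0.10, "G": 0.34},
)
_TRAIN_SEED = 917


@lru_cache(maxsize=1)
def _hexamer_tables() -> dict[str, float]:
    """Log2 odds (coding vs noncoding) per in-frame hexamer.

    Trained on a deterministic synthetic fixture: 120 codon-biased
    coding-like sequences (stop codons rejected internally) versus 120
    uniform-composition noncoding sequences, with +1 pseudocounts.
    """
    rng = np.random.default_rng(_TRAIN_SEED)
    nts = np.array(list("ACGT"))

    def coding_seq(n_codons: int) -> str:
        codons = []
        while len(codons) < n_codons:
            codon = "".join(
                rng.choice(nts, p=[w["A"], w["C"], w["G"], w["T"]])
                for w in _CODON_POS_WEIGHTS
            )
            if codon not in _STOPS:
                codons.append(codon)
        return "".join(codons)

    coding = [coding_seq(200) for _ in range(120)]
    noncoding = ["".join(rng.choice(nts, size=600)) for _ in range(120)]

    def counts(seqs, step):
        table = np.ones(4096)  # pseudocount
        idx = {c: i for i, c in enumerate("ACGT")}
        for s in seqs:
            for i in range(0, len(s) - 5, step):
                h = s[i:i + 6]
                code = 0
                ok = True
                for ch in h:
                    if ch not in idx:
                        ok = False
                        break
                    code = code * 4 + idx[ch]
                if ok:
                    table[code] += 1
        return table / table.sum()

    p_cod = counts(coding, 3)
    p_non = counts(noncoding, 1)
    logodds = np.log2(p_cod / p_non)
    keys = {}
    for code in range(4096):
        h = []
        c = code
        for _ in range(6):
            h.append("ACGT"[c % 4])
            c //= 4
        keys["".join(reversed(h))] = float(logodds[code])
    return keys


def coding_potential_score(sequence: str) -> tuple[float, bool]:
    """(hexamer log-odds of the longest ORF, is_coding flag).

    is_coding when the longest ORF reaches 100 codons, or covers >= 50% of
    the transcript with positive hexamer log-odds. Sequences with no
    ATG→stop ORF score -inf and are noncoding.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    orf = _longest_orf(seq)
    if orf is None:
        return (-math.inf, False)
    start, stop_end, n_codons = orf
    tables = _hexamer_tables()
    body = seq[start:stop_end - 3]
    scores = [
        tables.get(body[i:i + 6], 0.0) for i in range(0, len(body) - 5, 3)
    ]
    score = float(np.mean(scores)) if scores else -math.inf
    coverage = (stop_end - start) / len(seq)
    is_coding = n_codons >= 100 or (coverage >= 0.5 and score > 0)
    return (score, is_coding)


# ---------------------------------------------------------------------------
# The cascade

def run_identification(candidates: GenomeAnnotation,
                       reference: GenomeAnnotation,
                       expr: ExpressionMatrix,
                       sequences: dict[str, str],
                       skip_reference_ids: bool = False,
                       ) -> tuple[GenomeAnnotation, FilterReport]:
    """Apply the identification cascade and return (lncRNA set, report).

    Rules in order: (1) candidates matching an annotated transcript are
    split — annotated noncoding retained as annotated lncRNAs, annotated
    coding removed; (2) novel candidates must have class code u/x/i;
    (3) spliced length >= 150 nt; (4) TPMmax >= 1 over all samples;
    (5) no protein-coding potential. Removal is attributed to the first
    triggered rule only.
    """
    removed: dict[str, int] = {r: 0 for r in RULE_ORDER}
    reasons: dict[str, str] = {}
    retained: list[str] = []

    order = sorted(candidates.transcripts)
    for tid in order:
        t = candidates.transcripts[tid]
        if tid not in expr._index:
            raise ValueError(f"transcript {tid} has no expression row")
        if tid not in sequences:
            raise ValueError(f"transcript {tid} has no sequence")

        match = matches_annotated(t, reference)
        if match is not None:
            if match.biotype == "annotated_noncoding":
                retained.append(tid)        # annotated lncRNA
            else:
                removed["annotated_known"] += 1
                reasons[tid] = "annotated_known"
            continue

        code = assign_class_code(t, reference)
        if code.code not in ("u", "x", "i"):
            removed["class_code"] += 1
            reasons[tid] = "class_code"
            continue
        if t.length < MIN_LENGTH_NT:
            removed["short"] += 1
            reasons[tid] = "short"
            continue
        tpmmax = float(expr.tpm[expr.row(tid)].max())
        if tpmmax < MIN_TPMMAX:
            removed["low_abundance"] += 1
            reasons[tid] = "low_abundance"
            continue
        _, is_coding = coding_potential_score(sequences[tid])
        if is_coding:
            removed["coding_potential"] += 1
            reasons[tid] = "coding_potential"
            continue
        retained.append(tid)

    report = FilterReport(
        n_input=len(order),
        n_removed_by=removed,
        retained=retained,
        removal_reason=reasons,
    )
    assert report.check_conservation()
    return candidates.subset(retained), report
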