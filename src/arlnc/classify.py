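"""Genomic-location and functional classification of lncRNAs.

Location: a lncRNA is *antisense* when any of its exons overlaps an exon of
a protein-coding gene on the opposite strand; *intronic* when it lies fully
inside one intron of a coding isoform with no exon overlap; otherwise
*intergenic*. Independently of the primary label, *divergent* (head-to-head
TSSs within a window, default 1,000 bp) and *convergent* (tail-to-tail TESs
within the window) flags record promoter-proximal arrangements with coding
genes on the opposite strand; the flags are non-exclusive, so category
proportions may sum past 100%.

Function: lncRNAs with appreciable ribosome-footprint occupancy are
*ribo-lncRNAs*; those among them harbouring a small ORF whose footprint
density drops after the stop codon (ribosome release score >= 0.9) are
sORF-encoding; lncRNAs whose small-RNA coverage concentrates in 21–22-nt
read lengths are *sRNA precursors*; everything else is *canonical*. The
ribo and sRNA labels are non-exclusive.

The ribosome release score used here is bounded: rrs = d_orf /
(d_orf + d_down), the ORF footprint density against the density in a
window downstream of the stop, so the 0.9 reporting threshold is a
well-defined point of a [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import (
    contained_in_single_intron,
    exonic_overlap_bp,
    is_convergent,
    is_divergent,
)
from .io_formats import ExpressionMatrix, GenomeAnnotation, TranscriptModel

__all__ = [
    "LocationLabel",
    "SorfCall",
    "RiboProfile",
    "classify_genomic_location",
    "enumerate_sorfs",
    "compute_rrs",
    "detect_srna_precursor",
    "classify_functional",
    "summarize_features",
    "mann_whitney_u",
]

MIN_SORF_AA = 10          # peptide length floor (coding span >= 30 nt)
RRS_THRESHOLD = 0.9
SRNA_MIN_READS = 20
SRNA_LENGTH_RANGE = (21, 22)
SRNA_MIN_FRACTION = 0.5
RIBO_MIN_COVERAGE = 1.0   # mean reads/nt for the ribo-lncRNA call
DEFAULT_WINDOW_BP = 1000


@dataclass(frozen=True)
class LocationLabel:
    primary: str                      # intergenic | antisense | intronic
    flags: frozenset = frozenset()    # subset of {divergent, convergent}

    def __post_init__(self):
        if self.primary not in ("intergenic", "antisense", "intronic"):
            raise ValueError(f"bad primary location {self.primary!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class SorfCall:
    """An ATG→stop small ORF on the transcript (coordinates on the spliced
    transcript, 0-based; ``stop`` is the first base of the stop codon)."""

    start: int
    stop: int
    peptide_aa: int
    rrs: float | None = None


@dataclass
class RiboProfile:
    transcript_id: str
    coverage: np.ndarray  # reads/nt along the spliced transcript

    def __post_init__(self):
        self.coverage = np.asarray(self.coverage, dtype=float)
        if (self.coverage < 0).any():
            raise ValueError("negative footprint coverage")


def classify_genomic_location(lncrna: TranscriptModel,
                              reference: GenomeAnnotation,
                              window: int = DEFAULT_WINDOW_BP) -> LocationLabel:
    """Locate a lncRNA relative to the protein-coding annotation."""
    primary = "intergenic"
    coding = [
        t for t in reference.by_biotype("protein_coding")
        if t.chrom == lncrna.chrom
    ]
    for ref in coding:
        if ref.strand != lncrna.strand and exonic_overlap_bp(lncrna, ref) > 0:
            primary = "antisense"
            break
    if primary != "antisense":
        for ref in coding:
            if (exonic_overlap_bp(lncrna, ref) == 0
                    and contained_in_single_intron(lncrna, ref)):
                primary = "intronic"
                break
    flags = set()
    for ref in coding:
        if is_divergent(lncrna, ref, window):
            flags.add("divergent")
        if is_convergent(lncrna, ref, window):
            flags.add("convergent")
    return LocationLabel(primary, frozenset(flags))


def enumerate_sorfs(sequence: str) -> list[SorfCall]:
    """All small ORFs in the three forward frames of the spliced sequence.

    An sORF is an ATG…stop span with peptide length >= 10 aa (coding span
    excluding the stop >= 30 nt). Nested starts sharing a stop are reported
    once, at the 5'-most ATG.
    """
    seq = sequence.upper().replace("U", "T")
    stops = ("TAA", "TAG", "TGA")
    calls = []
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon == "ATG" and start is None:
                start = pos
            elif codon in stops and start is not None:
                aa = (pos - start) // 3  # includes the initiator Met
                if aa >= MIN_SORF_AA:
                    calls.append(SorfCall(start, pos, aa))
                start = None
    return sorted(calls, key=lambda c: (c.start, c.stop))


def compute_rrs(sorf: SorfCall, profile: RiboProfile,
                downstream_window: int = 100) -> float:
    """Ribosome release score in [0, 1].

    d_orf = mean coverage over [start, stop); d_down = mean coverage over
    the window after the stop codon. The window shrinks to what the
    transcript offers but must keep >= 10 nt; 0/0 gives 0.
    """
    cov = profile.coverage
    stop_codon_end = sorf.stop + 3
    down_end = min(len(cov), stop_codon_end + downstream_window)
    if down_end - stop_codon_end < 10:
        raise ValueError(
            f"less than 10 nt downstream of the stop at {sorf.stop}"
        )
    d_orf = float(cov[sorf.start:sorf.stop].mean())
    d_down = float(cov[stop_codon_end:down_end].mean())
    if d_orf + d_down == 0:
        return 0.0
    return d_orf / (d_orf + d_down)


def detect_srna_precursor(srna_length_counts: dict[int, float],
                          min_reads: int = SRNA_MIN_READS,
                          length_range: tuple[int, int] = SRNA_LENGTH_RANGE,
                          min_fraction: float = SRNA_MIN_FRACTION) -> bool:
    """sRNA-precursor call from per-read-length sRNA counts (18–26 nt).

    True when total reads reach *min_reads* and the 21–22-nt fraction is at
    least *min_fraction*.
    """
    total = float(sum(srna_length_counts.values()))
    if total < min_reads:
        return False
    lo, hi = length_range
    in_range = sum(
        v for k, v in srna_length_counts.items() if lo <= k <= hi
    )
    return in_range / total >= min_fraction


@dataclass
class FunctionalLabel:
    ribo_lncrna: bool
    sorf_encoding: bool
    srna_precursor: bool
    best_rrs: float | None
    best_sorf: SorfCall | None

    @property
    def canonical(self) -> bool:
        return not (self.ribo_lncrna or self.srna_precursor)

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        if self.ribo_lncrna:
            out.append("ribo_lncRNA")
        if self.srna_precursor:
            out.append("sRNA_precursor")
        if not out:
            out.append("canonical")
        return tuple(out)


def classify_functional(lncrna_id: str,
                        profile: RiboProfile | None,
                        srna_length_counts: dict[int, float] | None,
                        sequence: str,
                        ribo_min: float = RIBO_MIN_COVERAGE,
                        rrs_threshold: float = RRS_THRESHOLD,
                        downstream_window: int = 100) -> FunctionalLabel:
    """Functional label(s) for one lncRNA; ribo and sRNA are non-exclusive."""
    ribo = False
    sorf_encoding = False
    best_rrs = None
    best_sorf = None
    if profile is not None:
        ribo = float(profile.coverage.mean()) >= ribo_min
        if ribo:
            for sorf in enumerate_sorfs(sequence):
                try:
                    rrs = compute_rrs(sorf, profile, downstream_window)
                except ValueError:
                    continue  # too close to the 3' end to score
                if best_rrs is None or rrs > best_rrs:
                    best_rrs, best_sorf = rrs, sorf
            sorf_encoding = best_rrs is not None and best_rrs >= rrs_threshold
    srna = (detect_srna_precursor(srna_length_counts)
            if srna_length_counts is not None else False)
    return FunctionalLabel(ribo, sorf_encoding, srna, best_rrs, best_sorf)


# ---------------------------------------------------------------------------
# Feature summaries

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U. Exact for both n <= 20 without ties, else
    the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def summarize_features(lncrnas: GenomeAnnotation,
                       coding: GenomeAnnotation,
                       expr: ExpressionMatrix):
    """Per-set feature distributions with rank-sum comparisons.

    Features: spliced length, exons per transcript, isoforms per gene, and
    mean TPM over all samples. Returns a DataFrame with one row per feature
    carrying medians/means of both sets and the two-tailed Mann–Whitney p.
    """
    import pandas as pd

    if len(lncrnas) == 0 or len(coding) == 0:
        raise ValueError("both transcript sets must be non-empty")

    def features(ann: GenomeAnnotation):
        ts = [ann.transcripts[tid] for tid in sorted(ann.transcripts)]
        lengths = [t.length for t in ts]
        exons = [len(t.exons) for t in ts]
        isoforms = [len(tids) for _, tids in sorted(ann.genes.items())]
        mean_tpm = [
            expr.mean_tpm(t.transcript_id) for t in ts
            if t.transcript_id in expr._index
        ]
        return {
            "length_nt": lengths,
            "exons_per_transcript": exons,
            "isoforms_per_gene": isoforms,
            "mean_tpm": mean_tpm,
        }

    fl, fc = features(lncrnas), features(coding)
    rows = []
    for name in fl:
        a, b = fl[name], fc[name]
        u, p = mann_whitney_u(a, b)
        rows.append({
            "feature": name,
            "lncrna_median": float(np.median(a)),
            "lncrna_mean": float(np.mean(a)),
            "coding_median": float(np.median(b)),
            "coding_mean": float(np.mean(b)),
            "U": u,
            "p_value": p,
        })
    return pd.DataFrame(rows)
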