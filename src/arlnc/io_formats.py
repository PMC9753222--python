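"""Data model and file formats for the leaf-aging lncRNA pipeline.

Internal coordinates are 0-based half-open throughout; GTF on disk is
1-based inclusive (the GTF convention) and the shift happens only here.
Every other module receives genomic coordinates through
:class:`GenomeAnnotation` and never touches annotation files directly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptModel",
    "GenomeAnnotation",
    "ExpressionMatrix",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_expression",
    "write_table",
    "read_table",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

BIOTYPES = ("protein_coding", "annotated_noncoding", "novel")


class GtfParseError(ValueError):
    """Raised on a malformed GTF record; the message names the line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exons as sorted, non-overlapping half-open intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "novel"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for a, b in exons:
            if b <= a or a < 0:
                raise ValueError(
                    f"transcript {self.transcript_id}: bad exon [{a}, {b})"
                )
            if a < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = b
        if not exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exonic) length in nt."""
        return sum(b - a for a, b in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start position (0-based; the 5'-most transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end position (0-based; the 3'-most transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return self.introns


@dataclass
class GenomeAnnotation:
    """A set of transcripts grouped by gene, with chromosome lengths."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for t in self.transcripts.values():
            if t.chrom in self.chrom_lengths and t.end > self.chrom_lengths[t.chrom]:
                raise ValueError(
                    f"transcript {t.transcript_id} extends past the end of "
                    f"{t.chrom} ({t.end} > {self.chrom_lengths[t.chrom]})"
                )

    @property
    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tid in sorted(self.transcripts):
            out.setdefault(self.transcripts[tid].gene_id, []).append(tid)
        return out

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t

    def by_biotype(self, *biotypes: str) -> list[TranscriptModel]:
        return [
            t for tid, t in sorted(self.transcripts.items())
            if t.biotype in biotypes
        ]

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        """(chrom, start, end, strand) covering every isoform of the gene."""
        tids = self.genes[gene_id]
        ts = [self.transcripts[tid] for tid in tids]
        chroms = {t.chrom for t in ts}
        strands = {t.strand for t in ts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"gene {gene_id} spans chromosomes or strands")
        return (ts[0].chrom, min(t.start for t in ts),
                max(t.end for t in ts), ts[0].strand)

    def subset(self, tids) -> "GenomeAnnotation":
        tids = set(tids)
        return GenomeAnnotation(
            transcripts={k: v for k, v in self.transcripts.items() if k in tids},
            chrom_lengths=dict(self.chrom_lengths),
        )


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "((?:[^"\\]|\\.)*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path) -> GenomeAnnotation:
    """Read gene/transcript/exon features from a GTF file.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Exons are grouped per transcript and sorted. Lines with other feature
    types are ignored. A transcript's biotype is taken from a
    ``transcript_biotype`` (or ``gene_biotype``) attribute when present and
    defaults to ``novel`` for XLOC_ ids and ``protein_coding`` otherwise.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    declared: set[str] = set()
    chrom_max: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start_i < 1 or end_i < start_i:
                raise GtfParseError(
                    f"{path}: line {lineno}: bad interval {start}-{end}"
                )
            attr = _parse_attributes(attrs)
            if feature == "gene":
                continue
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing transcript_id/gene_id"
                )
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path}: line {lineno}: transcript strand {strand!r} is "
                    "not '+' or '-' (unstranded records are rejected)"
                )
            tid = attr["transcript_id"]
            biotype = attr.get("transcript_biotype", attr.get("gene_biotype", ""))
            if not biotype:
                biotype = "novel" if tid.startswith("XLOC_") else "protein_coding"
            if feature == "transcript":
                declared.add(tid)
                meta.setdefault(tid, (attr["gene_id"], chrom, strand, biotype))
            else:  # exon — 1-based inclusive -> 0-based half-open
                exons.setdefault(tid, []).append((start_i - 1, end_i))
                meta.setdefault(tid, (attr["gene_id"], chrom, strand, biotype))
                chrom_max[chrom] = max(chrom_max.get(chrom, 0), end_i)

    for tid in exons:
        if declared and tid not in declared:
            raise GtfParseError(
                f"{path}: exon with transcript_id {tid!r} has no parent "
                "transcript record"
            )

    ann = GenomeAnnotation(transcripts={}, chrom_lengths=chrom_max)
    for tid in sorted(exons):
        gene_id, chrom, strand, biotype = meta[tid]
        ann.add(TranscriptModel(tid, gene_id, chrom, strand,
                                tuple(exons[tid]), biotype))
    return ann


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write transcript/exon records, 0-based half-open back to 1-based GTF."""
    lines = []
    order = sorted(
        annotation.transcripts.values(),
        key=lambda t: (t.chrom, t.start, t.end, t.transcript_id),
    )
    for t in order:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'transcript_biotype "{t.biotype}";'
        )
        lines.append(
            f"{t.chrom}\tarlnc\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
            f"{t.strand}\t.\t{attrs}"
        )
        for a, b in t.exons:
            lines.append(
                f"{t.chrom}\tarlnc\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Expression matrices

_SAMPLE_RE = re.compile(r"^d(\d+)_r(\d+)$")


@dataclass
class ExpressionMatrix:
    """Per-transcript counts and TPM over (timepoint, replicate) samples."""

    transcript_ids: list[str]
    samples: list[tuple[int, int]]  # (day, replicate)
    counts: np.ndarray              # (n_transcripts, n_samples) int
    tpm: np.ndarray                 # (n_transcripts, n_samples) float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.tpm = np.asarray(self.tpm, dtype=float)
        n, m = len(self.transcript_ids), len(self.samples)
        if self.counts.shape != (n, m) or self.tpm.shape != (n, m):
            raise ValueError("counts/tpm shape does not match ids × samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        colsum = self.tpm.sum(axis=0)
        nonzero = colsum > 0
        if nonzero.any() and not np.allclose(colsum[nonzero], 1e6, rtol=1e-6):
            raise ValueError("TPM columns must sum to 1e6")
        self._index = {tid: i for i, tid in enumerate(self.transcript_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate transcript ids")

    @property
    def timepoints(self) -> list[int]:
        return sorted({d for d, _ in self.samples})

    def row(self, tid: str) -> int:
        return self._index[tid]

    def mean_tpm_profile(self, tid: str) -> np.ndarray:
        """Replicate-mean TPM per timepoint, in timepoint order."""
        r = self.tpm[self.row(tid)]
        return np.array([
            np.mean([r[j] for j, (d, _) in enumerate(self.samples) if d == day])
            for day in self.timepoints
        ])

    def mean_tpm(self, tid: str) -> float:
        return float(self.tpm[self.row(tid)].mean())

    def sample_columns(self, day: int) -> list[int]:
        return [j for j, (d, _) in enumerate(self.samples) if d == day]

    def subset(self, tids) -> "ExpressionMatrix":
        keep = [tid for tid in self.transcript_ids if tid in set(tids)]
        idx = [self._index[t] for t in keep]
        tpm = self.tpm[idx]
        # re-normalize is NOT done: TPM is defined on the full library
        m = ExpressionMatrix.__new__(ExpressionMatrix)
        m.transcript_ids = keep
        m.samples = list(self.samples)
        m.counts = self.counts[idx]
        m.tpm = tpm
        m._index = {tid: i for i, tid in enumerate(keep)}
        return m

    def to_frame(self) -> pd.DataFrame:
        cols = [f"d{d}_r{r}" for d, r in self.samples]
        return pd.DataFrame(self.counts, index=self.transcript_ids, columns=cols)


def read_expression(path, annotation: GenomeAnnotation) -> ExpressionMatrix:
    """Read a count table (first column transcript id, columns ``d{D}_r{R}``).

    Rows whose ids are absent from *annotation* are dropped with a warning.
    TPM is recomputed from counts and spliced lengths.
    """
    from .identify import compute_tpm

    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = []
    for col in df.columns:
        m = _SAMPLE_RE.match(col)
        if m is None:
            raise ValueError(f"{path}: column {col!r} is not of form d<D>_r<R>")
        samples.append((int(m.group(1)), int(m.group(2))))
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate transcript id {dup!r}")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    keep = df.index.isin(annotation.transcripts.keys())
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"{path}: dropped {dropped} row(s) absent from the annotation"
        )
    df = df.loc[keep]
    counts = df.values.astype(np.int64)
    lengths = np.array([annotation[tid].length for tid in df.index])
    tpm = np.column_stack([
        compute_tpm(counts[:, j], lengths) for j in range(counts.shape[1])
    ]) if counts.size else np.zeros_like(counts, dtype=float)
    return ExpressionMatrix(list(df.index), samples, counts, tpm)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().rename_axis("transcript_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Generic result tables

def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV (UTF-8, header row, >=6 sig digits)."""
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sequences

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement preserving the input alphabet (DNA T vs RNA U)."""
    has_u = "U" in sequence or "u" in sequence
    has_t = "T" in sequence or "t" in sequence
    if has_u and has_t:
        raise ValueError("sequence mixes T and U")
    alphabet = set("ACGTUNacgtun")
    bad = set(sequence) - alphabet
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    table = _RNA_COMP if has_u else _DNA_COMP
    return sequence.translate(table)[::-1]
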