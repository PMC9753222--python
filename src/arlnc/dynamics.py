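"""Age-related expression analysis over the leaf-aging time course.

Differential expression is tested per contrast window between the window's
endpoint timepoints: counts are normalized by median-of-ratios size
factors, a per-transcript negative-binomial dispersion is estimated by
method of moments pooled over the two endpoint groups, and a Wald test on
log2 fold change (delta-method standard error, two-sided normal reference)
yields the p-value. Benjamini–Hochberg adjustment is applied within each
contrast, and a transcript is called age-related (AR) when
|log2FC| >= 1 and adjusted p <= 0.05 in any window.

The default windows follow the leaf phenology: growth-to-maturation
(4 -> 18 d), maturation-to-senescence (16 -> 30 d) and the full lifespan
(4 -> 30 d).

AR transcripts are grouped into six temporal clusters (U1–U3 up, D1–D3
down) by k-means on z-scored log2 fold-change profiles relative to the
first timepoint; clusters are relabelled deterministically from their
centroids: direction by the sign of the terminal value, order within a
direction by the time at which half of the terminal change is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = [
    "WindowContrast",
    "DEFAULT_CONTRASTS",
    "DEResult",
    "ClusterAssignment",
    "size_factors",
    "nb_wald_test",
    "nb_wald_test_matrix",
    "bh_adjust",
    "call_ar_lncrnas",
    "log2fc_profiles",
    "kmeans_clusters",
    "localization_enrichment",
    "stress_overlap",
]

LOG2FC_MIN = 1.0
PADJ_MAX = 0.05
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class WindowContrast:
    name: str
    start_day: int
    end_day: int

    def __post_init__(self):
        if self.start_day >= self.end_day:
            raise ValueError("contrast start must precede end")


DEFAULT_CONTRASTS = (
    WindowContrast("G_to_M", 4, 18),
    WindowContrast("M_to_S", 16, 30),
    WindowContrast("G_to_S", 4, 30),
)


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    contrast: str
    log2fc: float
    p: float
    p_adj: float

    @property
    def is_ar(self) -> bool:
        return abs(self.log2fc) >= LOG2FC_MIN and self.p_adj <= PADJ_MAX


@dataclass(frozen=True)
class ClusterAssignment:
    transcript_id: str
    cluster: str               # U1..U3, D1..D3 or unclustered
    profile: tuple[float, ...]  # log2FC vs the first timepoint


# ---------------------------------------------------------------------------
# Normalization

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample/column).

    Uses transcripts with nonzero counts in every sample; if none exist,
    falls back to total-count ratios with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if all_nonzero.any():
        sub = counts[all_nonzero]
        log_geomean = np.mean(np.log(sub), axis=1)
        factors = np.exp(
            np.median(np.log(sub) - log_geomean[:, None], axis=0)
        )
    else:
        warnings.warn(
            "no transcript observed in all samples; falling back to "
            "total-count size factors"
        )
        totals = counts.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    return factors


# ---------------------------------------------------------------------------
# NB Wald endpoint test

def nb_wald_test_matrix(counts1: np.ndarray, counts2: np.ndarray,
                        factors1: np.ndarray, factors2: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB Wald test; rows are transcripts, columns replicates.

    Returns (log2fc, p). Normalized group means use a 0.5 pseudo-count;
    dispersion is method-of-moments pooled across the two groups with a
    small floor; the Wald statistic is log2fc over its delta-method
    standard error against a two-sided normal reference. Transcripts with
    zero counts at both endpoints get log2fc 0 and p 1.
    """
    c1 = np.atleast_2d(np.asarray(counts1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts2, dtype=float))
    f1 = np.asarray(factors1, dtype=float)
    f2 = np.asarray(factors2, dtype=float)
    n1, n2 = c1.shape[1], c2.shape[1]

    q1 = c1 / f1  # normalized counts
    q2 = c2 / f2
    m1 = q1.mean(axis=1) + PSEUDOCOUNT
    m2 = q2.mean(axis=1) + PSEUDOCOUNT
    log2fc = np.log2(m2 / m1)

    # method-of-moments dispersion, pooled over the two endpoint groups:
    # var(q) = mu + alpha * mu^2  =>  alpha = (var - mu) / mu^2
    def group_alpha(q, m):
        if q.shape[1] < 2:
            return np.zeros(q.shape[0])
        v = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m ** 2
        return np.where(np.isfinite(a), a, 0.0)

    alpha = np.maximum(
        (group_alpha(q1, m1) * n1 + group_alpha(q2, m2) * n2) / (n1 + n2),
        DISPERSION_FLOOR,
    )

    # delta method: var(log2 m) = var(mean q) / (m ln2)^2,
    # var(mean q) = (m / n_eff + alpha m^2 / n) with n_eff absorbing the
    # per-sample scale factors of the Poisson part
    inv_f1 = np.mean(1.0 / f1)
    inv_f2 = np.mean(1.0 / f2)
    var_m1 = m1 * inv_f1 / n1 + alpha * m1 ** 2 / n1
    var_m2 = m2 * inv_f2 / n2 + alpha * m2 ** 2 / n2
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(var_m1 / (m1 ** 2 * ln2sq) + var_m2 / (m2 ** 2 * ln2sq))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    both_zero = (c1.sum(axis=1) == 0) & (c2.sum(axis=1) == 0)
    log2fc = np.where(both_zero, 0.0, log2fc)
    p = np.where(both_zero, 1.0, np.clip(p, 0.0, 1.0))
    return log2fc, p


def nb_wald_test(counts1, counts2, factors1, factors2) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`nb_wald_test_matrix`."""
    lfc, p = nb_wald_test_matrix(
        np.asarray(counts1, dtype=float)[None, :],
        np.asarray(counts2, dtype=float)[None, :],
        factors1, factors2,
    )
    return float(lfc[0]), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_ar_lncrnas(expr: ExpressionMatrix, lncrna_ids,
                    contrasts=DEFAULT_CONTRASTS):
    """Endpoint DE tests for each contrast window over the lncRNA set.

    Size factors come from all samples of the full matrix; BH adjustment is
    applied within each contrast over the tested lncRNAs. Returns
    (results, ar_ids, per-contrast summary). The AR set is the union over
    contrasts of transcripts with |log2FC| >= 1 and p_adj <= 0.05.
    """
    lncrna_ids = [t for t in sorted(lncrna_ids) if t in expr._index]
    factors = size_factors(expr.counts)
    rows = [expr.row(t) for t in lncrna_ids]
    results: list[DEResult] = []
    summary = []
    ar: set[str] = set()
    for contrast in contrasts:
        cols1 = expr.sample_columns(contrast.start_day)
        cols2 = expr.sample_columns(contrast.end_day)
        if not cols1 or not cols2:
            raise ValueError(
                f"contrast {contrast.name}: endpoint day missing from samples"
            )
        c1 = expr.counts[np.ix_(rows, cols1)]
        c2 = expr.counts[np.ix_(rows, cols2)]
        lfc, p = nb_wald_test_matrix(c1, c2, factors[cols1], factors[cols2])
        padj = bh_adjust(p)
        up = down = 0
        for tid, l, pv, pa in zip(lncrna_ids, lfc, p, padj):
            r = DEResult(tid, contrast.name, float(l), float(pv), float(pa))
            results.append(r)
            if r.is_ar:
                ar.add(tid)
                if l > 0:
                    up += 1
                else:
                    down += 1
        summary.append({
            "contrast": contrast.name,
            "n_tested": len(lncrna_ids),
            "n_up": up,
            "n_down": down,
        })
    return results, sorted(ar), summary


# ---------------------------------------------------------------------------
# Temporal clustering

def log2fc_profiles(expr: ExpressionMatrix, tids) -> tuple[list[str], np.ndarray]:
    """Replicate-mean TPM log2 ratios to the first timepoint, with 0.5
    pseudo-count, one row per transcript."""
    tids = [t for t in tids if t in expr._index]
    profiles = []
    for t in tids:
        prof = expr.mean_tpm_profile(t) + PSEUDOCOUNT
        profiles.append(np.log2(prof / prof[0]))
    return tids, np.asarray(profiles)


def _relabel_from_centroids(centroids: np.ndarray) -> list[str]:
    """Map raw k-means labels to U1..Un / D1..Dn from the centroids alone.

    Direction = sign of the centroid's terminal value; within a direction,
    clusters are ordered by the first timepoint index at which the centroid
    passes half of its terminal value (earliest change first).
    """
    k = centroids.shape[0]
    info = []
    for c in range(k):
        cent = centroids[c]
        terminal = cent[-1]
        direction = "U" if terminal >= 0 else "D"
        half = 0.5 * terminal
        if direction == "U":
            idx = np.argmax(cent >= half) if (cent >= half).any() else len(cent)
        else:
            idx = np.argmax(cent <= half) if (cent <= half).any() else len(cent)
        info.append((c, direction, int(idx)))
    names = {}
    for direction in ("U", "D"):
        members = [x for x in info if x[1] == direction]
        members.sort(key=lambda x: (x[2], x[0]))
        for rank, (c, _, _) in enumerate(members, start=1):
            names[c] = f"{direction}{rank}"
    return [names[c] for c in range(k)]


def kmeans_clusters(profiles: np.ndarray, tids, k: int = 6,
                    seed: int = 0) -> list[ClusterAssignment]:
    """k-means temporal clustering of log2FC profiles.

    Profiles are z-scored per transcript before clustering; constant
    profiles cannot be standardized and are returned as ``unclustered``.
    The relabelling to U*/D* is a pure function of the centroids computed
    in the original (non-standardized) profile space.
    """
    profiles = np.asarray(profiles, dtype=float)
    tids = list(tids)
    if profiles.shape[0] != len(tids):
        raise ValueError("profiles and ids disagree")
    sd = profiles.std(axis=1)
    usable = sd > 0
    if usable.sum() < k:
        raise ValueError(f"need at least k={k} non-constant profiles")
    z = (profiles[usable] - profiles[usable].mean(axis=1, keepdims=True)) \
        / sd[usable][:, None]
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    raw = km.fit_predict(z)
    centroids = np.vstack([
        profiles[usable][raw == c].mean(axis=0) for c in range(k)
    ])
    names = _relabel_from_centroids(centroids)
    out = []
    j = 0
    for i, tid in enumerate(tids):
        if usable[i]:
            cluster = names[raw[j]]
            j += 1
        else:
            cluster = "unclustered"
        out.append(ClusterAssignment(tid, cluster, tuple(profiles[i])))
    return out


# ---------------------------------------------------------------------------
# Localization and stress overlap

def localization_enrichment(nuclear_tpm: dict[str, float],
                            cytosolic_tpm: dict[str, float]) -> dict[str, str]:
    """Per-transcript fraction call: nuclear iff nuclear TPM strictly
    exceeds cytosolic TPM (ties go to cytosolic); transcripts absent from
    both fractions are excluded."""
    out = {}
    for tid in sorted(set(nuclear_tpm) | set(cytosolic_tpm)):
        nuc = nuclear_tpm.get(tid, 0.0)
        cyt = cytosolic_tpm.get(tid, 0.0)
        if nuc == 0.0 and cyt == 0.0:
            continue
        out[tid] = "nuclear" if nuc > cyt else "cytosolic"
    return out


def stress_overlap(ar_ids, stress_sets: dict[str, set]):
    """Overlap of the AR set with each stress-responsive lncRNA set."""
    ar = set(ar_ids)
    rows = []
    for condition in sorted(stress_sets):
        s = set(stress_sets[condition])
        inter = len(s & ar)
        rows.append({
            "condition": condition,
            "n_overlap": inter,
            "n_stress": len(s),
            "fraction": inter / len(s) if s else 0.0,
        })
    return rows
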