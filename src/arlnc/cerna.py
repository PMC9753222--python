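"""ceRNA (lncRNA–miRNA–mRNA) set discovery and network assembly.

For every lncRNA–mRNA pair sharing at least one targeting miRNA, the
significance of the shared ("junction") miRNA count is evaluated with an
upper-tail hypergeometric test over the merged miRNA universe; pairs with
p < 0.05 whose expression profiles are positively correlated (PCC > 0.7 on
replicate-mean TPM) are retained as ceRNA sets and assembled into a
tripartite lncRNA–miRNA–mRNA network. No multiple-testing correction is
applied across candidate pairs by default (a BH option exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix
from .pairs import pearson_cc

__all__ = [
    "TargetTable",
    "CeRNASet",
    "hypergeom_pvalue",
    "find_cerna_sets",
    "build_network",
]

P_MAX = 0.05
PCC_MIN = 0.7


@dataclass
class TargetTable:
    """miRNA→target interaction edges; the input universe for ceRNA calls."""

    edges: set = field(default_factory=set)  # (mirna, target, target_class)

    def __post_init__(self):
        for e in self.edges:
            if len(e) != 3 or e[2] not in ("mRNA", "lncRNA"):
                raise ValueError(f"bad target edge {e!r}")

    @property
    def universe(self) -> set:
        return {m for m, _, _ in self.edges}

    def targets_of_class(self, target_class: str) -> dict[str, set]:
        """target id -> set of miRNAs targeting it, for one target class."""
        out: dict[str, set] = {}
        for m, t, c in self.edges:
            if c == target_class:
                out.setdefault(t, set()).add(m)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(rows, columns=["mirna_id", "target_id",
                                           "target_class"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TargetTable":
        return cls(edges={
            (r.mirna_id, r.target_id, r.target_class)
            for r in df.itertuples()
        })


@dataclass(frozen=True)
class CeRNASet:
    lncrna_id: str
    mrna_id: str
    junction_mirnas: frozenset
    p: float
    pcc: float


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N miRNAs in the universe, K targeting the mRNA, n targeting the lncRNA,
    k shared. Computed through the log-space survival function.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"k={k} outside the support [{max(0, K + n - N)}, {min(K, n)}]"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def find_cerna_sets(targets: TargetTable, expr: ExpressionMatrix,
                    p_max: float = P_MAX, pcc_min: float = PCC_MIN,
                    bh: bool = False) -> list[CeRNASet]:
    """Candidate lncRNA–mRNA pairs sharing miRNAs, tested and filtered.

    Candidates are every (lncRNA, mRNA) pair with >= 1 shared miRNA.
    Retained sets satisfy p < p_max (strict; raw p unless ``bh``) and
    PCC > pcc_min (strict, signed: positive co-expression only). Pairs
    missing expression are skipped with a warning. Output is ordered by
    p ascending, then ids.
    """
    universe = targets.universe
    if not universe:
        raise ValueError("empty miRNA universe")
    N = len(universe)
    mrna_targets = targets.targets_of_class("mRNA")
    lnc_targets = targets.targets_of_class("lncRNA")

    candidates = []
    for lnc in sorted(lnc_targets):
        for mrna in sorted(mrna_targets):
            shared = lnc_targets[lnc] & mrna_targets[mrna]
            if not shared:
                continue
            p = hypergeom_pvalue(N, len(mrna_targets[mrna]),
                                 len(lnc_targets[lnc]), len(shared))
            candidates.append((lnc, mrna, shared, p))

    if bh and candidates:
        from .dynamics import bh_adjust
        adj = bh_adjust([c[3] for c in candidates])
        candidates = [
            (lnc, mrna, shared, float(pa))
            for (lnc, mrna, shared, _), pa in zip(candidates, adj)
        ]

    sets = []
    for lnc, mrna, shared, p in candidates:
        if p >= p_max:
            continue
        if lnc not in expr._index or mrna not in expr._index:
            warnings.warn(f"no expression for pair ({lnc}, {mrna}); skipped")
            continue
        pcc = pearson_cc(expr.mean_tpm_profile(lnc),
                         expr.mean_tpm_profile(mrna))
        if pcc is None or pcc <= pcc_min:
            continue
        sets.append(CeRNASet(lnc, mrna, frozenset(shared), p, pcc))
    sets.sort(key=lambda s: (s.p, s.lncrna_id, s.mrna_id))
    return sets


def build_network(sets: list[CeRNASet]):
    """Tripartite edge list and node-degree summary.

    Every junction membership contributes a lncRNA–miRNA and a miRNA–mRNA
    edge. Returns (edges DataFrame, degrees DataFrame, counts per node type).
    """
    edges = set()
    for s in sets:
        for m in s.junction_mirnas:
            edges.add((s.lncrna_id, "lncRNA", m, "miRNA"))
            edges.add((m, "miRNA", s.mrna_id, "mRNA"))
    rows = sorted(edges)
    edge_df = pd.DataFrame(
        rows, columns=["source", "source_type", "target", "target_type"]
    )
    degree: dict[tuple[str, str], int] = {}
    for a, ta, b, tb in rows:
        degree[(a, ta)] = degree.get((a, ta), 0) + 1
        degree[(b, tb)] = degree.get((b, tb), 0) + 1
    deg_df = pd.DataFrame(
        [{"node": n, "node_type": t, "degree": d}
         for (n, t), d in sorted(degree.items())]
    )
    counts = {t: 0 for t in ("lncRNA", "miRNA", "mRNA")}
    if not deg_df.empty:
        for t, group in deg_df.groupby("node_type"):
            counts[t] = len(group)
    return edge_df, deg_df, counts
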