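"""Seed-and-extension screen for intermolecular lncRNA–mRNA duplexes.

The screen looks for ungapped antiparallel base-paired regions between an
lncRNA and an mRNA: exact Watson–Crick seeds of length 6 are located
through a k-mer index of the mRNA, each seed is extended outward in both
directions under a simple additive nearest-pair energy model (G:U wobbles
allowed in the extension, not in seeds), and the extension is trimmed back
to its best-energy span. Reported hits must reach an interaction energy
below −16 kcal/mol over at least 15 paired bases; candidate interactions
are then filtered by expression correlation over the leaf lifespan
(|PCC| ≥ 0.9).

The energy model is a deliberately simple stand-in for thermodynamic
nearest-neighbour energies: per-pair constants calibrated so that the
−16 kcal/mol reporting gate sits exactly at a 15-nt A:U-only perfect
duplex (15 × −1.1 = −16.5). Bulged (gapped) duplexes and intramolecular
accessibility are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix
from .pairs import pearson_cc

__all__ = [
    "EnergyModel",
    "DuplexHit",
    "InteractionCall",
    "find_seeds",
    "extend_duplex",
    "scan_pair",
    "screen_and_filter",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class EnergyModel:
    """Additive per-pair energies (kcal/mol) for ungapped duplex scoring."""

    gc: float = -2.2
    au: float = -1.1
    gu: float = -0.6
    mismatch: float = 1.0
    xdrop: float = 3.0
    seed_len: int = 6
    min_len: int = 15          # paired bases per reported hit
    max_energy: float = -16.0  # strict upper bound (E < max_energy)

    def pair_energy(self, a: str, b: str) -> float:
        """Energy of pairing nucleotide *a* with *b* (both as RNA, 5'->3' sense)."""
        p = (a, b)
        if p in _WC:
            return self.gc if a in "GC" else self.au
        if p in _GU:
            return self.gu
        return self.mismatch

    def is_wc(self, a: str, b: str) -> bool:
        return (a, b) in _WC


@dataclass(frozen=True)
class DuplexHit:
    """An ungapped antiparallel duplex between two transcripts.

    ``lnc_interval`` and ``mrna_interval`` are 0-based half-open on the two
    molecules; position ``lnc_interval[0] + t`` pairs with
    ``mrna_interval[1] - 1 - t``. ``paired_length`` counts non-mismatch
    positions within the span.
    """

    lnc_id: str
    mrna_id: str
    lnc_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    paired_length: int
    energy: float


@dataclass(frozen=True)
class InteractionCall:
    hit: DuplexHit
    pcc: float


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def find_seeds(lnc_seq: str, mrna_seq: str, seed_len: int = 6):
    """All (lnc_pos, mrna_pos) where a *seed_len*-mer of the lncRNA is the
    exact Watson–Crick reverse complement of an mRNA *seed_len*-mer.

    ``mrna_pos`` is the start of the mRNA k-mer. Found via a precomputed
    k-mer index of the mRNA; G:U pairs do not count in seeds.
    """
    lnc = _to_rna(lnc_seq)
    mrna = _to_rna(mrna_seq)
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    index: dict[str, list[int]] = {}
    for j in range(len(mrna) - seed_len + 1):
        kmer = mrna[j:j + seed_len]
        index.setdefault(kmer, []).append(j)
    seeds = []
    for i in range(len(lnc) - seed_len + 1):
        kmer = lnc[i:i + seed_len]
        try:
            target = "".join(comp[c] for c in reversed(kmer))
        except KeyError:
            continue  # N or other ambiguity: never seeds
        for j in index.get(target, ()):
            seeds.append((i, j))
    return seeds


def extend_duplex(seed: tuple[int, int], lnc_seq: str, mrna_seq: str,
                  model: EnergyModel = EnergyModel(),
                  lnc_id: str = "lncRNA", mrna_id: str = "mRNA") -> DuplexHit:
    """Extend a seed outward on its diagonal and trim to the best-energy span.

    Extension proceeds independently in each direction from the seed edge,
    accumulating per-position energies, and stops a direction once the
    running sum rises more than ``model.xdrop`` above that direction's best
    prefix. The reported span is the seed plus the best prefix of each
    direction; ``paired_length`` counts paired (non-mismatch) positions.
    """
    lnc = _to_rna(lnc_seq)
    mrna = _to_rna(mrna_seq)
    i, j = seed
    k = model.seed_len
    c = i + (j + k - 1)  # lnc[a] pairs mrna[c - a]

    def direction_best(a_start: int, step: int):
        """Best (energy, extent) walking from a_start by step until x-drop."""
        best, best_n = 0.0, 0
        run = 0.0
        n = 0
        a = a_start
        while 0 <= a < len(lnc) and 0 <= c - a < len(mrna):
            run += model.pair_energy(lnc[a], mrna[c - a])
            n += 1
            if run < best:
                best, best_n = run, n
            if run - best > model.xdrop:
                break
            a += step
        return best, best_n

    seed_energy = sum(model.pair_energy(lnc[a], mrna[c - a])
                      for a in range(i, i + k))
    left_e, left_n = direction_best(i - 1, -1)
    right_e, right_n = direction_best(i + k, +1)

    a0 = i - left_n
    a1 = i + k + right_n  # half-open on lnc
    energy = seed_energy + left_e + right_e
    paired = sum(
        1 for a in range(a0, a1)
        if model.pair_energy(lnc[a], mrna[c - a]) < 0
    )
    b0 = c - (a1 - 1)
    b1 = c - a0 + 1
    return DuplexHit(lnc_id, mrna_id, (a0, a1), (b0, b1), paired, energy)


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _codes(seq: str) -> np.ndarray:
    return np.array([_CODE.get(ch, 4) for ch in seq], dtype=np.int8)


def _pair_table(model: EnergyModel) -> np.ndarray:
    t = np.full((5, 5), model.mismatch)
    t[_CODE["G"], _CODE["C"]] = t[_CODE["C"], _CODE["G"]] = model.gc
    t[_CODE["A"], _CODE["U"]] = t[_CODE["U"], _CODE["A"]] = model.au
    t[_CODE["G"], _CODE["U"]] = t[_CODE["U"], _CODE["G"]] = model.gu
    return t


def _best_span_on_diagonal(e: np.ndarray) -> tuple[float, int, int]:
    """Minimum-sum subarray of per-position energies: (sum, start, stop)."""
    S = np.concatenate([[0.0], np.cumsum(e)])
    prefix_max = np.maximum.accumulate(S[:-1])
    vals = S[1:] - prefix_max
    t = int(np.argmin(vals))
    s = int(np.argmax(S[:t + 1]))
    return float(vals[t]), s, t + 1


def scan_pair(lnc_seq: str, mrna_seq: str,
              model: EnergyModel = EnergyModel(),
              lnc_id: str = "lncRNA", mrna_id: str = "mRNA",
              apply_thresholds: bool = True) -> list[DuplexHit]:
    """Screen one lncRNA–mRNA pair: seed, extend, merge, filter.

    Every seed is extended along its diagonal; extensions sharing a
    diagonal are refined jointly to that diagonal's exact best-energy span
    (the limit of x-drop extension with unbounded drop), so the reported
    candidate per diagonal is the optimal ungapped alignment through its
    seeds. Candidates overlapping on both molecules are then merged keeping
    the best-energy hit per overlapping group. With ``apply_thresholds``
    the reported hits satisfy ``energy < model.max_energy`` and
    ``paired_length >= model.min_len``; without it, all merged candidates
    are returned (used by the exhaustive oracle comparison). Hits are
    sorted by energy ascending.
    """
    lnc = _to_rna(lnc_seq)
    mrna = _to_rna(mrna_seq)
    seeds = find_seeds(lnc, mrna, model.seed_len)
    if not seeds:
        return []
    lc = _codes(lnc)
    mc = _codes(mrna)
    table = _pair_table(model)
    diagonals = sorted({i + j + model.seed_len - 1 for i, j in seeds})

    candidates: list[DuplexHit] = []
    for c in diagonals:
        a0 = max(0, c - (len(mrna) - 1))
        a1 = min(len(lnc) - 1, c)
        la = lc[a0:a1 + 1]
        ma = mc[c - a1:c - a0 + 1][::-1]  # aligned so index t pairs la[t]
        e = table[la, ma]
        energy, s, t = _best_span_on_diagonal(e)
        if energy >= 0:
            continue
        paired = int((e[s:t] < 0).sum())
        a_start, a_end = a0 + s, a0 + t
        b0 = c - (a_end - 1)
        b1 = c - a_start + 1
        candidates.append(DuplexHit(
            lnc_id, mrna_id, (a_start, a_end), (b0, b1), paired, energy))

    if apply_thresholds:
        # only candidates below the energy gate can be reported or suppress
        # a reportable hit (suppressors have better energy by construction)
        candidates = [h for h in candidates if h.energy < model.max_energy]

    # merge overlapping candidates, best energy first
    candidates.sort(key=lambda h: (h.energy, h.lnc_interval,
                                   h.mrna_interval))
    kept: list[DuplexHit] = []
    for hit in candidates:
        clash = False
        for other in kept:
            if (hit.lnc_interval[0] < other.lnc_interval[1]
                    and other.lnc_interval[0] < hit.lnc_interval[1]
                    and hit.mrna_interval[0] < other.mrna_interval[1]
                    and other.mrna_interval[0] < hit.mrna_interval[1]):
                clash = True
                break
        if not clash:
            kept.append(hit)

    if apply_thresholds:
        kept = [
            h for h in kept
            if h.energy < model.max_energy and h.paired_length >= model.min_len
        ]
    return sorted(kept, key=lambda h: (h.energy, h.lnc_interval))


def screen_and_filter(lnc_ids, mrna_ids, sequences: dict[str, str],
                      expr: ExpressionMatrix,
                      model: EnergyModel = EnergyModel(),
                      pcc_min: float = 0.9) -> list[InteractionCall]:
    """Scan every lncRNA × mRNA pair and keep hits with |PCC| >= pcc_min.

    PCC is computed on replicate-mean TPM over all timepoints; the
    correlation gate is non-strict (>=) and two-sided (absolute value).
    Pairs missing a sequence are skipped with a warning.
    """
    import warnings

    calls: list[InteractionCall] = []
    for lnc in sorted(lnc_ids):
        if lnc not in sequences:
            warnings.warn(f"no sequence for {lnc}; skipped")
            continue
        for mrna in sorted(mrna_ids):
            if mrna == lnc:
                continue
            if mrna not in sequences:
                warnings.warn(f"no sequence for {mrna}; skipped")
                continue
            hits = scan_pair(sequences[lnc], sequences[mrna], model, lnc, mrna)
            if not hits:
                continue
            x = expr.mean_tpm_profile(lnc)
            y = expr.mean_tpm_profile(mrna)
            pcc = pearson_cc(x, y)
            if pcc is None or abs(pcc) < pcc_min:
                continue
            for h in hits:
                calls.append(InteractionCall(h, pcc))
    calls.sort(key=lambda c: (c.hit.energy, c.hit.lnc_id, c.hit.mrna_id))
    return calls


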