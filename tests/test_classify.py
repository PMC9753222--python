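"""Location geometry, sORF calling, release scores and feature summaries."""

import numpy as np
import pytest

from arlnc.classify import (
    RiboProfile,
    SorfCall,
    classify_functional,
    classify_genomic_location,
    compute_rrs,
    detect_srna_precursor,
    enumerate_sorfs,
    mann_whitney_u,
    summarize_features,
)
from arlnc.io_formats import GenomeAnnotation, TranscriptModel


def _reference():
    """Two coding genes on chr1: [10k..13k) on + and [40k..43k) on -."""
    ann = GenomeAnnotation(transcripts={}, chrom_lengths={"chr1": 200_000})
    ann.add(TranscriptModel(
        "g1.1", "g1", "chr1", "+",
        ((10_000, 10_500), (11_200, 11_700), (12_500, 13_000)),
        "protein_coding"))
    ann.add(TranscriptModel(
        "g2.1", "g2", "chr1", "-",
        ((40_000, 40_600), (41_500, 42_000), (42_600, 43_000)),
        "protein_coding"))
    return ann


class TestGenomicLocation:
    def test_opposite_strand_exon_overlap_is_antisense(self):
        ref = _reference()
        lnc = TranscriptModel("l", "gl", "chr1", "-", ((11_300, 11_600),))
        assert classify_genomic_location(lnc, ref).primary == "antisense"

    def test_divergent_flag_from_head_to_head_tss(self):
        ref = _reference()
        # g1 TSS at 10,000 (+); lncRNA on '-' ending 300 bp upstream
        lnc = TranscriptModel("l", "gl", "chr1", "-", ((9_200, 9_700),))
        label = classify_genomic_location(lnc, ref)
        assert label.primary == "intergenic"
        assert label.flags == frozenset({"divergent"})

    def test_convergent_flag_from_tail_to_tail_tes(self):
        ref = _reference()
        # g1 TES at 12,999 (+); lncRNA on '-' starting 400 bp downstream
        lnc = TranscriptModel("l", "gl", "chr1", "-", ((13_400, 13_900),))
        label = classify_genomic_location(lnc, ref)
        assert label.primary == "intergenic"
        assert label.flags == frozenset({"convergent"})

    def test_far_from_genes_is_plain_intergenic(self):
        ref = _reference()
        lnc = TranscriptModel("l", "gl", "chr1", "+", ((100_000, 100_500),))
        label = classify_genomic_location(lnc, ref)
        assert label.primary == "intergenic"
        assert label.flags == frozenset()

    def test_intronic_either_strand(self):
        ref = _reference()
        for strand in "+-":
            lnc = TranscriptModel("l", "gl", "chr1", strand,
                                  ((10_600, 11_100),))
            assert classify_genomic_location(lnc, ref).primary == "intronic"

    def test_agrees_with_geometric_oracle_on_random_placements(self):
        """1,000 random placements against direct coordinate arithmetic."""
        ref = _reference()
        genes = list(ref.transcripts.values())
        rng = np.random.default_rng(23)
        for _ in range(1000):
            start = int(rng.integers(5_000, 50_000))
            width = int(rng.integers(100, 2_000))
            strand = "+" if rng.random() < 0.5 else "-"
            lnc = TranscriptModel("l", "gl", "chr1", strand,
                                  ((start, start + width),))
            got = classify_genomic_location(lnc, ref, window=1000)

            end = start + width

            def overlap(a, b, c, d):
                return max(0, min(b, d) - max(a, c))

            antisense = any(
                g.strand != strand
                and any(overlap(start, end, a, b) for a, b in g.exons)
                for g in genes)
            intronic = (not any(
                any(overlap(start, end, a, b) for a, b in g.exons)
                for g in genes)) and any(
                any(e1 <= start and end <= s2 for (_, e1), (s2, _) in
                    zip(g.exons[:-1], g.exons[1:]))
                for g in genes)
            primary = ("antisense" if antisense
                       else "intronic" if intronic else "intergenic")
            flags = set()
            for g in genes:
                if g.strand == strand:
                    continue
                if overlap(start, end, g.start, g.end):
                    continue
                tss_l = start if strand == "+" else end - 1
                tes_l = end - 1 if strand == "+" else start
                tss_g = g.start if g.strand == "+" else g.end - 1
                tes_g = g.end - 1 if g.strand == "+" else g.start
                left_is_lnc = start <= g.start
                if left_is_lnc:
                    l_str, r_str = strand, g.strand
                else:
                    l_str, r_str = g.strand, strand
                if l_str == "-" and r_str == "+" and \
                        abs(tss_l - tss_g) <= 1000:
                    flags.add("divergent")
                if l_str == "+" and r_str == "-" and \
                        abs(tes_l - tes_g) <= 1000:
                    flags.add("convergent")
            assert got.primary == primary, (start, width, strand)
            assert got.flags == frozenset(flags), (start, width, strand)


class TestSorfs:
    def test_minimum_peptide_boundary(self):
        # ATG + 9 sense codons + TAA: peptide 10 aa (coding span 30 nt)
        seq = "ATG" + "GCT" * 9 + "TAA"
        calls = enumerate_sorfs(seq)
        assert len(calls) == 1
        assert calls[0].peptide_aa == 10
        assert (calls[0].start, calls[0].stop) == (0, 30)

    def test_below_boundary_not_called(self):
        seq = "ATG" + "GCT" * 8 + "TAA"
        assert enumerate_sorfs(seq) == []

    def test_nested_starts_report_five_prime_most(self):
        seq = "ATG" + "GCT" * 3 + "ATG" + "GCT" * 9 + "TAA"
        calls = enumerate_sorfs(seq)
        assert len(calls) == 1
        assert calls[0].start == 0

    def test_agrees_with_brute_force_codon_walk(self):
        rng = np.random.default_rng(9)
        nts = np.array(list("ACGT"))
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(100):
            seq = "".join(rng.choice(nts, 500))
            got = {(c.start, c.stop) for c in enumerate_sorfs(seq)}
            want = set()
            for frame in range(3):
                codons = [seq[p:p + 3]
                          for p in range(frame, len(seq) - 2, 3)]
                open_start = None
                for ci, codon in enumerate(codons):
                    if codon == "ATG" and open_start is None:
                        open_start = ci
                    elif codon in stops and open_start is not None:
                        if ci - open_start >= 10:
                            want.add((frame + 3 * open_start,
                                      frame + 3 * ci))
                        open_start = None
            assert got == want


class TestRrs:
    def test_uniform_coverage_is_half(self):
        sorf = SorfCall(0, 30, 10)
        profile = RiboProfile("t", np.full(200, 3.0))
        assert compute_rrs(sorf, profile) == pytest.approx(0.5)

    def test_nine_to_one_ratio(self):
        cov = np.zeros(200)
        cov[:30] = 9.0
        cov[33:133] = 1.0
        assert compute_rrs(SorfCall(0, 30, 10),
                           RiboProfile("t", cov)) == pytest.approx(0.9)

    def test_zero_downstream_gives_one(self):
        cov = np.zeros(200)
        cov[:30] = 2.0
        assert compute_rrs(SorfCall(0, 30, 10), RiboProfile("t", cov)) == 1.0

    def test_zero_everywhere_gives_zero(self):
        assert compute_rrs(SorfCall(0, 30, 10),
                           RiboProfile("t", np.zeros(200))) == 0.0

    def test_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(1)
        cov = rng.poisson(4.0, 300).astype(float)
        sorf = SorfCall(12, 72, 20)
        base = compute_rrs(sorf, RiboProfile("t", cov))
        for c in (0.1, 3.0, 250.0):
            assert compute_rrs(sorf, RiboProfile("t", c * cov)) == \
                pytest.approx(base)

    def test_too_little_downstream_is_error(self):
        with pytest.raises(ValueError, match="downstream"):
            compute_rrs(SorfCall(0, 30, 10), RiboProfile("t", np.ones(38)))


class TestSrnaPrecursor:
    def test_enriched_21_22_called(self):
        counts = {21: 40, 22: 40, 24: 20}
        assert detect_srna_precursor(counts)

    def test_uniform_lengths_not_called(self):
        counts = {k: 100 // 9 for k in range(18, 27)}
        counts[18] += 100 - sum(counts.values())
        assert not detect_srna_precursor(counts)  # 2/9 < 0.5

    def test_depth_gate(self):
        assert not detect_srna_precursor({21: 5})


class TestFunctional:
    def test_planted_sorf_lncrnas_called_with_sorf(self, bundle):
        truth = bundle.truth
        for tid in sorted(truth.location_category):
            want = truth.functional_category[tid]
            lab = classify_functional(
                tid, RiboProfile(tid, bundle.ribo_profiles[tid]),
                bundle.srna_counts[tid], bundle.sequences[tid])
            assert lab.sorf_encoding == want.startswith("sorf"), tid
            assert lab.srna_precursor == want.endswith("srna"), tid
            assert lab.canonical == (want == "canonical"), tid

    def test_dual_labels_coexist(self, bundle):
        duals = [t for t, lab in bundle.truth.functional_category.items()
                 if lab == "sorf+srna"]
        assert duals
        lab = classify_functional(
            duals[0], RiboProfile(duals[0], bundle.ribo_profiles[duals[0]]),
            bundle.srna_counts[duals[0]], bundle.sequences[duals[0]])
        assert set(lab.labels) == {"ribo_lncRNA", "sRNA_precursor"}

    def test_quiet_lncrna_is_canonical(self):
        lab = classify_functional(
            "t", RiboProfile("t", np.zeros(300)),
            {k: 1 for k in range(18, 27)}, "ACGT" * 75)
        assert lab.labels == ("canonical",)


class TestSummaries:
    def test_identical_sets_give_p_one(self, bundle):
        ann = bundle.annotation
        coding = ann.subset([t for t in sorted(ann.transcripts)
                             if ann.transcripts[t].biotype == "protein_coding"])
        table = summarize_features(coding, coding, bundle.expr)
        assert np.allclose(table["p_value"], 1.0)

    def test_exact_rank_sum_on_separated_groups(self):
        u, p = mann_whitney_u([100, 200, 300], [400, 500, 600])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_lncrnas_shorter_than_coding(self, bundle):
        ann = bundle.annotation
        lnc = ann.subset(sorted(bundle.truth.location_category))
        coding = ann.subset([t for t in sorted(ann.transcripts)
                             if ann.transcripts[t].biotype == "protein_coding"])
        table = summarize_features(lnc, coding, bundle.expr).set_index("feature")
        row = table.loc["length_nt"]
        assert row["lncrna_median"] < row["coding_median"]
        assert row["p_value"] < 1e-4

    def test_empty_set_rejected(self, bundle):
        ann = bundle.annotation
        coding = ann.subset([t for t in sorted(ann.transcripts)
                             if ann.transcripts[t].biotype == "protein_coding"])
        with pytest.raises(ValueError, match="non-empty"):
            summarize_features(ann.subset([]), coding, bundle.expr)
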