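"""The identification cascade: TPM, class codes, coding potential, filters."""

import numpy as np
import pytest

from arlnc.identify import (
    RULE_ORDER,
    assign_class_code,
    coding_potential_score,
    compute_tpm,
    matches_annotated,
    run_identification,
)
from arlnc.io_formats import GenomeAnnotation, TranscriptModel
from arlnc.synthetic import identification_fixture


class TestComputeTpm:
    def test_length_normalization(self):
        # rates 0.01 and 0.02 -> 1/3 and 2/3 of a million
        tpm = compute_tpm([10, 10], [1000, 500])
        assert np.allclose(tpm, [1e6 / 3, 2e6 / 3])
        assert np.isclose(tpm.sum(), 1e6)

    def test_single_transcript_gets_everything(self):
        assert np.allclose(compute_tpm([7], [123]), [1e6])

    def test_all_zero_sample_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm([0, 0], [100, 100])
        assert np.all(tpm == 0)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_tpm([1], [0])
        with pytest.raises(ValueError):
            compute_tpm([-1], [100])


def _ref_with_gene(strand="+"):
    ann = GenomeAnnotation(transcripts={}, chrom_lengths={"chr1": 100_000})
    ann.add(TranscriptModel(
        "ref.1", "refgene", "chr1", strand,
        ((1000, 1300), (2000, 2300), (3000, 3400)), "protein_coding"))
    return ann


class TestClassCodes:
    def test_intergenic_is_u(self):
        ref = _ref_with_gene()
        t = TranscriptModel("n", "gn", "chr1", "+", ((50_000, 50_400),))
        assert assign_class_code(t, ref).code == "u"

    def test_opposite_strand_exon_overlap_is_x(self):
        ref = _ref_with_gene("+")
        t = TranscriptModel("n", "gn", "chr1", "-", ((2100, 2500),))
        code = assign_class_code(t, ref)
        assert code.code == "x"
        assert code.evidence == "refgene"

    def test_fully_intronic_is_i(self):
        ref = _ref_with_gene("+")
        t = TranscriptModel("n", "gn", "chr1", "+", ((1400, 1900),))
        assert assign_class_code(t, ref).code == "i"

    def test_same_strand_exon_overlap_is_other(self):
        ref = _ref_with_gene("+")
        t = TranscriptModel("n", "gn", "chr1", "+", ((2100, 2500),))
        assert assign_class_code(t, ref).code == "other"

    def test_partial_span_overlap_without_exons_is_other(self):
        # straddles the gene 3' boundary through the last intron
        ref = _ref_with_gene("+")
        t = TranscriptModel("n", "gn", "chr1", "+", ((2400, 2900), (3500, 3900)))
        assert assign_class_code(t, ref).code == "other"

    def test_agrees_with_brute_force_overlap_oracle(self):
        """Random placements against an all-pairs coordinate oracle."""
        ref = _ref_with_gene("+")
        refs = list(ref.transcripts.values())
        rng = np.random.default_rng(11)
        for _ in range(1000):
            start = int(rng.integers(0, 5000))
            width = int(rng.integers(50, 800))
            strand = "+" if rng.random() < 0.5 else "-"
            t = TranscriptModel("n", "gn", "chr1", strand,
                                ((start, start + width),))
            got = assign_class_code(t, ref).code

            # oracle: direct interval arithmetic, no shared helpers
            def seg_overlap(a, b, c, d):
                return max(0, min(b, d) - max(a, c))

            same = opp = span = intronic = False
            for r in refs:
                exonic = sum(
                    seg_overlap(start, start + width, a, b)
                    for a, b in r.exons
                )
                if seg_overlap(start, start + width, r.start, r.end):
                    span = True
                if exonic and r.strand == strand:
                    same = True
                elif exonic:
                    opp = True
                elif any(a <= start and start + width <= b
                         for a, b in zip(
                             [e[1] for e in r.exons[:-1]],
                             [e[0] for e in r.exons[1:]])):
                    intronic = True
            want = ("other" if same else "x" if opp else "i" if intronic
                    else "other" if span else "u")
            assert got == want


class TestMatching:
    def test_identical_intron_chain_matches(self):
        ref = _ref_with_gene("+")
        t = TranscriptModel(
            "n", "gn", "chr1", "+",
            ((900, 1300), (2000, 2300), (3000, 3500)))  # ends differ
        assert matches_annotated(t, ref).transcript_id == "ref.1"

    def test_different_intron_chain_does_not_match(self):
        ref = _ref_with_gene("+")
        t = TranscriptModel(
            "n", "gn", "chr1", "+", ((1000, 1300), (2100, 2300)))
        assert matches_annotated(t, ref) is None

    def test_single_exon_needs_reciprocal_half_overlap(self):
        ann = GenomeAnnotation(transcripts={}, chrom_lengths={"chr1": 10_000})
        ann.add(TranscriptModel("r.1", "r", "chr1", "+", ((1000, 1400),),
                                "annotated_noncoding"))
        near = TranscriptModel("n", "g", "chr1", "+", ((1100, 1500),))
        far = TranscriptModel("m", "g", "chr1", "+", ((1300, 1700),))
        assert matches_annotated(near, ann) is not None
        assert matches_annotated(far, ann) is None


class TestCodingPotential:
    def test_long_orf_is_coding(self):
        rng = np.random.default_rng(3)
        from arlnc.synthetic import _NON_STOP_CODONS
        orf = "ATG" + "".join(
            _NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))]
            for _ in range(400)
        ) + "TAA"
        seq = "GGGGG" + orf + "CCCCC"  # ~99% ORF coverage
        _, is_coding = coding_potential_score(seq)
        assert is_coding

    def test_random_sequences_rarely_coding(self):
        rng = np.random.default_rng(4)
        nts = np.array(list("ACGT"))
        n_coding = sum(
            coding_potential_score("".join(rng.choice(nts, 300)))[1]
            for _ in range(100)
        )
        assert n_coding <= 1

    def test_no_start_codon_is_noncoding_with_sentinel(self):
        score, is_coding = coding_potential_score("CCCCCCCCCCCC")
        assert not is_coding
        assert score == -np.inf


class TestCascade:
    def test_engineered_fixture_counts(self):
        candidates, reference, expr, seqs = identification_fixture()
        lnc, report = run_identification(candidates, reference, expr, seqs)
        assert report.n_input == 20
        assert report.n_removed_by == {
            "annotated_known": 3, "class_code": 4, "short": 2,
            "low_abundance": 2, "coding_potential": 1,
        }
        assert len(report.retained) == 8
        assert report.check_conservation()
        assert set(report.retained) == set(lnc.transcripts)

    def test_short_boundary_at_149(self):
        candidates, reference, expr, seqs = identification_fixture()
        assert candidates["XLOC_S0"].length == 149
        _, report = run_identification(candidates, reference, expr, seqs)
        assert report.removal_reason["XLOC_S0"] == "short"

    def test_first_rule_wins_attribution(self):
        """A transcript failing several rules is charged to the first."""
        candidates, reference, expr, seqs = identification_fixture()
        # XLOC_S1 is both short (120 nt) and would fail nothing else; make a
        # candidate that is short AND low-abundance: S-rule must win
        _, report = run_identification(candidates, reference, expr, seqs)
        for tid, reason in report.removal_reason.items():
            earlier = RULE_ORDER[:RULE_ORDER.index(reason)]
            # by construction no earlier rule applies; spot-check 'short'
            assert reason in RULE_ORDER
            assert "retained" not in earlier

    def test_missing_expression_row_is_error(self):
        candidates, reference, expr, seqs = identification_fixture()
        bad = candidates.subset(list(candidates.transcripts))
        bad.add(TranscriptModel("XLOC_NEW", "g", "chr1", "+",
                                ((400_000, 400_300),)))
        seqs2 = dict(seqs, XLOC_NEW="ACGT" * 75)
        with pytest.raises(ValueError, match="XLOC_NEW"):
            run_identification(bad, reference, expr, seqs2)

    def test_bundle_cascade_recovers_planted_lncrnas(self, bundle):
        ann = bundle.annotation
        reference = ann.subset([
            t for t in sorted(ann.transcripts)
            if ann.transcripts[t].biotype != "novel"
        ])
        lnc, report = run_identification(
            ann, reference, bundle.expr, bundle.sequences)
        planted = set(bundle.truth.location_category)
        retained = set(report.retained)
        # every coding transcript is dropped; nearly every planted lncRNA
        # survives (rare coding-potential false positives are tolerated)
        assert not any(
            ann.transcripts[t].biotype == "protein_coding" for t in retained
        )
        assert len(planted & retained) >= 0.95 * len(planted)
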