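"""Sequence/protein feature extraction against independent oracles."""

import math

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import DIWV
from hypothesis import given
from hypothesis import strategies as st

from ribopred.features import (
    NEndClass,
    UaugClass,
    build_cai_weights,
    build_feature_table,
    classify_uaug,
    compute_cai,
    compute_tai,
    instability_index,
    n_end_half_life,
    nucleotide_frequency_matrix,
    one_hot_encode,
    start_codon_type,
    stop_codon_type,
    tai_weights,
)
from ribopred.sequence_io import GeneRecord, translate_cds
from ribopred.tables import AMINO_ACIDS


class TestUaug:
    @pytest.mark.parametrize(
        "utr,expected",
        [
            ("CCCCCCCCCCCC", UaugClass.NONE),
            ("CCCCCCATGCCC", UaugClass.IN_FRAME),      # uATG at -6
            ("CCCCCATGCCCC", UaugClass.OUT_OF_FRAME),  # uATG at -7
            ("ATGCCCCCCCCC", UaugClass.IN_FRAME),      # uATG at -12
            ("CCCCCCCCCATG", UaugClass.IN_FRAME),      # uATG at -3
            ("CCCCCCCCATGC", UaugClass.OUT_OF_FRAME),  # uATG at -4
            ("", UaugClass.NONE),
            ("ATG", UaugClass.IN_FRAME),               # short UTR scanned as-is
        ],
    )
    def test_classification(self, utr, expected):
        assert classify_uaug(utr) is expected

    def test_in_frame_precedence_over_out_of_frame(self):
        # uATGs at -10 (out of frame) and -6 (in frame)
        assert classify_uaug("CCATGCATGCCC") is UaugClass.IN_FRAME

    def test_scan_restricted_to_window(self):
        # ATG at -15 lies outside the default 12-nt window
        assert classify_uaug("ATG" + "C" * 12) is UaugClass.NONE
        assert classify_uaug("ATG" + "C" * 12, window_len=15) is UaugClass.IN_FRAME

    @given(st.text(alphabet="ACGT", min_size=0, max_size=12))
    def test_in_frame_implies_atg_at_multiple_of_three(self, utr):
        result = classify_uaug(utr)
        starts = {
            len(utr) - i for i in range(len(utr) - 2) if utr[i:i + 3] == "ATG"
        }
        if result is UaugClass.IN_FRAME:
            assert any(p % 3 == 0 for p in starts)
        elif result is UaugClass.NONE:
            assert not starts


class TestStartStopCodons:
    @pytest.mark.parametrize(
        "cds,start,stop",
        [
            ("ATGAAATAA", "ATG", "TAA"),
            ("GTGAAATGA", "GTG", "TGA"),
            ("TTGAAATAG", "TTG", "TAG"),
        ],
    )
    def test_typing(self, cds, start, stop):
        assert start_codon_type(cds) == start
        assert stop_codon_type(cds) == stop

    def test_non_stop_terminal_is_error(self):
        with pytest.raises(ValueError):
            stop_codon_type("ATGAAAAAA")


class TestCai:
    def test_single_synonym_gets_weight_one(self):
        w = build_cai_weights(["ATG" + "AAA" * 30 + "TAA"])
        assert w["AAA"] == 1.0

    def test_ratio_weights(self):
        # body: AAA x30, AAG x15 -> w(AAG) = 0.5
        ref = ["ATG" + "AAA" * 30 + "AAG" * 15 + "TAA"]
        w = build_cai_weights(ref)
        assert w["AAG"] == pytest.approx(0.5)

    def test_pseudo_count_for_unseen_synonym(self):
        ref = ["ATG" + "AAA" * 30 + "TAA"]
        w = build_cai_weights(ref)
        assert w["AAG"] == pytest.approx(0.5 / 30)

    def test_absent_amino_acid_neutral_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            w = build_cai_weights(["ATG" + "AAA" * 5 + "TAA"])
        assert w["TGG"] == 1.0  # Trp never seen

    def test_geometric_mean(self):
        weights = {"AAA": 1.0, "AAG": 0.5}
        cds = "ATG" + "AAA" + "AAG" + "TAA"
        assert compute_cai(cds, weights) == pytest.approx(math.sqrt(0.5))

    def test_all_weight_one_gives_cai_one(self):
        assert compute_cai("ATG" + "GCA" * 7 + "TAA", {"GCA": 1.0}) == 1.0

    def test_permutation_invariance_and_bounds(self, rng):
        ref = ["ATG" + "AAAAAGGCAGCG" * 10 + "TAA"]
        w = build_cai_weights(ref)
        body = ["AAA", "AAG", "GCA", "GCG"] * 5
        cds1 = "ATG" + "".join(body) + "TAA"
        perm = [body[i] for i in rng.permutation(len(body))]
        cds2 = "ATG" + "".join(perm) + "TAA"
        v1, v2 = compute_cai(cds1, w), compute_cai(cds2, w)
        assert v1 == pytest.approx(v2)
        assert 0 < v1 <= 1

    def test_higher_weight_synonym_never_decreases_cai(self):
        w = {"AAA": 1.0, "AAG": 0.4, "GCA": 0.7}
        low = "ATG" + "AAG" + "GCA" * 4 + "TAA"
        high = "ATG" + "AAA" + "GCA" * 4 + "TAA"
        assert compute_cai(high, w) >= compute_cai(low, w)


class TestTai:
    def test_degenerate_uniform_limit(self):
        # equal adaptiveness for every codon -> tAI = 1 whatever the gene
        from ribopred.tables import SENSE_CODONS

        uniform = {c: 1.0 for c in SENSE_CODONS}
        cds = "ATG" + "AAAGCGTTC" + "TAA"
        assert compute_tai(cds, weights=uniform) == 1.0

    def test_two_codon_toy_geometric_mean(self):
        # W = (4, 2) -> w = (1, 0.5); gene body uses each once
        weights = {"AAA": 1.0, "GCA": 0.5}
        cds = "ATG" + "AAA" + "GCA" + "TAA"
        assert compute_tai(cds, weights=weights) == pytest.approx(math.sqrt(0.5))

    def test_packaged_weights_bounded(self):
        w = tai_weights()
        assert all(0 < v <= 1 for v in w.values())
        assert max(w.values()) == 1.0

    def test_single_codon_gene_with_max_weight(self):
        w = tai_weights()
        best = max(w, key=w.get)
        cds = "ATG" + best * 5 + "TAA"
        assert compute_tai(cds, weights=w) == pytest.approx(1.0)


class TestNEndRule:
    @pytest.mark.parametrize(
        "protein,expected",
        [
            ("MAKL", NEndClass.STABLE_GT_10H),     # Met excised, A stable
            ("MPKL", NEndClass.EXCLUDED_PRO),      # Met excised, Pro exposed
            ("MRKL", NEndClass.STABLE_GT_10H),     # R large: Met retained
            ("MSRL", NEndClass.STABLE_GT_10H),     # S excised, S stable
            ("MVKL", NEndClass.STABLE_GT_10H),
            ("M", NEndClass.STABLE_GT_10H),        # classified on residue 1
        ],
    )
    def test_classification(self, protein, expected):
        assert n_end_half_life(protein) is expected

    def test_destabilizing_after_excision(self):
        # excision exposes residue 2 only for small residues; craft one:
        # Met retained (L is large) -> M itself is stable
        assert n_end_half_life("MLKK") is NEndClass.STABLE_GT_10H
        # without excision the initiator Met is always classified
        assert n_end_half_life("MAKL", met_excision=False) is NEndClass.STABLE_GT_10H

    def test_excluded_pro_iff_classified_residue_is_proline(self):
        for protein in ("MPA", "MAV", "MPP"):
            cls = n_end_half_life(protein)
            excised = protein[1] in set("ACGPSTV")
            residue = protein[1] if excised else protein[0]
            assert (cls is NEndClass.EXCLUDED_PRO) == (residue == "P")


class TestInstabilityIndex:
    def test_formula_on_dipeptide(self):
        for a, b in [("M", "K"), ("W", "W"), ("A", "P")]:
            assert instability_index(a + b) == pytest.approx(5 * DIWV[a][b])

    def test_homopolymer_closed_form(self):
        # all DIWV(G,G) terms equal; II = 10 (L-1) DIWV(G,G) / L
        for L in (2, 5, 17):
            expected = 10.0 * (L - 1) * DIWV["G"]["G"] / L
            assert instability_index("G" * L) == pytest.approx(expected)

    def test_against_independent_sum_oracle(self, rng):
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(1000):
            pep = "".join(rng.choice(letters, size=rng.integers(2, 40)))
            oracle = 10.0 / len(pep) * sum(
                DIWV[pep[i]][pep[i + 1]] for i in range(len(pep) - 1)
            )
            assert abs(instability_index(pep) - oracle) < 1e-9

    def test_against_biopython(self, rng):
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(25):
            pep = "".join(rng.choice(letters, size=30))
            assert instability_index(pep) == pytest.approx(
                ProteinAnalysis(pep).instability_index(), abs=1e-6
            )

    def test_unknown_residue_is_error(self):
        with pytest.raises(ValueError):
            instability_index("MXK")


class TestFrequencyMatrix:
    def _record(self, gid, utr, cds):
        return GeneRecord(gene_id=gid, utr5=utr, cds=cds,
                          protein=translate_cds(cds))

    def test_identical_records_give_unit_frequencies(self):
        rec = self._record("g", "A" * 20, "ATG" + "GCA" * 10 + "TAA")
        freq = nucleotide_frequency_matrix([rec, rec])
        covered = freq.dropna()
        assert ((covered.max(axis=1) == 1.0).all())

    def test_rows_sum_to_one(self, small_dataset):
        freq = nucleotide_frequency_matrix(small_dataset["records"][:50])
        sums = freq.dropna().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_half_split_position(self):
        r1 = self._record("a", "A" * 20, "ATG" + "GCA" * 10 + "TAA")
        r2 = self._record("b", "A" * 5 + "G" + "A" * 14, "ATG" + "GCA" * 10 + "TAA")
        freq = nucleotide_frequency_matrix([r1, r2])
        assert freq.loc[-15].tolist() == [0.5, 0.0, 0.5, 0.0]

    def test_uncovered_positions_nan(self):
        rec = self._record("g", "AAA", "ATG" + "GCA" * 10 + "TAA")
        freq = nucleotide_frequency_matrix([rec])
        assert np.isnan(freq.loc[-15, "A"])
        assert freq.loc[-1, "A"] == 1.0


class TestFeatureTable:
    def test_missing_rule_drops_upstream_window_only(self, rng):
        # 20% of genes have UTRs too short for the -30..-1 window; the
        # downstream +1..+30 window is always covered.
        records = []
        for i in range(50):
            utr_len = 10 if i < 10 else 35
            utr = "".join(rng.choice(list("ACGT"), size=utr_len))
            cds = "ATG" + "GCAGAAGCG" * 12 + "TAA"
            records.append(GeneRecord(
                gene_id=f"g{i}", utr5=utr, cds=cds,
                protein=translate_cds(cds)))
        table = build_feature_table(records, missing_threshold=0.15)
        assert "MFE_m30_m1" not in table.columns
        assert "MFE_p1_p30" in table.columns
        assert len(table) == 50

    def test_zero_missing_keeps_all_windows(self, rng):
        records = []
        for i in range(20):
            utr = "".join(rng.choice(list("ACGT"), size=35))
            cds = "ATG" + "GCAGAAGCG" * 12 + "TAA"
            records.append(GeneRecord(
                gene_id=f"g{i}", utr5=utr, cds=cds,
                protein=translate_cds(cds)))
        table = build_feature_table(records)
        assert {"MFE_m30_m1", "MFE_p1_p30"} <= set(table.columns)

    def test_join_excludes_genes_absent_from_responses(self, small_dataset):
        import pandas as pd
        from ribopred.pipeline import prepare_response

        records = small_dataset["records"][:30]
        response = prepare_response(
            small_dataset["pa_table"], small_dataset["mrna_table"],
            small_dataset["grouping"],
        ).iloc[:10]
        table = build_feature_table(records, responses=response)
        assert set(table.index) <= set(response.index)

    def test_one_hot_uses_most_frequent_level_as_reference(self):
        import pandas as pd

        t = pd.DataFrame({"Stop": ["TAA", "TAA", "TGA"], "CAI": [0.5, 0.6, 0.7]})
        encoded, blocks = one_hot_encode(t, categorical=("Stop",))
        assert blocks["Stop"] == ["Stop=TGA"]  # TAA is the reference level
        assert blocks["CAI"] == ["CAI"]
        assert encoded["Stop=TGA"].tolist() == [0.0, 0.0, 1.0]


def test_feature_vector_typed_extraction(small_dataset):
    from ribopred.features import build_cai_weights, feature_vector, tai_weights

    records = small_dataset["records"][:5]
    cai_w = build_cai_weights([r.cds for r in small_dataset["records"]])
    tai_w = tai_weights()
    fv = feature_vector(records[0], cai_w, tai_w)
    assert fv.gene_id == records[0].gene_id
    assert 0 < fv.cai <= 1 and 0 < fv.tai <= 1
    assert fv.length == len(records[0].protein)
    assert fv.mfe_plus1_plus30 is None or fv.mfe_plus1_plus30 <= 0
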