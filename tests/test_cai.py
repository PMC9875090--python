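import math

import numpy as np
import pytest

import cubkit as ck
from cubkit.cai import (
    CAIScorer,
    WEIGHT_FLOOR,
    cai,
    expected_cai,
    weights_from_reference,
)
from cubkit.errors import CubkitError, ReferenceTableError
from cubkit.io import CodingSequence

from conftest import make_counts


@pytest.fixture(scope="module")
def host_weights(code):
    """Weights from the packaged human reference usage."""
    t2 = ck.load_fixture("table2")
    ref = t2[["codon", "homo_sapiens"]].rename(
        columns={"homo_sapiens": "rscu"}
    )
    return weights_from_reference(ref, code, reference_id="homo_sapiens")


class TestWeights:
    def test_family_max_is_one(self, host_weights, code):
        for aa, cods in code.synonymous_families.items():
            assert max(host_weights.w[c] for c in cods) == pytest.approx(1.0)

    def test_phe_ratio_from_printed_values(self, host_weights):
        # human Phe RSCU: UUU 0.97, UUC 1.03
        assert host_weights["UUU"] == pytest.approx(0.97 / 1.03, abs=1e-9)

    def test_zero_rscu_floored(self, code):
        ref = {c: 1.0 for c in code.synonymous_codons}
        ref["TTT"] = 0.0
        w = weights_from_reference(ref, code)
        assert w.w["TTT"] == WEIGHT_FLOOR

    def test_counts_reference_converted(self, code):
        # counts 9:1 → RSCU 1.8:0.2 → w 1 : 1/9
        ref = {c: 10 for c in code.synonymous_codons}
        ref.update({"TTT": 90, "TTC": 10})
        w = weights_from_reference(
            {c: float(v * 100) for c, v in ref.items()}, code
        )
        assert w.w["TTT"] == pytest.approx(1.0)
        assert w.w["TTC"] == pytest.approx(1 / 9)

    def test_missing_family_is_error(self, code):
        ref = {c: 1.0 for c in code.synonymous_codons if c[0] != "G"}
        with pytest.raises(ReferenceTableError):
            weights_from_reference(ref, code)


class TestCAI:
    def test_all_optimal_sequence_scores_one(self, host_weights, code):
        best = [
            max(cods, key=lambda c: host_weights.w[c])
            for cods in code.synonymous_families.values()
        ]
        seq = CodingSequence("opt", "".join(best * 3))
        assert cai(seq, host_weights, code) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self, host_weights, code):
        a, b = host_weights.w["TTT"], host_weights.w["GGT"]
        seq = CodingSequence("x", "TTTGGT")
        assert cai(seq, host_weights, code) == pytest.approx(
            math.sqrt(a * b), abs=1e-12
        )

    def test_order_permutation_invariance(self, host_weights, code, rng):
        codons = ["TTT", "GGT", "GCA", "CAA", "AAG", "CGT"] * 4
        s1 = CodingSequence("x", "".join(codons))
        shuffled = list(codons)
        rng.shuffle(shuffled)
        s2 = CodingSequence("y", "".join(shuffled))
        assert cai(s1, host_weights, code) == pytest.approx(
            cai(s2, host_weights, code)
        )

    def test_higher_weight_synonym_never_decreases(self, host_weights, code):
        # human Phe: UUC is the preferred codon, UUU the lesser one
        low = CodingSequence("x", "TTTGGTGCA")
        high = CodingSequence("y", "TTCGGTGCA")
        assert cai(high, host_weights, code) >= cai(
            low, host_weights, code
        )

    def test_met_trp_stop_excluded(self, host_weights, code):
        with_extras = CodingSequence("x", "ATGTGGTTTTAA")
        only_phe = CodingSequence("y", "TTT")
        assert cai(with_extras, host_weights, code) == pytest.approx(
            cai(only_phe, host_weights, code)
        )

    def test_no_scoreable_codons_is_error(self, host_weights, code):
        with pytest.raises(CubkitError):
            cai(CodingSequence("x", "ATGTGG"), host_weights, code)

    def test_scorer_estimator(self, host_weights, code):
        t2 = ck.load_fixture("table2")
        ref = t2[["codon", "homo_sapiens"]].rename(
            columns={"homo_sapiens": "rscu"}
        )
        seqs = ck.at_rich_panel(10, seed=13, length_codons=120)
        est = CAIScorer(reference=ref, genetic_code=code).fit()
        scores = est.transform(seqs)
        assert np.allclose(
            scores, [cai(s, host_weights, code) for s in seqs]
        )
        assert ((scores > 0) & (scores <= 1)).all()


class TestExpectedCAI:
    def test_uniform_weights_give_ecai_one(self, code):
        w = ck.WeightTable(w={c: 1.0 for c in code.synonymous_codons})
        seqs = ck.at_rich_panel(10, seed=21, length_codons=60)
        res = expected_cai(seqs, w, n_random=100, seed=1, code=code)
        assert res.sd_cai == 0.0
        assert res.e_cai == pytest.approx(1.0)

    def test_deterministic_under_seed(self, host_weights, code):
        seqs = ck.at_rich_panel(10, seed=22, length_codons=60)
        r1 = expected_cai(seqs, host_weights, n_random=120, seed=7,
                          code=code)
        r2 = expected_cai(seqs, host_weights, n_random=120, seed=7,
                          code=code)
        assert r1.mean_cai == r2.mean_cai
        assert np.array_equal(r1.cais, r2.cais)

    def test_adapted_query_beats_null(self, host_weights, code):
        best = [
            max(cods, key=lambda c: host_weights.w[c])
            for cods in code.synonymous_families.values()
        ]
        adapted = [
            CodingSequence(f"a{i}", "".join(best * 3)) for i in range(5)
        ]
        res = expected_cai(adapted, host_weights, n_random=150, seed=3,
                           code=code)
        query_mean = np.mean(
            [cai(s, host_weights, code) for s in adapted]
        )
        assert query_mean > res.e_cai

    def test_coverage_calibration(self, host_weights, code):
        """About 5% of fresh null draws exceed the 95%-coverage e-CAI."""
        seqs = ck.at_rich_panel(10, seed=30, length_codons=100)
        res = expected_cai(seqs, host_weights, n_random=500, seed=11,
                           code=code)
        fresh = expected_cai(seqs, host_weights, n_random=200, seed=12,
                             code=code)
        frac = float((fresh.cais > res.e_cai).mean())
        assert frac <= 0.05 + 0.03

    def test_small_n_rejected(self, host_weights, code):
        seqs = ck.at_rich_panel(10, seed=31, length_codons=60)
        with pytest.raises(CubkitError):
            expected_cai(seqs, host_weights, n_random=50, code=code)

    def test_degenerate_composition_is_error(self, host_weights, code):
        seqs = [CodingSequence("x", "TTT" * 20)]
        with pytest.raises(CubkitError, match="degenerate"):
            expected_cai(seqs, host_weights, n_random=100, code=code)
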