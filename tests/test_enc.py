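import numpy as np
import pytest

import cubkit as ck
from cubkit.errors import CubkitError, ENCUndefinedError
from cubkit.io import count_codons
from cubkit.enc import ENCScorer, enc, enc_gc3_table, expected_enc

from conftest import make_counts


def enc_oracle(counts, code):
    """Independent brute-force evaluation of the ENC estimator."""
    class_F = {}
    for aa, cods in code.synonymous_families.items():
        xs = [counts[c] for c in cods]
        n = sum(xs)
        if n < 2:
            continue
        F = (n * sum((x / n) ** 2 for x in xs) - 1) / (n - 1)
        if F > 0:
            class_F.setdefault(len(cods), []).append(F)
    fbar = {k: sum(v) / len(v) for k, v in class_F.items()}
    total = 2.0
    for k, n_aa in {2: 9, 3: 1, 4: 5, 6: 3}.items():
        if k == 3 and 3 not in fbar:
            total += 0.5 * (1 / fbar[2] + 1 / fbar[4])
        else:
            total += n_aa / fbar[k]
    return min(total, 61.0)


class TestENC:
    def test_uniform_usage_caps_at_61(self, code):
        t = make_counts({c: 10 for c in code.synonymous_codons})
        assert enc(t, code).enc == 61.0

    def test_one_codon_per_family_is_20(self, code):
        t = make_counts(
            {fam[0]: 5 for fam in code.synonymous_families.values()}
        )
        res = enc(t, code)
        assert res.enc == 20.0
        assert all(F == 1.0 for F, _ in res.per_aa_F.values())

    def test_matches_brute_force_oracle(self, code, rng):
        for _ in range(20):
            t = make_counts(
                {
                    c: int(rng.integers(0, 40))
                    for c in code.synonymous_codons
                }
            )
            try:
                ours = enc(t, code).enc
            except CubkitError:
                continue
            assert ours == pytest.approx(enc_oracle(t, code), abs=1e-9)

    def test_range_invariant(self, code, rng):
        for _ in range(20):
            t = make_counts(
                {
                    c: int(rng.integers(1, 30))
                    for c in code.synonymous_codons
                }
            )
            assert 20.0 <= enc(t, code).enc <= 61.0

    def test_concentration_never_increases_enc(self, code):
        """Moving a 4-fold family's counts onto fewer codons lowers ENC."""
        base = {c: 6 for c in code.synonymous_codons}
        spread = enc(make_counts(base), code).enc
        conc = dict(base)
        conc.update({"GCT": 24, "GCC": 0, "GCA": 0, "GCG": 0})
        assert enc(make_counts(conc), code).enc <= spread

    def test_scaling_counts_changes_enc_little(self, code, rng):
        """The n−1 correction makes ENC depend weakly on depth; once
        family totals are moderately large, a ×10 scaling moves ENC by
        < 0.5."""
        t = {c: int(rng.integers(50, 150)) for c in code.synonymous_codons}
        e1 = enc(make_counts(t), code).enc
        e10 = enc(
            make_counts({c: 10 * n for c, n in t.items()}), code
        ).enc
        assert abs(e1 - e10) < 0.5

    def test_missing_ile_uses_fallback(self, code):
        t = {c: 5 for c in code.synonymous_codons}
        for c in ("ATT", "ATC", "ATA"):
            t[c] = 0
        res = enc(make_counts(t), code)
        assert any("interpolated" in n for n in res.notes)

    def test_missing_required_class_is_error(self, code):
        # wipe out all 4-fold families
        t = {c: 5 for c in code.synonymous_codons}
        for aa in code.degeneracy_classes[4]:
            for c in code.synonymous_families[aa]:
                t[c] = 0
        with pytest.raises(ENCUndefinedError, match="class 4"):
            enc(make_counts(t), code)


class TestExpectedCurve:
    @pytest.mark.parametrize(
        "s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
    )
    def test_closed_form_points(self, s, expected):
        assert expected_enc(s) == pytest.approx(expected, abs=1e-12)

    def test_printed_formula_direct_evaluation(self):
        s = 0.2037
        assert expected_enc(s) == pytest.approx(
            2 + s + 29 / (s**2 + (1 - s) ** 2), abs=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(CubkitError):
            expected_enc(1.2)
        with pytest.raises(CubkitError):
            expected_enc(-0.1)


class TestENCGC3Table:
    def test_single_row(self, code):
        seqs = ck.at_rich_panel(10, seed=6, length_codons=200)[:1]
        tbl = enc_gc3_table(seqs, code)
        assert len(tbl) == 1
        assert set(tbl.columns) == {"s", "enc", "expected_enc"}

    def test_composition_only_model_straddles_curve(self, code):
        """Sequences whose codon choice depends only on third-base
        composition scatter around the expected curve with ~zero mean
        signed deviation."""
        rng = np.random.default_rng(77)
        seqs = []
        for i in range(40):
            model = ck.usage_model(gc3=float(rng.uniform(0.2, 0.8)))
            seqs.append(
                ck.sample_cds(model, 800, rng, seq_id=f"m{i}")
            )
        tbl = enc_gc3_table(seqs, code)
        dev = (tbl["enc"] - tbl["expected_enc"]).mean()
        assert abs(dev) < 2.0

    def test_biased_panel_mostly_below_curve(self, code, at_rich_90):
        tbl = enc_gc3_table(at_rich_90, code)
        frac_below = (tbl["enc"] < tbl["expected_enc"]).mean()
        assert frac_below >= 0.6

    def test_scorer_matches_function(self, code):
        seqs = ck.at_rich_panel(10, seed=8, length_codons=150)
        scores = ENCScorer(code).fit(seqs).transform(seqs)
        direct = [enc(count_codons(s, code), code).enc for s in seqs]
        assert np.allclose(scores, direct)
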