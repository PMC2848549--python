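"""MK tables, Fisher's exact test, Tajima's D, Ka/Ks, chi-square."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquascan.locus_stats import (
    CodingAlignment,
    FrameError,
    MKTable,
    classify_sites,
    fisher_exact_2x2,
    ka_ks,
    mk_test,
    tajimas_d,
    translate_codon,
    two_locus_independence,
)
from aquascan.synthetic_data import simulate_balanced_locus, simulate_coding_locus


class TestFisherExact:
    # the three worked 2x2 examples with their published two-tailed p-values
    @pytest.mark.parametrize("table,expected", [
        ((5, 4, 11, 49), 0.026),
        ((8, 20, 3, 40), 0.019),
        ((3, 20, 0, 40), 0.045),
    ])
    def test_published_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, abs=1e-3)

    def test_all_zero_table(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_transposition_and_swap_invariance(self, table):
        a, b, c, d = table
        p = fisher_exact_2x2(a, b, c, d)
        assert fisher_exact_2x2(a, c, b, d) == pytest.approx(p, rel=1e-9)  # transpose
        assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-9)  # row swap
        assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, rel=1e-9)  # col swap

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestMKTest:
    def test_published_ratios_and_p(self):
        r = mk_test(MKTable(Pn=5, Ps=4, Dn=11, Ds=49))
        assert r.ratio_poly == pytest.approx(1.25)
        assert r.ratio_div == pytest.approx(0.22, abs=0.005)
        assert r.p == pytest.approx(0.026, abs=1e-3)

    def test_second_locus_ratios(self):
        r = mk_test(MKTable(Pn=8, Ps=20, Dn=3, Ds=40))
        assert r.ratio_poly == pytest.approx(0.4)
        assert r.ratio_div == pytest.approx(0.075)
        assert r.p == pytest.approx(0.019, abs=1e-3)

    def test_indel_channel(self):
        r = mk_test(MKTable(Pn=8, Ps=20, Dn=3, Ds=40, P_indel=3, D_indel=0))
        assert r.p_indel == pytest.approx(0.045, abs=1e-3)

    def test_neutral_symmetric_table(self):
        r = mk_test(MKTable(Pn=6, Ps=6, Dn=6, Ds=6))
        assert r.ratio_poly == r.ratio_div == 1.0
        assert r.p == 1.0

    def test_zero_denominators_undefined(self):
        r = mk_test(MKTable(Pn=3, Ps=0, Dn=0, Ds=0))
        assert np.isnan(r.ratio_poly) and np.isnan(r.ratio_div)

    def test_neutral_generator_type_one_error_not_inflated(self):
        # tables with identical expected A/S ratios for polymorphism and
        # divergence; Fisher on discrete tables is conservative, so the
        # realized rejection rate must not exceed nominal (binomial slack)
        rng = np.random.default_rng(42)
        n_sim, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_sim):
            ratio = rng.uniform(0.2, 0.8)
            pn = rng.binomial(30, ratio)
            dn = rng.binomial(60, ratio)
            p = mk_test(MKTable(Pn=int(pn), Ps=int(30 - pn),
                                Dn=int(dn), Ds=int(60 - dn))).p
            rejections += p < alpha
        rate = rejections / n_sim
        assert rate <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_sim)


class TestClassifySites:
    def test_no_variation_all_zero(self):
        coding = CodingAlignment(["ATGGGTCTT" ] * 4, "ATGGGTCTT")
        t = classify_sites(coding)
        assert (t.Pn, t.Ps, t.Dn, t.Ds, t.P_indel, t.D_indel) == (0, 0, 0, 0, 0, 0)

    def test_silent_third_position_polymorphism(self):
        # CTT -> CTC, both Leu
        ingroup = ["CTT", "CTT", "CTT", "CTC"]
        t = classify_sites(CodingAlignment(ingroup, "CTT"))
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (0, 1, 0, 0)

    def test_replacement_divergence(self):
        # ingroup fixed GGT (Gly), outgroup AGT (Ser)
        t = classify_sites(CodingAlignment(["GGT"] * 4, "AGT"))
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (0, 0, 1, 0)

    def test_polymorphic_site_not_double_counted_as_divergence(self):
        # site segregates in the ingroup AND differs from the outgroup:
        # counted as polymorphism only
        t = classify_sites(CodingAlignment(["CTT", "CTT", "CTT", "CTC"], "CTG"))
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (0, 1, 0, 0)

    def test_codons_with_missing_sit_out(self):
        t = classify_sites(CodingAlignment(["GGT", "GGN", "GGT", "GGT"], "GGT"))
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (0, 0, 0, 0)

    def test_frame_violation_errors(self):
        with pytest.raises(FrameError):
            CodingAlignment(["GGTA"] * 3, "GGTA")

    def test_published_table_recovered_from_generator(self):
        coding = simulate_coding_locus(12, 120, Pn=5, Ps=4, Dn=11, Ds=49, seed=1)
        t = classify_sites(coding)
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (5, 4, 11, 49)

    @pytest.mark.parametrize("seed", range(5))
    def test_generator_truth_recovery_with_indels(self, seed):
        t = classify_sites(simulate_coding_locus(
            10, 100, Pn=3, Ps=7, Dn=2, Ds=12, seed=seed, P_indel=3, D_indel=2))
        assert (t.Pn, t.Ps, t.Dn, t.Ds, t.P_indel, t.D_indel) == (3, 7, 2, 12, 3, 2)

    def test_internal_stop_warns_not_fails(self):
        with pytest.warns(UserWarning, match="stop"):
            CodingAlignment(["TAAGGT"] * 3, "TAAGGT")


def oracle_tajimas_d(seqs):
    """Independently coded constants-from-scratch reference."""
    import math

    cols = [c for c in zip(*seqs) if set(c) <= set("ACGT")]
    n = len(seqs)
    S = sum(1 for c in cols if len(set(c)) > 1)
    if S == 0:
        return float("nan")
    pi = 0.0
    for i, j in itertools.combinations(range(n), 2):
        pi += sum(1 for c in cols if c[i] != c[j])
    pi /= n * (n - 1) / 2
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k**2 for k in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(["ACGT" * 10] * 5))

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            tajimas_d(["ACGT"] * 3)

    def test_matches_independent_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            L = int(rng.integers(50, 300))
            base = rng.choice(list("ACGT"), size=L)
            seqs = []
            for _i in range(n):
                s = base.copy()
                k = int(rng.integers(0, max(2, L // 20)))
                pos = rng.choice(L, size=k, replace=False)
                for p in pos:
                    s[p] = "ACGT"[int(rng.integers(4))]
                seqs.append("".join(s))
            expected = oracle_tajimas_d(seqs)
            got = tajimas_d(seqs)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_complete_deletion_of_missing_columns(self):
        # one strain has an N in a monomorphic column: the whole column is
        # dropped for everyone, so D equals D on the explicitly pruned locus
        seqs = ["CCGTAC", "ACGTAC", "AAGTAC", "AAGNAC", "AAGTAC"]
        pruned = [s[:3] + s[4:] for s in seqs]
        assert tajimas_d(seqs) == pytest.approx(tajimas_d(pruned), abs=1e-12)

    def test_balanced_locus_positive(self):
        # two deep haplotype classes at intermediate frequency skew D positive
        seqs = simulate_balanced_locus(12, 1000, (6, 6), divergence=10, seed=0)
        assert tajimas_d(seqs) > 0


def oracle_ng86(seq_a, seq_b):
    """Independent NG86 site/difference counting via full path enumeration."""
    syn_sites_a = syn_sites_b = 0.0
    sd = nd = 0.0
    for c0 in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[c0:c0 + 3], seq_b[c0:c0 + 3]
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue
        for codon, acc in ((ca, "a"), (cb, "b")):
            aa = translate_codon(codon)
            s = 0.0
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1:]
                    if translate_codon(mut) == aa and aa != "*":
                        s += 1 / 3
            if acc == "a":
                syn_sites_a += s
            else:
                syn_sites_b += s
        diff = [i for i in range(3) if ca[i] != cb[i]]
        paths = []
        stop_paths = []
        for order in itertools.permutations(diff):
            cur, s, n, hit = ca, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if translate_codon(nxt) == translate_codon(cur):
                    s += 1
                else:
                    n += 1
                if translate_codon(nxt) == "*":
                    hit = True
                cur = nxt
            (stop_paths if hit else paths).append((s, n))
        if diff:
            pool = paths or stop_paths
            sd += np.mean([p[0] for p in pool])
            nd += np.mean([p[1] for p in pool])
    S = (syn_sites_a + syn_sites_b) / 2
    return S, sd, nd


class TestKaKs:
    def test_identical_sequences(self):
        r = ka_ks("ATGGGTCTT", "ATGGGTCTT")
        assert r.Ka == 0.0 and r.Ks == 0.0 and np.isnan(r.ratio)

    def test_single_synonymous_change(self):
        a = "GGT" * 30
        b = "GGC" + "GGT" * 29
        r = ka_ks(a, b)
        assert r.Ka == 0.0 and r.Ks > 0.0

    def test_single_nonsynonymous_change(self):
        a = "GGT" * 30
        b = "AGT" + "GGT" * 29
        r = ka_ks(a, b)
        assert r.Ks == 0.0 and r.Ka > 0.0 and np.isnan(r.ratio)

    def test_random_pairs_match_site_counting_oracle(self, rng):
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if translate_codon(a + b + c) != "*"]
        for _ in range(10):
            a = "".join(rng.choice(codons, 300))
            b = list(a)
            # mutate ~3% of positions
            for pos in rng.choice(900, size=30, replace=False):
                b[pos] = "ACGT"[int(rng.integers(4))]
            b = "".join(b)
            S, sd, nd = oracle_ng86(a, b)
            N = 3 * 300 - S
            ps, pn = sd / S, nd / N
            exp_ks = -0.75 * np.log(1 - 4 * ps / 3)
            exp_ka = -0.75 * np.log(1 - 4 * pn / 3)
            r = ka_ks(a, b)
            assert r.Ks == pytest.approx(exp_ks, abs=1e-9)
            assert r.Ka == pytest.approx(exp_ka, abs=1e-9)

    def test_purifying_regime_ratio_below_one(self, rng):
        # many synonymous, few nonsynonymous changes -> Ka/Ks << 1
        a = "GGT" * 200
        b = ["GGC"] * 40 + ["AGT"] * 2 + ["GGT"] * 158
        r = ka_ks(a, "".join(b))
        assert 0 < r.ratio < 0.2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(FrameError):
            ka_ks("GGTGGT", "GGT")


class TestTwoLocusIndependence:
    def test_exact_independence(self):
        chi2, p = two_locus_independence([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_value(self):
        chi2, p = two_locus_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert p < 1e-4

    def test_zero_marginal_undefined(self):
        chi2, p = two_locus_independence([[5, 0], [7, 0]])
        assert np.isnan(chi2) and np.isnan(p)

    def test_matches_formula_oracle(self, rng):
        for _ in range(25):
            obs = rng.integers(1, 30, size=(2, 2))
            n = obs.sum()
            exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
            expected_chi2 = float(((obs - exp) ** 2 / exp).sum())
            chi2, p = two_locus_independence(obs)
            assert chi2 == pytest.approx(expected_chi2, rel=1e-12)

    def test_yates_flag_reduces_statistic(self):
        plain, _ = two_locus_independence([[12, 3], [4, 11]])
        corrected, _ = two_locus_independence([[12, 3], [4, 11]], correction=True)
        assert corrected < plain
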