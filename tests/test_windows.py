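"""Windowed diversity statistics against brute-force pair-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from qtlsweep import windows as pw
from qtlsweep.alignment import OutgroupSequence, SiteFilterConfig, site_table

from conftest import make_alignment, make_site


def brute_force_pi(columns):
    """Mean pairwise difference summed over sites, by explicit enumeration.

    ``columns`` is a list of per-site base lists (N excluded beforehand).
    Returns the window total (not per site).
    """
    total = 0.0
    for bases in columns:
        pairs = list(itertools.combinations(bases, 2))
        if not pairs:
            continue
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total


class TestThetaPi:
    def test_two_sequences_one_difference(self):
        sites = [make_site(1, {"p": {"A": 1, "G": 1}})]
        sites += [make_site(i, {"p": {"A": 2}}) for i in range(2, 101)]
        pi, l_valid = pw.theta_pi_window(sites, "p")
        assert l_valid == 100
        assert pi == pytest.approx(0.01)

    def test_identical_sequences(self):
        sites = [make_site(i, {"p": {"A": 4}}) for i in range(1, 51)]
        pi, _ = pw.theta_pi_window(sites, "p")
        assert pi == 0.0

    def test_half_frequency_site(self):
        # n=4, counts (2,2): per-site pi = 2*2*2/12 = 2/3; L_valid = 10
        sites = [make_site(1, {"p": {"A": 2, "G": 2}})]
        sites += [make_site(i, {"p": {"A": 4}}) for i in range(2, 11)]
        pi, _ = pw.theta_pi_window(sites, "p")
        assert pi == pytest.approx((2.0 / 3.0) / 10.0)

    def test_zero_valid_sites_flagged(self):
        assert math.isnan(pw.theta_pi_window([], "p")[0])


class TestThetaW:
    def test_pairwise_sample(self):
        # n=2 everywhere: a(2)=1, S=3, L=100
        sites = [make_site(i, {"p": {"A": 1, "G": 1}}) for i in range(1, 4)]
        sites += [make_site(i, {"p": {"A": 2}}) for i in range(4, 101)]
        w, _ = pw.theta_w_window(sites, "p")
        assert w == pytest.approx(0.03)

    def test_no_segregating_sites(self):
        sites = [make_site(i, {"p": {"C": 5}}) for i in range(1, 11)]
        assert pw.theta_w_window(sites, "p")[0] == 0.0

    def test_harmonic_denominator(self):
        # n=5, S=4, L=200: theta_w = 4 / (a(5)*200), a(5) = 1+1/2+1/3+1/4
        sites = [make_site(i, {"p": {"A": 4, "G": 1}}) for i in range(1, 5)]
        sites += [make_site(i, {"p": {"A": 5}}) for i in range(5, 201)]
        w, _ = pw.theta_w_window(sites, "p")
        a5 = 1 + 0.5 + 1 / 3 + 0.25
        assert w == pytest.approx(4.0 / (a5 * 200))


class TestDxy:
    def test_no_divergence(self):
        sites = [make_site(i, {"p": {"A": 3}}, outgroup="A") for i in range(1, 101)]
        assert pw.dxy_window(sites, "p")[0] == 0.0

    def test_fixed_differences(self):
        sites = [make_site(i, {"p": {"A": 3}}, outgroup="G") for i in range(1, 11)]
        sites += [make_site(i, {"p": {"A": 3}}, outgroup="A") for i in range(11, 101)]
        assert pw.dxy_window(sites, "p")[0] == pytest.approx(0.10)

    def test_polymorphic_site_fractional_weight(self):
        sites = [make_site(1, {"p": {"A": 3, "G": 1}}, outgroup="G")]
        dxy, l_valid = pw.dxy_window(sites, "p")
        assert (dxy, l_valid) == (pytest.approx(3.0 / 4.0), 1)

    def test_outgroup_n_sites_dropped(self):
        sites = [make_site(1, {"p": {"A": 2}}, outgroup="N"),
                 make_site(2, {"p": {"A": 2}}, outgroup="G")]
        dxy, l_valid = pw.dxy_window(sites, "p")
        assert l_valid == 1 and dxy == pytest.approx(1.0)


class TestTajimaD:
    def test_all_singletons_negative(self):
        sites = [make_site(i, {"p": {"A": 9, "G": 1}}) for i in range(1, 11)]
        assert pw.tajima_d_window(sites, "p") < 0

    def test_frozen_value(self):
        # n=10, S=16, window-total pi = 3.888 -> D = -1.446 (constants
        # recomputed independently from their closed forms)
        k = pw.tajima_constants(10)
        var = k["e1"] * 16 + k["e2"] * 16 * 15
        d = (3.888 - 16 / k["a1"]) / math.sqrt(var)
        assert d == pytest.approx(-1.446, abs=1e-3)
        # the window route agrees: 16 sites at n=10 whose pi terms sum to pi_total
        # use 8 singletons and 8 doubletons: pi = 8*(2*9/90) + 8*(2*2*8/90)
        sites = [make_site(i, {"p": {"A": 9, "G": 1}}) for i in range(8)]
        sites += [make_site(8 + i, {"p": {"A": 8, "G": 2}}) for i in range(8)]
        pi_total = 8 * (2 * 9 / 90) + 8 * (2 * 2 * 8 / 90)
        expected = (pi_total - 16 / k["a1"]) / math.sqrt(var)
        assert pw.tajima_d_window(sites, "p") == pytest.approx(expected)

    def test_no_segregating_sites_is_undefined(self):
        sites = [make_site(1, {"p": {"A": 5}})]
        assert math.isnan(pw.tajima_d_window(sites, "p"))


class TestFst:
    def test_identical_monomorphic_undefined(self):
        sites = [make_site(i, {"a": {"A": 4}, "b": {"A": 4}}) for i in range(1, 6)]
        rec = pw.fst_nei_window(sites, "a", "b")
        assert math.isnan(rec.fst)

    def test_fixed_differences_give_one(self):
        sites = [make_site(i, {"a": {"A": 4}, "b": {"G": 4}}) for i in range(1, 6)]
        assert pw.fst_nei_window(sites, "a", "b").fst == pytest.approx(1.0)

    def test_single_site_against_brute_force(self):
        # pop a = {A,A,G,G}, pop b = {A,A,A,A}
        sites = [make_site(1, {"a": {"A": 2, "G": 2}, "b": {"A": 4}})]
        rec = pw.fst_nei_window(sites, "a", "b")
        a_seqs, b_seqs = ["A", "A", "G", "G"], ["A", "A", "A", "A"]
        hb = np.mean([x != y for x in a_seqs for y in b_seqs])
        hw_a = np.mean([x != y for x, y in itertools.combinations(a_seqs, 2)])
        hw_b = 0.0
        expected = (hb - 0.5 * (hw_a + hw_b)) / hb
        assert rec.fst == pytest.approx(expected)

    def test_self_split_near_zero(self):
        """A population split at random into halves has FST centred on zero."""
        from qtlsweep.simulate import SimulationConfig, simulate_neutral_haplotypes
        from qtlsweep.alignment import SiteRecord

        rng = np.random.default_rng(11)
        vals = []
        for rep in range(200):
            cfg = SimulationConfig(n=12, length=4000, theta=0.01, rho=0.0, seed=3000 + rep)
            hap = simulate_neutral_haplotypes(cfg)
            if hap.segsites == 0:
                continue
            perm = rng.permutation(12)
            ha, hb = hap.matrix[perm[:6]], hap.matrix[perm[6:]]
            sites = []
            for k in range(hap.segsites):
                ca = {"A": int((ha[:, k] == 0).sum()), "G": int((ha[:, k] == 1).sum())}
                cb = {"A": int((hb[:, k] == 0).sum()), "G": int((hb[:, k] == 1).sum())}
                sites.append(make_site(k + 1, {
                    "a": {b: c for b, c in ca.items() if c},
                    "b": {b: c for b, c in cb.items() if c}}))
            rec = pw.fst_nei_window(sites, "a", "b")
            if math.isfinite(rec.fst):
                vals.append(rec.fst)
        assert abs(np.mean(vals)) < 0.02


class TestBruteForceAgreement:
    """All window statistics vs exhaustive pairwise enumeration on tiny alignments."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_alignments(self, seed):
        rng = np.random.default_rng(seed)
        n, L = rng.integers(3, 7), rng.integers(10, 51)
        rows = ["".join(rng.choice(list("ACGN"), L, p=[0.5, 0.4, 0.05, 0.05]))
                for _ in range(n)]
        aln = make_alignment(rows)
        og = OutgroupSequence("".join(rng.choice(list("AC"), L)))
        cfg = SiteFilterConfig(max_missing_frac=0.5)
        records = site_table(aln, og, cfg)
        usable = [r for r in records if r.status in ("monomorphic", "biallelic")]

        # oracle works directly on the character matrix
        cols = []
        for r in usable:
            bases = [b for b in aln.seq_matrix[:, r.coord - 1] if b in "ACGT"]
            cols.append((r, bases))

        pi_cols = [bases for r, bases in cols if len(bases) >= 2]
        expected_pi = brute_force_pi(pi_cols) / len(pi_cols)
        got_pi, _ = pw.theta_pi_window(records, "pop")
        assert got_pi == pytest.approx(expected_pi, rel=1e-12)

        expected_w = sum(
            1.0 / pw.harmonic(len(bases))
            for r, bases in cols
            if len(bases) >= 2 and len(set(bases)) == 2
        ) / len(pi_cols)
        got_w, _ = pw.theta_w_window(records, "pop")
        assert got_w == pytest.approx(expected_w, rel=1e-12)

        dxy_cols = [
            (r, bases) for r, bases in cols
            if r.outgroup_base != "N" and len(bases) >= 1
        ]
        expected_dxy = sum(
            np.mean([b != r.outgroup_base for b in bases]) for r, bases in dxy_cols
        ) / len(dxy_cols)
        got_dxy, _ = pw.dxy_window(records, "pop")
        assert got_dxy == pytest.approx(expected_dxy, rel=1e-12)


class TestNeutralRecovery:
    def test_diversity_estimators_unbiased_small_scale(self):
        """Quick neutral recovery at reduced size (the full-scale version
        lives in the acceptance suite)."""
        from qtlsweep import validation

        r = validation.estimator_recovery(n_reps=60, length=20_000, seed=17)
        assert abs(r.mean_theta_pi - r.theta_true) < 3 * r.se_theta_pi
        assert abs(r.mean_theta_w - r.theta_true) < 3 * r.se_theta_w
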