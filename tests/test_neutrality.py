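"""Neutrality statistics against brute-force oracles and null calibration."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import popgenstat

from mitopop import coalsim
from mitopop.iohap import Alignment
from mitopop.neutrality import (
    ON_S,
    ON_THETA,
    attach_pvalue,
    fu_li_d,
    fus_fs,
    neutrality_pvalue,
    r2,
    significance_stars,
    tajimas_d,
)


# ---------------------------------------------------------------------------
# independent oracle implementations (straight from the published formulas,
# coded separately from the library: per-site loops, no shared helpers)
# ---------------------------------------------------------------------------

def _site_columns(aln):
    return [[s[j] for s in aln.seqs] for j in range(aln.length)]


def oracle_tajima_d(aln):
    n = aln.n
    S = sum(1 for col in _site_columns(aln) if len(set(col)) > 1)
    diffs = [sum(a != b for a, b in zip(s1, s2))
             for s1, s2 in itertools.combinations(aln.seqs, 2)]
    k = sum(diffs) / len(diffs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_singletons(aln, outgroup=None):
    """(eta, eta_s, eta_e, U) by per-column tallies."""
    n = aln.n
    eta = eta_s = eta_e = 0
    U = [0] * n
    for j, col in enumerate(_site_columns(aln)):
        states = sorted(set(col))
        if len(states) < 2:
            continue
        eta += len(states) - 1
        for s in states:
            if col.count(s) == 1:
                eta_s += 1
                U[col.index(s)] += 1
                if outgroup is not None and s != outgroup[j]:
                    eta_e += 1
    return eta, eta_s, eta_e, U


def oracle_fu_li_dstar(aln):
    n = aln.n
    eta, eta_s, _, _ = oracle_singletons(aln)
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    an1 = a + 1.0 / n
    d = c + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )
    v = ((n / (n - 1)) ** 2 * b + a**2 * d
         - 2 * (n * a * (a + 1)) / (n - 1) ** 2) / (a**2 + b)
    u = (n / (n - 1)) * (a - n / (n - 1)) - v
    return ((n / (n - 1)) * eta - a * eta_s) / math.sqrt(u * eta + v * eta**2)


def oracle_fu_li_d(aln, outgroup):
    n = aln.n
    eta, _, eta_e, _ = oracle_singletons(aln, outgroup)
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v = 1 + a**2 / (b + a**2) * (c - (n + 1) / (n - 1))
    u = a - 1 - v
    return (eta - a * eta_e) / math.sqrt(u * eta + v * eta**2)


def oracle_r2(aln):
    n = aln.n
    S = sum(1 for col in _site_columns(aln) if len(set(col)) > 1)
    diffs = [sum(a != b for a, b in zip(s1, s2))
             for s1, s2 in itertools.combinations(aln.seqs, 2)]
    k = sum(diffs) / len(diffs)
    _, _, _, U = oracle_singletons(aln)
    return math.sqrt(sum((u - k / 2) ** 2 for u in U) / n) / S


def oracle_fs_by_ewens_enumeration(n, K, theta):
    """P(K=k) = |s(n,k)| theta^k / theta^(n) via the exact recurrence."""
    row = [1]
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    denom = 1.0
    for i in range(n):
        denom *= theta + i
    pk = [row[k] * theta**k / denom for k in range(n + 1)]
    upper = sum(pk[K:])
    return math.log(upper / (1 - upper))


# ---------------------------------------------------------------------------
# statistic values
# ---------------------------------------------------------------------------

class TestStatisticOracles:
    def test_tajimas_d_matches_constants_oracle(self, toy_five, neutral_sample):
        for aln in (toy_five, neutral_sample):
            assert tajimas_d(aln).value == pytest.approx(
                oracle_tajima_d(aln), rel=1e-12
            )

    def test_tajimas_d_matches_dendropy(self, neutral_sample):
        fasta = "".join(f">{i}\n{s}\n"
                        for i, s in zip(neutral_sample.ids, neutral_sample.seqs))
        cm = dendropy.DnaCharacterMatrix.get(data=fasta, schema="fasta")
        assert tajimas_d(neutral_sample).value == pytest.approx(
            popgenstat.tajimas_d(cm), rel=1e-9
        )

    def test_fu_li_dstar_matches_tally_oracle(self, toy_five, neutral_sample):
        for aln in (toy_five, neutral_sample):
            assert fu_li_d(aln).value == pytest.approx(
                oracle_fu_li_dstar(aln), rel=1e-12
            )

    def test_fu_li_d_with_outgroup_matches_tally_oracle(self, toy_five):
        outgroup = "AATGCTACGTTA"  # same length, polarises the singletons
        res = fu_li_d(toy_five, outgroup_sequence=outgroup)
        assert res.name == "FuLiD"
        assert res.value == pytest.approx(
            oracle_fu_li_d(toy_five, outgroup), rel=1e-12
        )

    def test_r2_matches_tally_oracle(self, toy_five, neutral_sample):
        for aln in (toy_five, neutral_sample):
            assert r2(aln).value == pytest.approx(oracle_r2(aln), rel=1e-12)

    def test_fs_matches_ewens_enumeration_small_n(self):
        # n=4: two haplotypes of the four sequences identical
        aln = Alignment.from_records(
            [("a", "AAAA"), ("b", "AAAT"), ("c", "AAAT"), ("d", "CAAT")]
        )
        res = fus_fs(aln)
        diffs = [sum(x != y for x, y in zip(s1, s2))
                 for s1, s2 in itertools.combinations(aln.seqs, 2)]
        theta = sum(diffs) / len(diffs)
        assert res.value == pytest.approx(
            oracle_fs_by_ewens_enumeration(4, 3, theta), rel=1e-10
        )

    def test_undefined_when_monomorphic(self):
        aln = Alignment.from_records([(f"x{i}", "ACGT") for i in range(5)])
        assert not tajimas_d(aln).defined
        assert not fu_li_d(aln).defined
        assert not r2(aln).defined
        fs = fus_fs(aln)
        assert not fs.defined

    def test_single_haplotype_fs_flagged_infinite(self):
        # polymorphism present in a gap column only: k=0 under complete deletion
        aln = Alignment.from_records(
            [("a", "A-GT"), ("b", "ACGT"), ("c", "AAGT"), ("d", "ATGT")]
        )
        res = fus_fs(aln)
        assert not res.defined

    def test_reordering_invariance(self, neutral_sample):
        perm = np.random.default_rng(0).permutation(neutral_sample.n)
        shuffled = Alignment.from_records(
            [(neutral_sample.ids[i], neutral_sample.seqs[i]) for i in perm]
        )
        for fn in (tajimas_d, fu_li_d, fus_fs, r2):
            assert fn(shuffled).value == pytest.approx(
                fn(neutral_sample).value, rel=1e-12
            )


# ---------------------------------------------------------------------------
# null behaviour and p-values
# ---------------------------------------------------------------------------

class TestNullCalibration:
    def test_neutral_means_near_zero(self):
        rng = np.random.default_rng(8)
        model = coalsim.DemographyModel.constant(theta=5.0, n=30)
        D, Ds = [], []
        for _ in range(300):
            aln, _ = coalsim.simulate_dataset(model, seed=rng)
            d = tajimas_d(aln)
            if d.defined:
                D.append(d.value)
            ds = fu_li_d(aln)
            if ds.defined:
                Ds.append(ds.value)
        assert -0.2 < np.mean(D) < 0.1
        assert -0.25 < np.mean(Ds) < 0.15

    def test_expansion_direction(self, expansion_sample, neutral_sample):
        assert tajimas_d(expansion_sample).value < -1.0
        assert fus_fs(expansion_sample).value < -5.0

    def test_expansion_r2_smaller_than_constant(self):
        rng = np.random.default_rng(4)
        exp_model = coalsim.DemographyModel.stepwise_expansion(
            theta0=0.0, theta1=16.98, tau=4.56, n=30
        )
        con_model = coalsim.DemographyModel.constant(theta=5.0, n=30)
        r_exp, r_con = [], []
        for _ in range(150):
            a1, _ = coalsim.simulate_dataset(exp_model, seed=rng)
            a2, _ = coalsim.simulate_dataset(con_model, seed=rng)
            v1, v2 = r2(a1), r2(a2)
            if v1.defined:
                r_exp.append(v1.value)
            if v2.defined:
                r_con.append(v2.value)
        assert np.mean(r_exp) < np.mean(r_con)

    def test_pvalue_self_consistency_at_median(self, neutral_sample):
        obs = tajimas_d(neutral_sample)
        res = neutrality_pvalue(obs, neutral_sample, n_sims=2000, seed=1)
        # draw the null once more and check the observed quantile agrees
        res2 = neutrality_pvalue(obs, neutral_sample, n_sims=2000, seed=2)
        assert abs(res.p_value - res2.p_value) < 0.05
        assert 0.0 <= res.p_value <= 1.0

    def test_pvalue_monotone_in_observed_value(self, neutral_sample):
        from dataclasses import replace

        obs = tajimas_d(neutral_sample)
        ps = []
        for shift in (-1.0, 0.0, 1.0):
            fake = replace(obs, value=obs.value + shift)
            ps.append(neutrality_pvalue(fake, neutral_sample, n_sims=1000,
                                        seed=3).p_value)
        assert ps[0] <= ps[1] <= ps[2]

    def test_expansion_fs_significant(self, expansion_sample):
        res = attach_pvalue(fus_fs, expansion_sample, n_sims=500, seed=7)
        assert res.p_value < 0.05

    def test_conditioning_on_theta_also_calibrated(self, neutral_sample):
        obs = tajimas_d(neutral_sample)
        res = neutrality_pvalue(obs, neutral_sample, n_sims=500, seed=5,
                                conditioning=ON_THETA)
        assert 0.0 <= res.p_value <= 1.0
        assert res.conditioning == ON_THETA

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == ""
        assert significance_stars(None) == ""
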