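"""Site statistics: residue proportions, the count null model, Fisher's
exact test against an exact enumeration oracle, and substitution
enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from phosnp.core_io import DomainAnnotation, PhosphoSite, SnpRecord
from phosnp.site_statistics import (
    bh_adjust,
    domain_location_fraction,
    expected_count_distribution,
    fisher_exact,
    permute_phospho_labels,
    proportions_from_counts,
    residue_proportions,
    substitution_enrichment,
)
from phosnp.variant_mapping import ProteinEffect


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration (independent oracle)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    if 0 in (r1, r2, c1, b + d):
        return 1.0
    obs = comb(r1, a) * comb(r2, c1 - a)
    num = sum(
        comb(r1, k) * comb(r2, c1 - k)
        for k in range(max(0, c1 - r2), min(c1, r1) + 1)
        if comb(r1, k) * comb(r2, c1 - k) <= obs
    )
    return float(Fraction(num, comb(n, c1)))


class TestResidueProportions:
    def test_published_counts(self):
        props = proportions_from_counts({"S": 5078, "T": 1482, "Y": 618})
        assert props.display["S"] == 70.7
        assert props.display["Y"] == 8.6
        assert props.percent["S"] == pytest.approx(70.7439, abs=1e-3)
        assert props.percent["T"] == pytest.approx(20.6464, abs=1e-3)
        assert props.percent["Y"] == pytest.approx(8.6096, abs=1e-3)

    def test_equal_counts(self):
        props = proportions_from_counts({"S": 1, "T": 1, "Y": 1})
        assert all(v == 33.3 for v in props.display.values())

    def test_single_residue_type(self):
        props = proportions_from_counts({"S": 10, "T": 0, "Y": 0})
        assert props.display == {"S": 100.0, "T": 0.0, "Y": 0.0}

    def test_empty_site_set_errors(self):
        with pytest.raises(ValueError):
            residue_proportions([])


class TestDomainLocation:
    def test_boundary_positions_are_inside(self):
        sites = [
            PhosphoSite("p", 10, "S", "experimental"),
            PhosphoSite("p", 20, "S", "experimental"),
            PhosphoSite("p", 21, "S", "experimental"),
        ]
        domains = [DomainAnnotation("p", 10, 20, "D1")]
        df = domain_location_fraction(sites, domains).set_index("residue")
        assert df.loc["S", "n_inside"] == 2  # both boundaries, not 21

    def test_no_domains_all_outside(self):
        sites = [PhosphoSite("p", 3, "T", "experimental")]
        df = domain_location_fraction(sites, []).set_index("residue")
        assert df.loc["T", "n_inside"] == 0

    def test_uniform_sites_match_domain_coverage(self):
        rng = np.random.default_rng(4)
        length = 1000
        seq_sites = []
        domains = [DomainAnnotation("p", 101, 400, "D1")]  # 30% coverage
        for pos in rng.choice(length, size=400, replace=False):
            seq_sites.append(PhosphoSite("p", int(pos) + 1, "S", "experimental"))
        df = domain_location_fraction(seq_sites, domains).set_index("residue")
        assert df.loc["S", "fraction_inside"] == pytest.approx(0.30, abs=0.07)


class TestCountNull:
    def test_formula_arithmetic(self):
        proteome = {"a": "S" * 10, "b": "S" * 20}
        sites = [PhosphoSite("a", i, "S", "experimental") for i in (1, 2)] + [
            PhosphoSite("b", i, "S", "experimental") for i in (1, 2, 3, 4)
        ]
        null = expected_count_distribution(proteome, sites)
        assert null.p == pytest.approx(0.2)
        assert null.expected_count["a"] == pytest.approx(2.0)
        assert null.expected_count["b"] == pytest.approx(4.0)

    def test_conservation_is_exact(self, sim_small):
        null = expected_count_distribution(
            sim_small.proteome, sim_small.sites_experimental
        )
        assert null.expected_total_exact == null.total_sites  # exact rationals

    def test_constant_rate_sites_fit_binomial_null(self, sim_small):
        null = expected_count_distribution(
            sim_small.proteome, sim_small.sites_experimental
        )
        obs = null.observed_hist.astype(float)
        exp = null.expected_hist * obs.sum() / null.expected_hist.sum()
        # pool sparse tail bins for a valid chi-square
        while len(exp) > 2 and exp[-1] < 5:
            exp[-2] += exp[-1]
            obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        stat, p = sps.chisquare(obs, exp)
        assert p > 0.05

    def test_concentrated_sites_show_heavy_tail(self):
        proteome = {f"p{i}": "SSSSSSSSSS" for i in range(20)}
        sites = [PhosphoSite("p0", i, "S", "experimental") for i in range(1, 11)]
        null = expected_count_distribution(proteome, sites)
        # all sites on one protein: observed count at the tail exceeds expected
        assert null.observed_hist[10] == 1
        assert null.expected_hist[10] < 0.01

    def test_no_sty_errors(self):
        with pytest.raises(ValueError):
            expected_count_distribution({"p": "MKLV"}, [])


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected_p",
        [
            ([[2, 2], [2, 2]], 1.0),
            ([[3, 1], [1, 3]], 0.485714285714286),
            ([[0, 5], [5, 0]], 2 / 252),
        ],
    )
    def test_known_tables(self, table, expected_p):
        p, _ = fisher_exact(table)
        assert p == pytest.approx(expected_p, abs=1e-12)

    def test_odds_ratio_sample_estimate(self):
        _, odds = fisher_exact([[3, 1], [1, 3]])
        assert odds == 9.0

    def test_zero_margin_is_p1_with_undefined_or(self):
        p, odds = fisher_exact([[0, 0], [3, 4]])
        assert p == 1.0 and np.isnan(odds)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(1, 61))
            a, b, c, d = map(int, rng.multinomial(n, [0.25] * 4))
            p, _ = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)


class TestBhAdjust:
    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.5]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.5]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_empty_input(self):
        assert bh_adjust([]) == []

    def test_q_at_least_p_and_order_invariant(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        q = np.array(bh_adjust(list(p)))
        assert (q >= p - 1e-15).all()
        perm = rng.permutation(40)
        q_perm = np.array(bh_adjust(list(p[perm])))
        assert q_perm == pytest.approx(q[perm])


def _make_effect(pid, pos, ref, alt, accs=("a1",)):
    cls = "synonymous" if ref == alt else "nonsynonymous"
    return ProteinEffect(
        pid, pos, ref, alt, cls, frozenset(accs),
        SnpRecord("c", pos, "A", "G", frozenset(accs)),
    )


class TestSubstitutionEnrichment:
    def test_planted_excess_at_sites_is_flagged(self, sim_small):
        """T->N substitutions planted 5x more often at pT sites come out
        enriched after BH."""
        proteome = sim_small.proteome
        rng = np.random.default_rng(9)
        t_positions = [
            (pid, pos + 1)
            for pid, seq in proteome.items()
            for pos in range(len(seq))
            if seq[pos] == "T"
        ]
        sites = [
            PhosphoSite(pid, pos, "T", "experimental")
            for pid, pos in t_positions
            if rng.random() < 0.3
        ]
        site_keys = {(s.protein_id, s.position) for s in sites}
        effects = []
        for pid, pos in t_positions:
            rate = 0.25 if (pid, pos) in site_keys else 0.05
            if rng.random() < rate:
                effects.append(_make_effect(pid, pos, "T", "N"))
        df = substitution_enrichment(
            sites, effects, proteome, universe="phosphoproteins"
        )
        row = df[(df.from_residue == "T") & (df.to_symbol == "N")].iloc[0]
        assert row.significant
        assert row.direction == "enriched_in_phosphosites"

    def test_never_observed_pairs_are_not_tested(self, sim_small):
        sites = [PhosphoSite("P0001", pos + 1, aa, "experimental")
                 for pos, aa in enumerate(sim_small.proteome["P0001"])
                 if aa == "S"][:2]
        effects = [_make_effect("P0001", sites[0].position, "S", "N")]
        df = substitution_enrichment(
            sites, effects, sim_small.proteome, universe="phosphoproteins"
        )
        never = df[df.never_observed]
        assert (never.direction == "never_observed").all()
        assert never.p_value.isna().all()
        assert len(df[~df.never_observed]) >= 1

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            substitution_enrichment([], [], {"p": "MST"})

    def test_permuted_labels_control_type_one_error(self, sim_small):
        """With labels shuffled within residue type, p-values are roughly
        uniform and nothing survives BH."""
        proteome = sim_small.proteome
        rng = np.random.default_rng(21)
        effects = []
        for pid, seq in proteome.items():
            for pos0, aa in enumerate(seq):
                if aa in "STY" and rng.random() < 0.08:
                    effects.append(_make_effect(pid, pos0 + 1, aa, "N"))
        permuted = permute_phospho_labels(
            proteome, sim_small.sites_experimental, seed=3
        )
        df = substitution_enrichment(
            permuted, effects, proteome, universe="phosphoproteins"
        )
        assert not df["significant"].any()
        pvals = df.loc[~df.never_observed, "p_value"].to_numpy()
        ecdf_excess = max(
            (np.searchsorted(np.sort(pvals), t, side="right") / len(pvals)) - t
            for t in (0.05, 0.1, 0.25, 0.5)
        )
        assert ecdf_excess < 0.25  # discrete p-values sit at or above uniform
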