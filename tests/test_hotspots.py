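"""Hotspot scan: window scoring and deduplication, background simulation,
detection, run merging and the domain-overlap permutation test."""

import numpy as np
import pytest

from phosnp.core_io import DomainAnnotation, PhosphoSite
from phosnp.hotspots import (
    BackgroundDistribution,
    HotspotConfig,
    HotspotRun,
    HotspotWindow,
    detect_hotspots,
    domain_overlap_test,
    extract_profile,
    merge_runs,
    scan_windows,
    simulate_background,
)


def brute_force_windows(sequence, positions, winsize):
    """Independent oracle: all windows, dedup by identical S/T/Y set."""
    out = []
    prev_sty = None
    for start in range(1, len(sequence) - winsize + 2):
        span = range(start, start + winsize)
        sty = frozenset(p for p in span if sequence[p - 1] in "STY")
        score = sum(1 for p in positions if p in span)
        if sty != prev_sty or start == 1:
            out.append((start, float(score)))
        prev_sty = sty
    return out


class TestScanWindows:
    def test_counts_sites_in_window(self):
        seq = "S" * 20
        windows = scan_windows(seq, [1, 3, 5, 7, 9], 10)
        assert windows[0] == (1, 5.0)

    def test_duplicate_sty_set_windows_counted_once(self):
        # S/T/Y only at positions 5 and 8; windows starting at 2,3 see {5,8}
        seq = "AAAAS" + "AAS" + "AAAAAAA"
        windows = dict(scan_windows(seq, [5], 4))
        assert 2 in windows and 3 not in windows

    def test_predicted_mode_sums_scores(self):
        seq = "ASATASAAAA"
        windows = scan_windows(seq, {2: 1.2, 4: -0.3, 6: 2.0}, 10, mode="predicted")
        assert windows[0][1] == pytest.approx(2.9)

    def test_short_protein_yields_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert scan_windows("MST", [2], 10) == []
        assert "shorter" in caplog.text

    def test_matches_brute_force_oracle_on_random_proteins(self):
        rng = np.random.default_rng(17)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            n = int(rng.integers(12, 80))
            seq = "".join(rng.choice(aas, size=n))
            sty = [i + 1 for i, a in enumerate(seq) if a in "STY"]
            positions = [p for p in sty if rng.random() < 0.4]
            w = int(rng.integers(3, 12))
            assert scan_windows(seq, positions, w) == brute_force_windows(
                seq, positions, w
            )


@pytest.fixture(scope="module")
def profile(sim_small):
    return extract_profile(sim_small.proteome, sites=sim_small.sites_experimental)


class TestBackground:
    def test_fixed_seed_is_bit_identical(self, profile):
        config = HotspotConfig(winsize=10, n_background_proteomes=20, seed=5)
        bg1 = simulate_background(profile, config)
        bg2 = simulate_background(profile, config)
        assert np.array_equal(bg1.hist, bg2.hist)
        assert bg1.n_windows == bg2.n_windows

    def test_mean_score_matches_independent_simulation(self, profile):
        """Background mean agrees with a small pure-Python resimulation of
        the same null (binomial phosphorylation of sampled proteins)."""
        config = HotspotConfig(winsize=10, n_background_proteomes=50, seed=5)
        bg = simulate_background(profile, config)
        rng = np.random.default_rng(99)
        aas = "STY" + "A" * 17  # categories; only S/T/Y identity matters
        comp_sty = [profile.composition[i] for i in (15, 16, 19)]
        p_other = 1 - sum(comp_sty)
        probs = comp_sty + [p_other / 17] * 17
        scores = []
        for _ in range(2000):
            length = int(rng.choice(profile.lengths))
            seq = "".join(rng.choice(list(aas), size=length, p=probs))
            positions = [
                i + 1
                for i, a in enumerate(seq)
                if a in "STY" and rng.random() < profile.phospho_prob[a]
            ]
            scores.extend(s for _, s in scan_windows(seq, positions, 10))
        assert bg.mean_score == pytest.approx(
            float(np.mean(scores)), rel=0.15
        )

    def test_default_background_sizes_by_mode(self):
        assert HotspotConfig(mode="experimental").n_background_proteomes == 10_000
        assert HotspotConfig(mode="predicted").n_background_proteomes == 1_000

    def test_zero_sty_profile_errors(self, profile):
        import dataclasses

        comp = profile.composition.copy()
        comp[[15, 16, 19]] = 0.0
        bad = dataclasses.replace(profile, composition=comp / comp.sum())
        with pytest.raises(ValueError):
            simulate_background(bad, HotspotConfig(n_background_proteomes=1))


class TestDetection:
    def test_planted_hotspot_detected(self, sim_small):
        from phosnp.synthetic_data import PlantedHotspot, SimulationConfig, simulate

        config = SimulationConfig(
            n_proteins=60, seed=42, snp_rate=0.0,
            planted_hotspots=(PlantedHotspot(3, 50, 10, 6),),
        )
        data = simulate(config)
        hs_config = HotspotConfig(
            winsize=10, n_background_proteomes=300, seed=42
        )
        windows = detect_hotspots(
            data.proteome, data.sites_experimental, hs_config
        )
        assert any(
            w.protein_id == "P0004" and w.start <= 50 <= w.start + 9
            for w in windows
        )

    def test_zero_score_window_never_significant(self, sim_small):
        config = HotspotConfig(winsize=10, n_background_proteomes=20, seed=1)
        windows = detect_hotspots(sim_small.proteome, [], config)
        assert windows == []

    def test_scores_recount_from_sites(self, sim_small):
        """Recount invariant: reported scores equal a direct recount."""
        from phosnp.synthetic_data import PlantedHotspot, SimulationConfig, simulate

        config = SimulationConfig(
            n_proteins=40, seed=8, snp_rate=0.0,
            planted_hotspots=(PlantedHotspot(0, 30, 10, 6),),
        )
        data = simulate(config)
        windows = detect_hotspots(
            data.proteome, data.sites_experimental,
            HotspotConfig(winsize=10, n_background_proteomes=200, seed=8),
        )
        assert windows
        positions = {
            (s.protein_id, s.position) for s in data.sites_experimental
        }
        for w in windows:
            recount = sum(
                1 for p in range(w.start, w.start + w.winsize)
                if (w.protein_id, p) in positions
            )
            assert w.score == recount

    def test_adding_a_site_never_decreases_score(self, sim_small):
        """Monotonicity against a fixed background."""
        profile = extract_profile(
            sim_small.proteome, sites=sim_small.sites_experimental
        )
        config = HotspotConfig(winsize=10, n_background_proteomes=50, seed=2)
        bg = simulate_background(profile, config)
        sites = list(sim_small.sites_experimental)
        pid = sites[0].protein_id
        seq = sim_small.proteome[pid]
        free = [
            i + 1 for i, a in enumerate(seq)
            if a in "STY" and not any(
                s.protein_id == pid and s.position == i + 1 for s in sites
            )
        ]
        assert free
        before = dict(scan_windows(seq, [s.position for s in sites
                                         if s.protein_id == pid], 10))
        extra = free[0]
        after_positions = [s.position for s in sites if s.protein_id == pid]
        after_positions.append(extra)
        after = dict(scan_windows(seq, after_positions, 10))
        for start, score in before.items():
            covering = [
                s for s in after
                if s <= extra <= s + 9 and s == start
            ]
            assert after.get(start, score) >= score


class TestMergeRuns:
    def _win(self, start, winsize=10):
        return HotspotWindow("p", start, winsize, 4.0, 1e-4, 1e-2)

    def test_overlapping_windows_merge(self):
        runs = merge_runs([self._win(10), self._win(15)])
        assert [(r.start, r.end) for r in runs] == [(10, 24)]

    def test_adjacent_windows_merge(self):
        runs = merge_runs([self._win(10), self._win(20)])
        assert [(r.start, r.end) for r in runs] == [(10, 29)]

    def test_singleton_run_equals_window_span(self):
        runs = merge_runs([self._win(7)])
        assert [(r.start, r.end) for r in runs] == [(7, 16)]

    def test_output_runs_disjoint_and_non_adjacent(self):
        rng = np.random.default_rng(3)
        wins = [self._win(int(s)) for s in rng.integers(1, 200, size=40)]
        runs = merge_runs(wins)
        ordered = sorted(runs, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            assert b.start > a.end + 1


class TestDomainOverlap:
    def test_toy_intersection_counted(self):
        proteome = {"p": "A" * 40}
        runs = [HotspotRun("p", 5, 14, ())]
        domains = [DomainAnnotation("p", 10, 20, "D")]
        result = domain_overlap_test(runs, domains, proteome,
                                     n_permutations=500, seed=1)
        assert result["observed_overlap"] == 1

    def test_no_domains_gives_depletion_p_one(self):
        proteome = {"p": "A" * 40}
        runs = [HotspotRun("p", 5, 14, ())]
        result = domain_overlap_test(runs, [], proteome, n_permutations=100,
                                     seed=1)
        assert result["observed_overlap"] == 0
        assert result["p_depletion"] == 1.0

    def test_hotspots_inside_sparse_domains_look_enriched(self):
        """All hotspots inside domains covering 10% of residues: enrichment
        p small, depletion p near 1."""
        proteome = {f"p{i}": "A" * 200 for i in range(10)}
        domains = [DomainAnnotation(f"p{i}", 91, 110, "D") for i in range(10)]
        runs = [HotspotRun(f"p{i}", 95, 104, ()) for i in range(10)]
        result = domain_overlap_test(runs, domains, proteome,
                                     n_permutations=2000, seed=5)
        assert result["p_enrichment"] < 0.01
        assert result["p_depletion"] > 0.9
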