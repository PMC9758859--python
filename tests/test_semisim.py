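import numpy as np
import pandas as pd
import pytest

from solodmr import fixtures, semisim
from solodmr.methylome_io import MethylomeError, ProbeManifest


def _manifest_from_positions(positions, chrom="chr1"):
    ids = [f"p{i}" for i in range(len(positions))]
    return ProbeManifest(
        pd.DataFrame(
            {
                "chrom": pd.array([chrom] * len(positions), dtype="string"),
                "pos": pd.array(positions, dtype="Int64"),
                "strand": ["+"] * len(positions),
            },
            index=pd.Index(ids, name="probe_id"),
        )
    )


class TestFixedWindows:
    def test_hand_enumerated_k2(self):
        man = _manifest_from_positions([100, 300, 500, 900, 5000, 5100])
        wins = semisim.build_fixed_windows(man, k=2)
        spans = [(w[1], w[2]) for w in wins]
        assert spans == [(99, 300), (499, 900), (4999, 5100)]

    def test_hand_enumerated_k4_span_limit(self):
        man = _manifest_from_positions([100, 300, 500, 900, 5000, 5100, 5200, 5300])
        wins = semisim.build_fixed_windows(man, k=4)
        assert [(w[1], w[2]) for w in wins] == [(99, 900), (4999, 5300)]
        # a 4-run wider than the span cap is skipped probe by probe
        man2 = _manifest_from_positions([100, 300, 2000, 2100, 2200, 2300])
        wins2 = semisim.build_fixed_windows(man2, k=4)
        assert [(w[1], w[2]) for w in wins2] == [(1999, 2300)]

    def test_k1_gives_one_window_per_probe(self, small_manifest):
        wins = semisim.build_fixed_windows(small_manifest, k=1)
        assert len(wins) == len(small_manifest)

    def test_windows_non_overlapping(self, small_manifest):
        wins = semisim.build_fixed_windows(small_manifest, k=4)
        used = np.concatenate([w[3] for w in wins])
        assert len(used) == len(set(used))


class TestTrueRegionSelection:
    def test_selected_fraction_exact_and_deterministic(self, small_manifest):
        design = semisim.SimulationDesign(n_segments_per_chrom=1000, modified_fraction=0.1)
        wins = semisim.build_fixed_windows(small_manifest, k=4)
        l1 = semisim.select_true_regions(
            small_manifest, wins, design, np.random.default_rng(4)
        )
        l2 = semisim.select_true_regions(
            small_manifest, wins, design, np.random.default_rng(4)
        )
        assert np.array_equal(l1, l2)
        # the fraction of true windows tracks the modified fraction
        assert 0.05 <= l1.mean() <= 0.2

    def test_boundary_straddling_window_is_true(self):
        # chr spans [99, 20099): 1000 segments of 20 bp; window [1099,1121)
        # straddles segments 50 and 51 - selecting either labels it true
        positions = [100 + 20 * i for i in range(1001)]
        man = _manifest_from_positions(positions)
        wins = [("chr1", 1099, 1121, np.array([50, 51]))]
        design = semisim.SimulationDesign(n_segments_per_chrom=1000, modified_fraction=0.1)

        class PickFifty:
            def choice(self, n, size, replace):
                return np.array([51] + list(range(900, 900 + size - 1)))

        labels = semisim.select_true_regions(man, wins, design, PickFifty())
        assert labels[0]

    def test_short_chromosome_rejected(self):
        man = _manifest_from_positions([100, 200, 300, 400])
        design = semisim.SimulationDesign(n_segments_per_chrom=1000)
        with pytest.raises(MethylomeError, match="shorter"):
            semisim.select_true_regions(
                man, semisim.build_fixed_windows(man, k=2), design,
                np.random.default_rng(0),
            )


class TestApplyShift:
    def test_direction_rule(self):
        rng = np.random.default_rng(0)
        out = semisim.apply_shift(np.array([0.9, 0.1]), 0.05, 1e-12, rng)
        assert out[0] == pytest.approx(0.85, abs=1e-6)  # high side: subtract
        assert out[1] == pytest.approx(0.15, abs=1e-6)  # low side: add

    def test_zero_shift_is_identity(self):
        beta = np.array([0.2, 0.5, 0.8])
        out = semisim.apply_shift(beta, 0.0, 1e-15, np.random.default_rng(1))
        assert np.allclose(out, beta, atol=1e-12)

    def test_clipping(self):
        out = semisim.apply_shift(np.array([0.02, 0.99]), 0.2, 1e-12, np.random.default_rng(2))
        assert np.all((out >= 0) & (out <= 1))


class TestAucs:
    def test_perfect_separation(self):
        assert semisim.pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)
        assert semisim.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_roc_matches_pair_counting_oracle(self):
        scores = [0.9, 0.4, 0.35, 0.1]
        labels = [1, 0, 1, 0]
        # brute force over all positive/negative pairs: 3 of 4 ordered correctly
        assert semisim.roc_auc(scores, labels) == pytest.approx(0.75)

    def test_random_labels_give_half_roc(self, rng):
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert semisim.roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(MethylomeError, match="degenerate"):
            semisim.pr_auc([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def medium():
    spec = fixtures.FixtureSpec(n_probes=6000, n_samples=520, seed=13)
    man = fixtures.make_manifest(spec)
    return man, fixtures.make_controls(spec, man)


class TestRunSimulation:
    def test_deterministic_under_seed(self, medium):
        man, beta = medium
        design = semisim.SimulationDesign(n_controls=100, seed=9)
        s1 = semisim.run_simulation(beta, man, design)
        s2 = semisim.run_simulation(beta, man, design)
        assert s1.pr_aucs == s2.pr_aucs and s1.roc_aucs == s2.roc_aucs

    def test_strong_signal_is_nearly_perfect(self, medium):
        man, beta = medium
        design = semisim.SimulationDesign(
            signal_pct=0.40, noise_pct=0.05, n_controls=500, seed=9
        )
        s = semisim.run_simulation(beta, man, design)
        assert s.mean_pr_auc > 0.99
        assert s.method == "zscore"

    def test_signal_equal_to_noise_scores_at_prevalence(self, medium):
        man, beta = medium
        design = semisim.SimulationDesign(
            signal_pct=0.05, noise_pct=0.05, n_controls=100, seed=9
        )
        s = semisim.run_simulation(beta, man, design)
        prevalence = s.n_true_windows / s.n_windows
        assert s.mean_pr_auc == pytest.approx(prevalence, abs=0.05)
        assert s.mean_roc_auc == pytest.approx(0.5, abs=0.05)

    def test_signal_and_noise_monotonicity(self, medium):
        man, beta = medium
        cache = {}
        last = -1.0
        for signal in [0.10, 0.20, 0.30, 0.40]:
            d = semisim.SimulationDesign(
                signal_pct=signal, noise_pct=0.05, n_controls=100, seed=9
            )
            auc = semisim.run_simulation(beta, man, d, _cache=cache).mean_pr_auc
            assert auc >= last
            last = auc
        last = 2.0
        for noise in [0.02, 0.05, 0.10]:
            d = semisim.SimulationDesign(
                signal_pct=0.20, noise_pct=noise, n_controls=100, seed=9
            )
            auc = semisim.run_simulation(beta, man, d, _cache=cache).mean_pr_auc
            assert auc <= last
            last = auc

    def test_small_control_pool_switches_to_crawford_howell(self, medium):
        man, beta = medium
        design = semisim.SimulationDesign(
            signal_pct=0.30, noise_pct=0.05, n_controls=10, seed=9
        )
        s = semisim.run_simulation(beta, man, design)
        assert s.method == "crawford_howell"
        assert s.mean_pr_auc > 0.8

    def test_too_few_samples_rejected(self, medium):
        man, beta = medium
        with pytest.raises(MethylomeError, match="need"):
            semisim.run_simulation(
                beta, man, semisim.SimulationDesign(n_controls=600)
            )


class TestRunSweep:
    def test_single_point_matches_run_simulation(self, small_manifest, small_controls):
        base = semisim.SimulationDesign(n_controls=40, seed=21)
        table = semisim.run_sweep(
            small_controls, small_manifest, {"signal_pct": [0.30]}, base
        )
        direct = semisim.run_simulation(
            small_controls, small_manifest,
            semisim.SimulationDesign(n_controls=40, signal_pct=0.30, seed=21),
        )
        assert len(table) == 1
        assert table["mean_pr_auc"].iloc[0] == pytest.approx(direct.mean_pr_auc)
        assert table["seed"].iloc[0] == 21

    def test_grid_is_cartesian_with_seed_policy(self, small_manifest, small_controls):
        base = semisim.SimulationDesign(n_controls=30, seed=5)
        table = semisim.run_sweep(
            small_controls, small_manifest,
            {"signal_pct": [0.2, 0.3], "cpgs_per_window": [2, 4]}, base,
        )
        assert len(table) == 4
        assert list(table["seed"]) == [5, 6, 7, 8]
        assert set(zip(table["signal_pct"], table["cpgs_per_window"])) == {
            (0.2, 2), (0.2, 4), (0.3, 2), (0.3, 4),
        }
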