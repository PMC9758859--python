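import numpy as np
import pandas as pd
import pytest

from solodmr import dmr_calling as dc
from solodmr import fixtures
from solodmr.methylome_io import Blacklist, BetaMatrix, ProbeManifest, RegionSet


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


class TestRollingWindows:
    def test_hand_enumerated_oracle(self):
        man = _manifest_from_positions([100, 300, 500, 900, 5000, 5100, 5200])
        wins = dc.build_rolling_windows(man, span=1000, min_cpgs=4)
        assert len(wins) == 1
        assert wins[0].probe_ids == ("p0", "p1", "p2", "p3")
        assert (wins[0].start, wins[0].end) == (99, 900)

    def test_too_few_probes_gives_empty(self):
        man = _manifest_from_positions([100, 200, 300])
        assert dc.build_rolling_windows(man, span=1000, min_cpgs=4) == []

    def test_overlapping_candidates_merge_to_probe_union(self):
        # candidates anchored at 100 and 700 overlap (share p3, p4)
        man = _manifest_from_positions([100, 300, 700, 900, 1050, 1400, 1600])
        wins = dc.build_rolling_windows(man, span=1000, min_cpgs=4)
        assert len(wins) == 1
        assert wins[0].probe_ids == tuple(f"p{i}" for i in range(7))

    def test_windows_disjoint_sorted_and_merge_idempotent(self, small_manifest):
        wins = dc.build_rolling_windows(small_manifest, span=1000, min_cpgs=4)
        assert wins, "fixture should produce windows"
        for a, b in zip(wins, wins[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start  # non-overlapping
        assert all(w.n_probes >= 4 for w in wins)
        # re-merging the output's probe runs (in global coordinates) is a no-op
        offset, runs = 0, []
        for w in wins:
            runs.append((offset, offset + w.n_probes - 1))
            offset += w.n_probes + 1  # disjoint runs stay disjoint
        assert dc._merge_runs(runs) == runs


@pytest.fixture(scope="module")
def shifted_case(small_spec, small_manifest, small_controls):
    """A patient with one low-methylation cluster shifted up by 0.30."""
    params = fixtures.probe_params(small_spec)
    clusters = fixtures.cluster_ids(small_manifest)
    df = small_manifest.data
    target = None
    for cid in np.unique(clusters):
        members = df.index[clusters == cid]
        if len(members) >= 5 and (params.loc[members, "mean"] < 0.4).all():
            target = members
            break
    assert target is not None
    sub = df.loc[target]
    region = RegionSet(
        "target",
        [(str(sub["chrom"].iloc[0]), int(sub["pos"].min()) - 1, int(sub["pos"].max()))],
    )
    patient, modified = fixtures.make_patient(
        small_controls, small_manifest, region, shift=0.30, seed=5, spec=small_spec
    )
    assert set(modified) == set(target)
    return patient, region, list(target)


class TestCallDmrs:
    def test_recovers_implanted_region_and_only_it(
        self, shifted_case, small_controls, small_manifest
    ):
        patient, region, target = shifted_case
        dmrs = dc.call_dmrs(patient, small_controls, small_manifest)
        sig = [d for d in dmrs if d.significant]
        assert len(sig) == 1
        assert set(target) <= set(sig[0].window.probe_ids)
        assert sig[0].direction == "hyper"
        assert sig[0].median_delta_beta >= 0.10
        assert sig[0].p_aggregated < 0.01

    def test_patient_at_control_mean_yields_no_significant_dmrs(
        self, small_controls, small_manifest
    ):
        mean = pd.Series(
            small_controls.data.mean(axis=1), index=small_controls.probe_ids
        )
        dmrs = dc.call_dmrs(mean, small_controls, small_manifest)
        assert not any(d.significant for d in dmrs)

    def test_blacklisted_region_flagged_and_excluded(
        self, shifted_case, small_controls, small_manifest
    ):
        patient, _, target = shifted_case
        blacklist = Blacklist(frozenset({target[0]}))
        dmrs = dc.call_dmrs(
            patient, small_controls, small_manifest, blacklist=blacklist
        )
        hit = [d for d in dmrs if target[0] in d.window.probe_ids]
        assert len(hit) == 1 and hit[0].blacklisted
        assert not hit[0].significant
        assert hit[0].p_aggregated < 0.01  # still reported for audit

    def test_determinism(self, shifted_case, small_controls, small_manifest):
        patient, _, _ = shifted_case
        d1 = dc.call_dmrs(patient, small_controls, small_manifest)
        d2 = dc.call_dmrs(patient, small_controls, small_manifest)
        assert d1 == d2

    def test_probe_with_missing_control_left_out_of_windows(
        self, shifted_case, small_controls, small_manifest
    ):
        patient, _, target = shifted_case
        data = small_controls.data.copy()
        data.loc[target[0], data.columns[3]] = np.nan
        dmrs = dc.call_dmrs(patient, BetaMatrix(data), small_manifest)
        assert all(target[0] not in d.window.probe_ids for d in dmrs)
        sig = [d for d in dmrs if d.significant]
        assert len(sig) == 1  # remaining 4+ shifted probes still called
        assert set(sig[0].window.probe_ids) <= set(target)

    def test_monotone_in_shift(
        self, small_spec, small_manifest, small_controls, shifted_case
    ):
        _, region, target = shifted_case
        last_p = None
        for shift in [0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40]:
            patient, _ = fixtures.make_patient(
                small_controls, small_manifest, region, shift=shift, seed=5,
                spec=small_spec,
            )
            dmrs = dc.call_dmrs(patient, small_controls, small_manifest)
            hit = [d for d in dmrs if set(target) <= set(d.window.probe_ids)]
            assert len(hit) == 1
            if last_p is not None:
                assert hit[0].p_aggregated <= last_p + 1e-15
            last_p = hit[0].p_aggregated


class TestScoreRegionList:
    def test_target_region_significant_and_bonferroni_over_regions(
        self, shifted_case, small_controls, small_manifest, small_spec
    ):
        patient, region, target = shifted_case
        df = small_manifest.data
        clusters = fixtures.cluster_ids(small_manifest)
        extra = []
        for cid in np.unique(clusters):
            members = df.index[clusters == cid]
            if len(members) >= 4 and not set(members) & set(target):
                sub = df.loc[members]
                extra.append(
                    (str(sub["chrom"].iloc[0]), int(sub["pos"].min()) - 1, int(sub["pos"].max()))
                )
            if len(extra) == 42:
                break
        regions = RegionSet("loci", region.intervals + extra)
        dmrs = dc.score_region_list(patient, small_controls, small_manifest, regions)
        assert len(dmrs) == 43
        assert dmrs[0].p_aggregated < 0.01
        for d in dmrs:
            assert d.p_aggregated_adjusted == pytest.approx(
                min(1.0, d.p_aggregated * 43)
            )

    def test_region_without_probes_reported_untestable(
        self, shifted_case, small_controls, small_manifest
    ):
        patient, _, _ = shifted_case
        regions = RegionSet("empty", [("chr1", 1, 2)])
        dmrs = dc.score_region_list(patient, small_controls, small_manifest, regions)
        assert len(dmrs) == 1
        assert dmrs[0].n_probes == 0 and np.isnan(dmrs[0].p_aggregated)
        assert not dmrs[0].significant
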