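"""Window construction and single-patient DMR calling.

The genome-wide scan anchors a candidate window at every probe: the maximal
run of probes within ``span`` bp (default 1000) downstream of the anchor.
Candidates with at least ``min_cpgs`` probes (default 4) are kept and
overlapping candidates on a chromosome are merged into maximal regions;
aggregation then runs once per merged region, so no probe is double-counted.

A region is called significant when its Brown-aggregated p-value is below
``p_threshold`` (default 0.01), the absolute median per-probe beta difference
between patient and control mean is at least ``effect_threshold`` (default
0.10, i.e. 10 percentage points of methylation), and the region contains no
blacklisted probe. All regions are returned with their flags so thresholds
can be re-applied post hoc; blacklisted regions are flagged, not deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aggregation, cpg_tests
from .methylome_io import (
    BetaMatrix,
    Blacklist,
    MethylomeError,
    ProbeManifest,
    RegionSet,
    beta_to_m,
    filter_probes,
)

__all__ = ["Window", "Dmr", "DmrParams", "build_rolling_windows", "call_dmrs", "score_region_list"]


@dataclass(frozen=True)
class Window:
    """A run of probes on one chromosome; coordinates 0-based half-open,
    covering every member probe."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class Dmr:
    window: Window
    p_aggregated: float
    median_delta_beta: float
    direction: str  # hyper | hypo
    n_probes: int
    blacklisted: bool
    significant: bool
    p_aggregated_adjusted: float | None = None
    per_probe: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class DmrParams:
    span: int = 1000
    min_cpgs: int = 4
    p_threshold: float = 0.01
    effect_threshold: float = 0.10
    method: str = "auto"
    epsilon: float = 0.001
    sd_floor: float = 0.0


def _candidate_runs(pos: np.ndarray, span: int, min_cpgs: int) -> list[tuple[int, int]]:
    """Kept candidate index ranges [i, j] (inclusive) for one chromosome:
    anchor at each probe i, include probes with pos in [pos_i, pos_i + span)."""
    ends = np.searchsorted(pos, pos + span, side="left") - 1
    return [(i, int(j)) for i, j in enumerate(ends) if j - i + 1 >= min_cpgs]


def _merge_runs(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping (probe-index) ranges into maximal ranges."""
    merged: list[list[int]] = []
    for i, j in runs:  # runs are sorted by construction
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [tuple(r) for r in merged]


def build_rolling_windows(
    manifest: ProbeManifest, span: int = 1000, min_cpgs: int = 4
) -> list[Window]:
    """Merged candidate regions from a filtered manifest (see module docs).

    Merging is idempotent: re-running the merge on the output changes nothing.
    """
    windows: list[Window] = []
    df = manifest.sorted().data
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        pos = sub["pos"].to_numpy(dtype=int)
        kept = _candidate_runs(pos, span, min_cpgs)
        for i, j in _merge_runs(kept):
            probes = tuple(sub.index[i : j + 1])
            windows.append(
                Window(chrom=str(chrom), start=int(pos[i]) - 1, end=int(pos[j]), probe_ids=probes)
            )
    return windows


def _window_index_arrays(windows: list[Window], probe_index: pd.Index) -> list[np.ndarray]:
    lookup = pd.Series(np.arange(len(probe_index)), index=probe_index)
    return [lookup.loc[list(w.probe_ids)].to_numpy() for w in windows]


def _make_dmr(
    window: Window,
    p_agg: float,
    delta: np.ndarray,
    blacklisted: bool,
    params: DmrParams,
    p_adj: float | None = None,
) -> Dmr:
    med = float(np.median(delta))
    significant = (
        p_agg < params.p_threshold
        and abs(med) >= params.effect_threshold
        and not blacklisted
    )
    return Dmr(
        window=window,
        p_aggregated=float(p_agg),
        median_delta_beta=med,
        direction="hyper" if med >= 0 else "hypo",
        n_probes=window.n_probes,
        blacklisted=blacklisted,
        significant=significant,
        p_aggregated_adjusted=p_adj,
    )


def _prepare(patient_beta, controls_beta, manifest, params):
    """Shared front end: filter, align, transform, per-CpG testing.

    Returns (manifest of testable probes sorted, results frame restricted to
    them, patient beta, control beta frame, control M ndarray).
    """
    manifest, controls_beta = filter_probes(manifest, controls_beta)
    patient_beta = patient_beta.loc[patient_beta.index.isin(manifest.probe_ids)]
    shared = controls_beta.probe_ids.intersection(patient_beta.index)
    if len(shared) == 0:
        raise MethylomeError("patient and control probe universes do not overlap")
    order = manifest.sorted().probe_ids
    order = order[order.isin(shared)]
    manifest = manifest.subset(order)
    controls_beta = controls_beta.subset(order)
    patient_beta = patient_beta.loc[order]

    controls_m = beta_to_m(controls_beta, epsilon=params.epsilon)
    patient_m = pd.Series(
        np.log(
            np.clip(patient_beta.to_numpy(float), params.epsilon, 1 - params.epsilon)
            / (1 - np.clip(patient_beta.to_numpy(float), params.epsilon, 1 - params.epsilon))
        ),
        index=order,
    )
    results = cpg_tests.test_sample(
        patient_m,
        controls_m,
        method=params.method,
        patient_beta=patient_beta,
        controls_beta=controls_beta,
        sd_floor=params.sd_floor,
    )
    testable = results.index[results["testable"]]
    return (
        manifest.subset(testable),
        results.loc[testable],
        patient_beta.loc[testable],
        controls_beta.subset(testable),
        controls_m.data.loc[testable].to_numpy(float),
    )


def call_dmrs(
    patient_beta: pd.Series,
    controls_beta: BetaMatrix,
    manifest: ProbeManifest,
    params: DmrParams | None = None,
    blacklist: Blacklist | None = None,
) -> list[Dmr]:
    """Genome-wide single-patient DMR scan.

    Pipeline: probe filtering → logit transform → per-CpG outlier test
    (auto-selected by control count) → rolling-window construction over
    testable probes → Brown calibration and aggregation of raw per-CpG
    p-values per merged region → significance/effect/blacklist flags.
    """
    params = params or DmrParams()
    blacklist = blacklist or Blacklist()
    manifest, results, patient_beta, controls_beta, cm = _prepare(
        patient_beta, controls_beta, manifest, params
    )
    windows = build_rolling_windows(manifest, span=params.span, min_cpgs=params.min_cpgs)
    if not windows:
        raise MethylomeError("zero candidate windows (too few clustered probes)")
    idx_arrays = _window_index_arrays(windows, manifest.probe_ids)
    c, df = aggregation.calibrate_windows(cm, idx_arrays)
    p_win = aggregation.aggregate_windows(
        results["p_raw"].to_numpy(float), idx_arrays, c, df
    )
    delta = results["delta_beta"].to_numpy(float)
    dmrs = []
    for w, idx, p in zip(windows, idx_arrays, p_win):
        bl = any(pid in blacklist for pid in w.probe_ids)
        dmrs.append(_make_dmr(w, p, delta[idx], bl, params))
    return dmrs


def score_region_list(
    patient_beta: pd.Series,
    controls_beta: BetaMatrix,
    manifest: ProbeManifest,
    regions: RegionSet,
    params: DmrParams | None = None,
    blacklist: Blacklist | None = None,
) -> list[Dmr]:
    """Score a fixed list of regions (e.g. known imprinted loci).

    One Dmr per region over all testable probes inside it (no window
    construction); region-level Bonferroni adjustment over the number of
    regions tested. Regions without testable probes are returned untestable
    (p = NaN) rather than dropped.
    """
    params = params or DmrParams()
    blacklist = blacklist or Blacklist()
    manifest, results, patient_beta, controls_beta, cm = _prepare(
        patient_beta, controls_beta, manifest, params
    )
    df_man = manifest.data
    n_regions = len(regions)
    dmrs = []
    scored = []
    for chrom, start, end in regions:
        on_chrom = df_man.index[df_man["chrom"] == chrom]
        pos = df_man.loc[on_chrom, "pos"].to_numpy(int)
        # 1-based probe position p lies in 0-based half-open [start, end) iff start < p <= end
        inside = on_chrom[(pos > start) & (pos <= end)]
        window = Window(chrom=chrom, start=start, end=end, probe_ids=tuple(inside))
        if len(inside) == 0:
            dmrs.append(
                Dmr(
                    window=window,
                    p_aggregated=float("nan"),
                    median_delta_beta=float("nan"),
                    direction="hyper",
                    n_probes=0,
                    blacklisted=False,
                    significant=False,
                )
            )
            continue
        idx = [np.flatnonzero(manifest.probe_ids.isin(inside))]
        c, dof = aggregation.calibrate_windows(cm, idx)
        p = aggregation.aggregate_windows(
            results["p_raw"].to_numpy(float), idx, c, dof
        )[0]
        delta = results.loc[inside, "delta_beta"].to_numpy(float)
        bl = any(pid in blacklist for pid in inside)
        dmr = _make_dmr(window, p, delta, bl, params)
        dmrs.append(dmr)
        scored.append(dmr)
    for dmr in scored:
        dmr.p_aggregated_adjusted = min(1.0, dmr.p_aggregated * n_regions)
    return dmrs
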