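"""Semi-simulated benchmark for single-patient DMR detection.

Starting from a real (or realistic synthetic) control beta matrix, the
benchmark fabricates patients with known ground truth and scores the caller:

1. adjacent probes are grouped into non-overlapping fixed-size windows
   (k CpGs, span ≤ 1000 bp);
2. each chromosome is cut into 1000 equal segments and 10% of them are
   selected; windows overlapping a selected segment are the true DMRs;
3. 10 samples are drawn from the control population to be modified and
   compared against (a subsample of) the remaining controls;
4. every probe of a modified sample receives a Gaussian noise shift
   (mean = noise level, sd = 0.005); probes inside true windows instead
   receive a Gaussian signal shift (mean = signal level). Shifts are
   subtracted when beta > 0.5 and added otherwise, then clipped to [0, 1],
   so the net methylation defect of a true window over the background is
   signal − noise;
5. per-CpG outlier tests run on M values (Z-score, or Crawford–Howell when
   the comparison population is below 50), raw p-values are Brown-aggregated
   per window, and windows are ranked by aggregated p; detection is scored
   by the areas under the precision–recall and ROC curves against the
   true-window labels, averaged over the 10 modified samples.

Randomness derives from one master seed via named substreams (sample
selection, segment selection, then per-sample noise and signal draws), so a
run is fully reproducible from (inputs, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn import metrics

from . import aggregation
from .cpg_tests import select_test
from .methylome_io import BetaMatrix, MethylomeError, ProbeManifest, beta_to_m

__all__ = [
    "SimulationDesign",
    "PerformanceSummary",
    "build_fixed_windows",
    "select_true_regions",
    "apply_shift",
    "run_simulation",
    "run_sweep",
    "pr_auc",
    "roc_auc",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one semi-simulation run (proportions on the beta scale)."""

    noise_pct: float = 0.05
    signal_pct: float = 0.30
    shift_sd: float = 0.005
    n_modified_samples: int = 10
    n_controls: int = 500
    cpgs_per_window: int = 4
    max_span: int = 1000
    n_segments_per_chrom: int = 1000
    modified_fraction: float = 0.1
    method: str = "auto"
    epsilon: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_pct < 0.5 or not 0 <= self.signal_pct < 0.5:
            raise ValueError("noise_pct and signal_pct must lie in [0, 0.5)")
        if self.shift_sd <= 0:
            raise ValueError("shift_sd must be positive")
        if not 0 < self.modified_fraction < 1:
            raise ValueError("modified_fraction must lie in (0, 1)")


@dataclass
class PerformanceSummary:
    design: SimulationDesign
    pr_aucs: list[float]
    roc_aucs: list[float]
    n_windows: int
    n_true_windows: int
    method: str

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.pr_aucs))

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.roc_aucs))


# ---------------------------------------------------------------------------
# windows and truth
# ---------------------------------------------------------------------------


def build_fixed_windows(
    manifest: ProbeManifest, k: int, max_span: int = 1000
) -> list[tuple[str, int, int, np.ndarray]]:
    """Non-overlapping k-CpG windows by a greedy left-to-right scan.

    Per chromosome: take the next k adjacent probes; if their span is at most
    ``max_span`` bp emit the window and advance past it, otherwise advance
    the start by one probe. Returns tuples (chrom, start, end, probe row
    indices into the sorted manifest), coordinates 0-based half-open.
    """
    df = manifest.sorted().data
    out = []
    offset = 0
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        pos = sub["pos"].to_numpy(dtype=int)
        i = 0
        while i + k <= len(pos):
            if pos[i + k - 1] - pos[i] <= max_span:
                out.append(
                    (
                        str(chrom),
                        int(pos[i]) - 1,
                        int(pos[i + k - 1]),
                        np.arange(offset + i, offset + i + k),
                    )
                )
                i += k
            else:
                i += 1
        offset += len(pos)
    return out


def select_true_regions(
    manifest: ProbeManifest,
    windows: list[tuple[str, int, int, np.ndarray]],
    design: SimulationDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean true-DMR label per window.

    Each chromosome's probe-covered span is segmented into
    ``n_segments_per_chrom`` equal parts; ``modified_fraction`` of them are
    selected uniformly at random. A window overlapping at least one selected
    segment is a true window (windows straddling a boundary count).
    """
    df = manifest.sorted().data
    n_seg = design.n_segments_per_chrom
    n_pick = int(round(design.modified_fraction * n_seg))
    seg = {}
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        lo = int(sub["pos"].min()) - 1
        hi = int(sub["pos"].max())
        if hi - lo < n_seg:
            raise MethylomeError(
                f"{chrom}: probe span {hi - lo} bp is shorter than {n_seg} segments"
            )
        selected = np.zeros(n_seg, dtype=bool)
        selected[rng.choice(n_seg, size=n_pick, replace=False)] = True
        seg[str(chrom)] = (lo, (hi - lo) / n_seg, selected)
    labels = np.zeros(len(windows), dtype=bool)
    for wi, (chrom, start, end, _idx) in enumerate(windows):
        lo, length, selected = seg[chrom]
        first = int((start - lo) // length)
        last = min(int((end - 1 - lo) // length), len(selected) - 1)
        labels[wi] = selected[first : last + 1].any()
    return labels


def apply_shift(
    beta: np.ndarray,
    mean_shift: float,
    shift_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian methylation shift with the boundary-avoiding direction rule.

    Per value, δ ~ Normal(mean_shift, shift_sd); δ is subtracted when
    beta > 0.5 and added when beta ≤ 0.5, and the result is clipped to [0, 1].
    """
    beta = np.asarray(beta, dtype=float)
    delta = rng.normal(mean_shift, shift_sd, size=beta.shape)
    shifted = np.where(beta > 0.5, beta - delta, beta + delta)
    return np.clip(shifted, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def pr_auc(scores, labels) -> float:
    """Area under the precision–recall step curve (trapezoid over recall,
    ties grouped); higher score = more significant."""
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise MethylomeError("labels are degenerate (need >= 1 positive and negative)")
    precision, recall, _ = metrics.precision_recall_curve(labels, scores)
    return float(metrics.auc(recall, precision))


def roc_auc(scores, labels) -> float:
    """ROC AUC (equals the normalized Mann–Whitney U statistic)."""
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise MethylomeError("labels are degenerate (need >= 1 positive and negative)")
    return float(metrics.roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


def run_simulation(
    controls_beta: BetaMatrix,
    manifest: ProbeManifest,
    design: SimulationDesign,
    _cache: dict | None = None,
) -> PerformanceSummary:
    """One benchmark run (see module docstring).

    ``_cache`` is an optional dict shared between runs on the same inputs;
    rank transforms and window sets that depend only on (controls, design
    subsets) are memoized there to speed up parameter sweeps.
    """
    order = manifest.sorted().probe_ids
    order = order[order.isin(controls_beta.probe_ids)]
    manifest = manifest.subset(order)
    beta = controls_beta.data.loc[order]

    n_total = beta.shape[1]
    if design.n_controls + design.n_modified_samples > n_total:
        raise MethylomeError(
            f"need {design.n_controls + design.n_modified_samples} samples, "
            f"have {n_total}"
        )

    ss = np.random.SeedSequence(design.seed)
    ss_samples, ss_segments, ss_noise, ss_signal = ss.spawn(4)

    rng = np.random.default_rng(ss_samples)
    modified_cols = rng.choice(n_total, size=design.n_modified_samples, replace=False)
    rest = np.setdiff1d(np.arange(n_total), modified_cols)
    control_cols = rng.choice(rest, size=design.n_controls, replace=False)

    windows = build_fixed_windows(manifest, design.cpgs_per_window, design.max_span)
    if not windows:
        raise MethylomeError("no fixed windows could be built")
    labels = select_true_regions(
        manifest, windows, design, np.random.default_rng(ss_segments)
    )

    ctrl = beta.iloc[:, control_cols].to_numpy(dtype=float)
    eps = design.epsilon
    ctrl_m = np.log(np.clip(ctrl, eps, 1 - eps) / (1 - np.clip(ctrl, eps, 1 - eps)))
    mu = np.nanmean(ctrl_m, axis=1)
    sd = np.nanstd(ctrl_m, axis=1, ddof=1)

    # probes with any missing control value or zero control variance make a
    # window untestable; such windows leave both candidate and truth sets
    # (constancy checked as max == min: std of identical floats is not exactly 0)
    with np.errstate(invalid="ignore"):
        bad_probe = np.isnan(ctrl_m).any(axis=1) | (np.ptp(ctrl_m, axis=1) == 0)
    sd[bad_probe] = np.nan  # excluded probes: keep divide warnings quiet
    keep = np.array([not bad_probe[idx].any() for *_, idx in windows])
    windows = [w for w, k in zip(windows, keep) if k]
    labels = labels[keep]
    if not labels.any() or labels.all():
        raise MethylomeError("degenerate truth labels after the missing-value filter")
    idx_arrays = [idx for *_, idx in windows]
    true_probe = np.zeros(len(order), dtype=bool)
    true_probe[np.concatenate([idx for idx, lab in zip(idx_arrays, labels) if lab])] = True

    cache = _cache if _cache is not None else {}
    cal_key = ("cal", tuple(control_cols), design.cpgs_per_window, design.max_span, eps)
    if cal_key in cache:
        c, dof = cache[cal_key]
    else:
        c, dof = aggregation.calibrate_windows(ctrl_m, idx_arrays)
        cache[cal_key] = (c, dof)

    method = design.method
    if method == "auto":
        method = select_test(design.n_controls)

    from scipy import stats  # local import keeps module load light

    pr_list, roc_list = [], []
    noise_seeds = ss_noise.spawn(design.n_modified_samples)
    signal_seeds = ss_signal.spawn(design.n_modified_samples)
    for col, nss, sss in zip(modified_cols, noise_seeds, signal_seeds):
        original = beta.iloc[:, col].to_numpy(dtype=float)
        sample = apply_shift(
            original, design.noise_pct, design.shift_sd, np.random.default_rng(nss)
        )
        # the signal shift replaces the noise shift inside true windows, so the
        # net window effect over the background is signal − noise
        sig = apply_shift(
            original[true_probe],
            design.signal_pct,
            design.shift_sd,
            np.random.default_rng(sss),
        )
        sample[true_probe] = sig

        x = np.log(np.clip(sample, eps, 1 - eps) / (1 - np.clip(sample, eps, 1 - eps)))
        if method == "zscore":
            stat = (x - mu) / sd
            p = 2 * stats.norm.sf(np.abs(stat))
        else:
            n = design.n_controls
            stat = (x - mu) / (sd * np.sqrt(1 + 1 / n))
            p = 2 * stats.t.sf(np.abs(stat), df=n - 1)
        p_win = aggregation.aggregate_windows(p, idx_arrays, c, dof)
        scores = -np.log(np.clip(p_win, 1e-300, None))
        pr_list.append(pr_auc(scores, labels))
        roc_list.append(roc_auc(scores, labels))

    return PerformanceSummary(
        design=design,
        pr_aucs=pr_list,
        roc_aucs=roc_list,
        n_windows=len(windows),
        n_true_windows=int(labels.sum()),
        method=method,
    )


def run_sweep(
    controls_beta: BetaMatrix,
    manifest: ProbeManifest,
    grid: dict[str, list],
    base: SimulationDesign | None = None,
) -> pd.DataFrame:
    """Cartesian parameter sweep; one run per grid point.

    ``grid`` maps SimulationDesign field names to value lists. Seeds follow
    the policy seed_i = base.seed + i over the enumeration order, so a
    single-point grid reproduces ``run_simulation`` with that seed. Returns
    one row per run with all design fields and the mean/per-sample AUCs.
    """
    if not grid:
        raise MethylomeError("empty parameter grid")
    base = base or SimulationDesign()
    keys = list(grid)
    rows = []
    cache: dict = {}
    for i, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        design = replace(base, **dict(zip(keys, combo)), seed=base.seed + i)
        summary = run_simulation(controls_beta, manifest, design, _cache=cache)
        row = {f: getattr(design, f) for f in design.__dataclass_fields__}
        row.update(
            mean_pr_auc=summary.mean_pr_auc,
            mean_roc_auc=summary.mean_roc_auc,
            n_windows=summary.n_windows,
            n_true_windows=summary.n_true_windows,
            method=summary.method,
        )
        rows.append(row)
    return pd.DataFrame(rows)
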