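"""Per-CpG single-case outlier tests against a control population.

A single patient value is compared with the distribution of control values at
the same probe, on the M-value (logit) scale. Two tests are available:

* two-tailed Z-score — appropriate for large normative samples;
* two-tailed Crawford–Howell t test — a single-case t with n − 1 degrees of
  freedom and the (1 + 1/n) variance inflation, appropriate when fewer than
  50 controls are available.

Raw p-values feed the window aggregation step; Bonferroni-adjusted p-values
(using the array size as the number of tests) are reported per CpG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methylome_io import BetaMatrix, MValueMatrix, MethylomeError, beta_to_m

__all__ = [
    "ControlSummary",
    "zscore_test",
    "crawford_howell_test",
    "select_test",
    "bonferroni_adjust",
    "test_sample",
    "summarize_controls",
]

#: normative-sample size below which the Crawford-Howell test is preferred
CH_THRESHOLD = 50


@dataclass
class ControlSummary:
    """Per-probe control statistics: ``data`` is indexed by probe id with
    columns ``n`` (controls with a value), ``mu`` / ``sd`` (mean and sample
    sd of control M values, ddof=1), ``mean_beta`` (mean control beta) and
    ``testable`` (no missing control values and sd > 0)."""

    data: pd.DataFrame

    @property
    def testable_probes(self) -> pd.Index:
        return self.data.index[self.data["testable"]]


def summarize_controls(
    controls_m: MValueMatrix,
    controls_beta: BetaMatrix,
    sd_floor: float = 0.0,
) -> ControlSummary:
    m = controls_m.data.to_numpy(dtype=float)
    n_total = m.shape[1]
    if n_total < 2:
        raise MethylomeError("need at least 2 control samples")
    missing = np.isnan(m).any(axis=1)
    mu = np.nanmean(m, axis=1)
    sd = np.nanstd(m, axis=1, ddof=1)
    if sd_floor > 0:
        sd = np.maximum(sd, sd_floor)
    n = np.sum(~np.isnan(m), axis=1)
    mean_beta = np.nanmean(controls_beta.data.to_numpy(dtype=float), axis=1)
    with np.errstate(invalid="ignore"):
        not_constant = np.ptp(m, axis=1) > 0
    testable = ~missing & (sd > 0) & (n >= 2) & not_constant
    return ControlSummary(
        pd.DataFrame(
            {
                "n": n,
                "mu": mu,
                "sd": sd,
                "mean_beta": mean_beta,
                "testable": testable,
            },
            index=controls_m.probe_ids,
        )
    )


def zscore_test(x, mu, sd):
    """Two-tailed Z-score test: z = (x − mu)/sd, p = 2·Φ(−|z|).

    Accepts scalars or aligned arrays. ``sd`` must be positive.
    """
    x, mu, sd = np.asarray(x, float), np.asarray(mu, float), np.asarray(sd, float)
    if np.any(sd <= 0):
        raise MethylomeError("zscore_test requires sd > 0 (probe is untestable)")
    z = (x - mu) / sd
    p = 2 * stats.norm.sf(np.abs(z))
    return z, p


def crawford_howell_test(x, controls):
    """Two-tailed Crawford–Howell single-case t test.

    t = (x − mean)/(s·sqrt(1 + 1/n)) with s the sample sd (ddof=1) of the n
    controls; p is the two-tailed tail probability of Student's t with n − 1
    degrees of freedom. ``controls`` may be a 1-D vector (scalar x) or a
    probes × n matrix (vector x).
    """
    controls = np.asarray(controls, float)
    x = np.asarray(x, float)
    if controls.ndim == 1:
        controls = controls[None, :]
    n = controls.shape[1]
    if n < 2:
        raise MethylomeError("Crawford-Howell test needs at least 2 controls")
    mean = controls.mean(axis=1)
    s = controls.std(axis=1, ddof=1)
    if np.any(s <= 0):
        raise MethylomeError("controls are constant (s = 0): probe is untestable")
    t = (x - mean) / (s * np.sqrt(1 + 1 / n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    if t.shape == (1,) and np.ndim(x) == 0:
        return float(t[0]), float(p[0])
    return t, p


def select_test(n_controls: int, threshold: int = CH_THRESHOLD) -> str:
    """``crawford_howell`` when the normative sample is smaller than the
    threshold (strictly less than 50 by default), else ``zscore``."""
    if n_controls < 2:
        raise MethylomeError("need at least 2 controls")
    return "crawford_howell" if n_controls < threshold else "zscore"


def bonferroni_adjust(p_raw, m: int):
    """p_adjusted = min(1, m · p_raw)."""
    if m < 1:
        raise MethylomeError("number of tests m must be >= 1")
    return np.minimum(1.0, np.asarray(p_raw, float) * m)


def test_sample(
    patient_m: pd.Series,
    controls_m: MValueMatrix,
    method: str = "auto",
    patient_beta: pd.Series | None = None,
    controls_beta: BetaMatrix | None = None,
    n_tests: int | None = None,
    sd_floor: float = 0.0,
) -> pd.DataFrame:
    """Test one patient against a control population at every probe.

    Returns a DataFrame indexed by probe id with columns ``statistic``,
    ``p_raw``, ``p_adjusted``, ``delta_beta``, ``method`` and ``testable``.
    Probes with a missing patient value, any missing control value, or zero
    control variance are marked untestable (statistics NaN) and must be
    excluded from window aggregation downstream. ``delta_beta`` (patient
    beta − mean control beta) is computed on the beta scale when the beta
    inputs are supplied.
    """
    if not patient_m.index.equals(controls_m.probe_ids):
        raise MethylomeError("patient and control probe sets are not aligned")
    cm = controls_m.data.to_numpy(dtype=float)
    n_controls = cm.shape[1]
    if method == "auto":
        method = select_test(n_controls)
    if method not in ("zscore", "crawford_howell"):
        raise MethylomeError(f"unknown test method: {method!r}")

    x = patient_m.to_numpy(dtype=float)
    mu = np.nanmean(cm, axis=1) if n_controls else np.full(len(x), np.nan)
    sd = np.nanstd(cm, axis=1, ddof=1)
    if sd_floor > 0:
        sd = np.maximum(sd, sd_floor)
    with np.errstate(invalid="ignore"):
        not_constant = np.ptp(cm, axis=1) > 0  # std of identical floats is ~1e-16
    testable = ~np.isnan(x) & ~np.isnan(cm).any(axis=1) & (sd > 0) & not_constant
    if not testable.any():
        raise MethylomeError("zero testable probes")

    stat = np.full(len(x), np.nan)
    p_raw = np.full(len(x), np.nan)
    if method == "zscore":
        stat[testable], p_raw[testable] = zscore_test(
            x[testable], mu[testable], sd[testable]
        )
    else:
        stat[testable], p_raw[testable] = crawford_howell_test(
            x[testable], cm[testable]
        )

    m = n_tests if n_tests is not None else int(testable.sum())
    p_adj = np.where(np.isnan(p_raw), np.nan, np.minimum(1.0, p_raw * m))

    if patient_beta is not None and controls_beta is not None:
        delta_beta = patient_beta.to_numpy(dtype=float) - np.nanmean(
            controls_beta.data.to_numpy(dtype=float), axis=1
        )
    else:
        delta_beta = np.full(len(x), np.nan)

    return pd.DataFrame(
        {
            "statistic": stat,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "delta_beta": delta_beta,
            "method": method,
            "testable": testable,
        },
        index=patient_m.index,
    )
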