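"""Cohort-level outcomes, deviations versus a reference schedule, statistics.

``evaluate_cohort`` runs the full per-patient pipeline (schedule-conditional
accumulation -> DVH -> dose metrics -> EQD2 -> TCP/NTCP) and returns one
outcome record per patient x schedule.  ``deviation_vs_reference`` summarizes
each schedule's mean signed percent deviation from a reference (daily
imaging, by default).  ``compare_schedules`` runs the Shapiro-Wilk normality
check, the Friedman omnibus test over the related samples, and all pairwise
paired t-tests with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .dvh import compute_dvh, dvh_metric, DEFAULT_BIN_WIDTH
from .radiobiology import (
    DEFAULT_NTCP_PARAMS,
    DEFAULT_TCP_PARAMS,
    NtcpParams,
    TcpParams,
    dvh_to_eqd2,
    lkb_ntcp,
    poisson_tcp,
)
from .schedules import IGSchedule, default_schedules, select_and_accumulate

TARGET_METRICS = ("d95_PTVsc", "d95_PTVcw", "tcp_PTVsc", "tcp_PTVcw")
OAR_METRICS = ("dmean_heart", "dmean_lung_ipsi", "dmean_breast_contra",
               "ntcp_heart", "ntcp_lung_ipsi")


def evaluate_cohort(
    cohort: Cohort,
    schedules: Sequence[IGSchedule] | None = None,
    tcp_params: dict[str, TcpParams] | None = None,
    ntcp_params: dict[str, NtcpParams] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """One outcome record per patient x schedule.

    Columns: target D95s (Gy), OAR mean doses (Gy), per-target TCP and
    per-OAR NTCP (probabilities).  Deterministic given the cohort.
    """
    schedules = list(schedules) if schedules is not None else default_schedules(
        cohort.config.n_fractions, cohort.config.fractions_per_week
    )
    tcp_params = tcp_params or DEFAULT_TCP_PARAMS
    ntcp_params = ntcp_params or DEFAULT_NTCP_PARAMS
    n_fx = cohort.config.n_fractions

    rows = []
    for pid in cohort.patient_ids:
        fractions = cohort.fractions(pid)
        for schedule in schedules:
            acc = select_and_accumulate(fractions, schedule)
            row: dict = {"patient_id": pid, "schedule": schedule.name}
            for name, mask in cohort.masks.items():
                dvh = compute_dvh(acc, mask, bin_width)
                if name in tcp_params:
                    row[f"d95_{name}"] = dvh_metric(dvh, "D95")
                    dvh_bio = dvh_to_eqd2(dvh, n_fx, tcp_params[name].alpha_beta)
                    row[f"tcp_{name}"] = poisson_tcp(dvh_bio, tcp_params[name])
                else:
                    row[f"dmean_{name}"] = dvh_metric(dvh, "Dmean")
                    if name in ntcp_params:
                        dvh_bio = dvh_to_eqd2(dvh, n_fx, ntcp_params[name].alpha_beta)
                        row[f"ntcp_{name}"] = lkb_ntcp(dvh_bio, ntcp_params[name])
            rows.append(row)
    return pd.DataFrame(rows)


def _pivot(records: pd.DataFrame, metric: str) -> pd.DataFrame:
    if metric not in records.columns:
        raise ValueError(f"metric '{metric}' not among record columns")
    wide = records.pivot(index="patient_id", columns="schedule", values=metric)
    return wide


def deviation_vs_reference(
    records: pd.DataFrame, metric: str, reference: str = "DIG"
) -> pd.DataFrame:
    """Mean signed percent deviation of each schedule from the reference.

    For each patient: ``100 * (x_ref - x_sched) / x_ref`` (positive = worse
    than reference, for metrics where larger is better); averaged over
    patients, with the standard deviation as dispersion.  Patients with a
    zero reference value are excluded with a warning.
    """
    wide = _pivot(records, metric)
    if reference not in wide.columns:
        raise ValueError(f"reference schedule '{reference}' absent from records")
    ref = wide[reference]
    keep = ref != 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} patient(s) excluded from '{metric}' deviation: "
            f"zero reference value"
        )
        wide, ref = wide[keep], ref[keep]
    rows = []
    for sched in wide.columns:
        dev = 100.0 * (ref - wide[sched]) / ref
        rows.append({
            "schedule": sched,
            "metric": metric,
            "mean_pct_deviation": float(dev.mean()),
            "sd_pct_deviation": float(dev.std(ddof=1)) if len(dev) > 1 else 0.0,
            "n_patients": int(len(dev)),
        })
    return pd.DataFrame(rows)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a - b
    if np.allclose(diff, 0):
        return 0.0, 1.0  # identical samples: no evidence of a difference
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = sps.ttest_rel(a, b)
    if not np.isfinite(p):
        return float(t) if np.isfinite(t) else 0.0, 1.0
    return float(t), float(p)


def pairwise_paired_tests(wide: pd.DataFrame | np.ndarray,
                          columns: Sequence[str] | None = None) -> pd.DataFrame:
    """All pairwise paired t-tests with Bonferroni-adjusted p-values.

    ``wide`` is subjects x groups.  Adjustment multiplies each raw p by the
    number of comparisons, capped at 1.
    """
    if isinstance(wide, pd.DataFrame):
        columns = list(wide.columns)
        data = wide.to_numpy(dtype=float)
    else:
        data = np.asarray(wide, dtype=float)
        columns = list(columns) if columns is not None else [
            f"g{i}" for i in range(data.shape[1])
        ]
    pairs = list(itertools.combinations(range(len(columns)), 2))
    n_comp = len(pairs)
    rows = []
    for i, j in pairs:
        t, p = _paired_t(data[:, i], data[:, j])
        rows.append({
            "a": columns[i], "b": columns[j],
            "t": t, "p_raw": p, "p_adjusted": min(1.0, p * n_comp),
        })
    return pd.DataFrame(rows)


def compare_schedules(
    records: pd.DataFrame, metric: str, alpha: float = 0.05
) -> dict:
    """Omnibus and pairwise comparison of the schedules for one metric.

    Requires a balanced design (every patient evaluated under every
    schedule).  Returns the Friedman omnibus result, per-schedule
    Shapiro-Wilk p-values (logged as a caveat; the paired t-tests are run
    regardless), and the Bonferroni-adjusted pairwise table.
    """
    wide = _pivot(records, metric)
    if wide.isna().any().any():
        missing = wide.isna().sum().sum()
        raise ValueError(
            f"unbalanced design for '{metric}': {missing} missing "
            f"patient x schedule cells"
        )
    data = wide.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro = {}
        for col in wide.columns:
            x = wide[col].to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                shapiro[col] = 1.0  # constant sample: test undefined, no evidence
            else:
                shapiro[col] = float(sps.shapiro(x).pvalue)
        try:
            fr = sps.friedmanchisquare(*[data[:, j] for j in range(data.shape[1])])
            friedman = {"statistic": float(fr.statistic), "pvalue": float(fr.pvalue)}
        except (ValueError, ZeroDivisionError):
            friedman = {"statistic": 0.0, "pvalue": 1.0}
    if not np.isfinite(friedman["statistic"]):
        friedman = {"statistic": 0.0, "pvalue": 1.0}
    pairwise = pairwise_paired_tests(wide)
    pairwise["significant"] = pairwise["p_adjusted"] < alpha
    return {
        "metric": metric,
        "alpha": alpha,
        "friedman": friedman,
        "shapiro_pvalues": shapiro,
        "normality_rejected": any(p < alpha for p in shapiro.values()),
        "pairwise": pairwise,
    }
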