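"""End-to-end result tables, figures and the markdown summary."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cohort import Cohort
from .exposure import ExposureTable, exposure_report
from .schedules import IGSchedule, SCHEDULE_NAMES
from .stats import (
    TARGET_METRICS,
    OAR_METRICS,
    compare_schedules,
    deviation_vs_reference,
    evaluate_cohort,
)

REFERENCE_SCHEDULE = "DIG"


def run_evaluation(
    cohort: Cohort,
    schedules: list[IGSchedule],
    out_dir: str | Path,
    exposure_table: ExposureTable | None = None,
    reference: str = REFERENCE_SCHEDULE,
) -> Path:
    """Evaluate a cohort and write outcome, deviation, exposure and stats files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = evaluate_cohort(cohort, schedules)
    records.to_csv(out_dir / "outcomes.csv", index=False)

    metrics = [m for m in (*TARGET_METRICS, *OAR_METRICS) if m in records.columns]
    deviations = pd.concat(
        [deviation_vs_reference(records, m, reference) for m in metrics],
        ignore_index=True,
    )
    deviations.to_csv(out_dir / "deviations.csv", index=False)

    exposure = exposure_report(schedules, exposure_table, reference_name=reference)
    exposure.to_csv(out_dir / "exposure.csv", index=False)

    stats_summary = {"config_sha256": cohort.config.digest(),
                     "seed": cohort.config.seed,
                     "reference_schedule": reference,
                     "metrics": {}}
    for m in metrics:
        res = compare_schedules(records, m)
        stats_summary["metrics"][m] = {
            "friedman": res["friedman"],
            "shapiro_pvalues": res["shapiro_pvalues"],
            "normality_rejected": res["normality_rejected"],
            "pairwise": res["pairwise"].to_dict(orient="records"),
        }
    (out_dir / "stats.json").write_text(json.dumps(stats_summary, indent=1, sort_keys=True))
    return out_dir


def _schedule_order(names) -> list[str]:
    known = [n for n in SCHEDULE_NAMES if n in set(names)]
    extra = [n for n in names if n not in known]
    return known + extra


def write_report(results_dir: str | Path, out_dir: str | Path | None = None) -> Path:
    """Render figures and a markdown summary from evaluation outputs."""
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    required = ["outcomes.csv", "deviations.csv", "exposure.csv", "stats.json"]
    missing = [f for f in required if not (results_dir / f).is_file()]
    if missing:
        raise FileNotFoundError(
            f"missing evaluation outputs in {results_dir}: {', '.join(missing)}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    figures = out_dir / "figures"
    figures.mkdir(exist_ok=True)

    records = pd.read_csv(results_dir / "outcomes.csv")
    deviations = pd.read_csv(results_dir / "deviations.csv")
    exposure = pd.read_csv(results_dir / "exposure.csv")
    stats_summary = json.loads((results_dir / "stats.json").read_text())
    order = _schedule_order(records["schedule"].unique())

    def box(metric: str, title: str, fname: str) -> None:
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = [records.loc[records["schedule"] == s, metric] for s in order]
        ax.boxplot(groups, tick_labels=order)
        ax.set_title(title)
        ax.set_xlabel("IG schedule")
        fig.tight_layout()
        fig.savefig(figures / fname, dpi=120)
        plt.close(fig)

    for metric, title, fname in (
        ("d95_PTVcw", "Chest-wall PTV D95 (Gy)", "d95_ptvcw.png"),
        ("d95_PTVsc", "Supraclavicular PTV D95 (Gy)", "d95_ptvsc.png"),
        ("tcp_PTVcw", "Chest-wall PTV TCP", "tcp_ptvcw.png"),
        ("tcp_PTVsc", "Supraclavicular PTV TCP", "tcp_ptvsc.png"),
    ):
        if metric in records.columns:
            box(metric, title, fname)

    # exposure / cost bars
    exp = exposure.set_index("schedule").loc[order]
    cost_col = next(c for c in exp.columns if c.startswith("cost_"))
    dose_cols = [c for c in exp.columns if c.startswith("dose_")]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    x = np.arange(len(order))
    for i, col in enumerate(dose_cols):
        axes[0].bar(x + 0.35 * i, exp[col], width=0.35,
                    label=col.removeprefix("dose_").removesuffix("_mgy"))
    axes[0].set_xticks(x + 0.17, order)
    axes[0].set_ylabel("cumulative imaging dose (mGy)")
    axes[0].legend()
    axes[1].bar(x, exp[cost_col])
    axes[1].set_xticks(x, order)
    axes[1].set_ylabel(cost_col.replace("_", " "))
    fig.tight_layout()
    fig.savefig(figures / "exposure_cost.png", dpi=120)
    plt.close(fig)

    # deviation-vs-reference bars
    fig, ax = plt.subplots(figsize=(7, 4))
    for metric, grp in deviations.groupby("metric"):
        grp = grp.set_index("schedule").reindex(order)
        ax.plot(order, grp["mean_pct_deviation"].abs(), marker="o", label=metric)
    ax.set_ylabel("|mean % deviation| vs reference")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(figures / "deviation.png", dpi=120)
    plt.close(fig)

    summary = _summary_markdown(records, deviations, exposure, stats_summary, order)
    path = out_dir / "summary.md"
    path.write_text(summary)
    return path


def _summary_markdown(records, deviations, exposure, stats_summary, order) -> str:
    ref = stats_summary.get("reference_schedule", REFERENCE_SCHEDULE)
    lines = [
        "# Image-guidance schedule evaluation",
        "",
        f"- patients: {records['patient_id'].nunique()}",
        f"- schedules: {', '.join(order)}",
        f"- reference schedule: {ref}",
        f"- cohort config sha256: {stats_summary.get('config_sha256', 'n/a')}",
        f"- seed: {stats_summary.get('seed', 'n/a')}",
        "",
        "## Cohort means by schedule",
        "",
    ]
    means = records.groupby("schedule").mean(numeric_only=True).drop(
        columns=["patient_id"]).loc[order]
    lines.append("| schedule | " + " | ".join(means.columns) + " |")
    lines.append("|" + "---|" * (len(means.columns) + 1))
    for s, row in means.iterrows():
        lines.append(f"| {s} | " + " | ".join(f"{v:.4g}" for v in row) + " |")

    lines += ["", "## Imaging dose and cost", ""]
    lines.append("| " + " | ".join(exposure.columns) + " |")
    lines.append("|" + "---|" * len(exposure.columns))
    for _, row in exposure.iterrows():
        lines.append("| " + " | ".join(
            f"{v:.4g}" if isinstance(v, float) else str(v) for v in row) + " |")

    thrig = deviations[deviations["schedule"] == "THRIG"]
    if not thrig.empty and "THRIG" in order and ref in order:
        exp_idx = exposure.set_index("schedule")
        pct = exp_idx.loc["THRIG", "pct_of_reference"]
        lines += [
            "",
            f"## THRIG vs {ref} trade-off",
            "",
            "| metric | THRIG mean % deviation |",
            "|---|---|",
        ]
        for _, row in thrig.iterrows():
            lines.append(f"| {row['metric']} | {row['mean_pct_deviation']:.3f} |")
        lines += [
            "",
            f"THRIG delivers {pct:.1f}% of the {ref} imaging dose and cost.",
        ]
    lines.append("")
    return "\n".join(lines)
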