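"""Plain-text/Markdown rendering of a StatReport.

Mirrors the structure of a standard results write-up for this paradigm:
condition summaries (accuracy mean +/- SEM, precision, reach time), the
rank-test contrasts with T/U, z and p, correlation and slope tests, the
abbreviated first-25 repeat, and the individual-level battery where
applicable.
"""

from __future__ import annotations

from typing import Any, Mapping

__all__ = ["render_markdown"]


def _num(v: Any, digits: int = 4) -> str:
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:.{digits}g}"
    return str(v)


def _p(v: float) -> str:
    if v < 0.001:
        return "< .001"
    return f"{v:.3f}"


def _test_rows(tests: Mapping[str, Any]) -> list[str]:
    rows = []
    for name, t in tests.items():
        stat = t.get("statistic", t.get("observed_slope"))
        stat_name = t.get("statistic_name", "slope")
        n = t.get("n")
        rows.append(
            f"| {name} | {stat_name} = {_num(stat, 6)} | "
            f"{_num(t.get('z'), 4)} | {_p(t['p'])} | {n} |"
        )
    return rows


def render_markdown(report: Mapping[str, Any]) -> str:
    """Render a serialized StatReport (its ``to_dict`` form) as Markdown."""
    lines: list[str] = []
    lines.append(f"# Reaching assessment report — {report['experiment']}")
    lines.append("")
    lines.append(
        f"Design: **{report['design']}** | participants: "
        f"{report['n_participants']} | trials analyzed per condition: "
        f"{report['first_n'] or 'all'} | seed: {report.get('seed')}"
    )
    if report.get("config_hash"):
        lines.append(f"Config hash: `{report['config_hash']}`")
    lines.append("")

    lines.append("## Condition summaries")
    lines.append("")
    lines.append(
        "| condition | accuracy (deg, mean ± SEM) | precision (deg, mean ± SD) "
        "| reach time (ms, mean ± SD) | n |"
    )
    lines.append("|---|---|---|---|---|")
    for cond, g in report["group"].items():
        lines.append(
            f"| {cond} | {g['accuracy_mean_deg']:.2f} ± "
            f"{g['accuracy_sem_deg']:.2f} | {g['precision_mean_deg']:.2f} ± "
            f"{g['precision_sd_deg']:.2f} | {g['reach_time_mean_ms']:.0f} ± "
            f"{g['reach_time_sd_ms']:.0f} | {g['n']} |"
        )
    lines.append("")

    if report.get("tests"):
        lines.append("## Group-level tests")
        lines.append("")
        lines.append("| test | statistic | z | p | n |")
        lines.append("|---|---|---|---|---|")
        lines.extend(_test_rows(report["tests"]))
        lines.append("")

    if report.get("slopes"):
        lines.append("## Error-vs-trial slopes (deg/trial)")
        lines.append("")
        lines.append("| condition | mean slope | SD |")
        lines.append("|---|---|---|")
        for cond, s in report["slopes"].items():
            lines.append(f"| {cond} | {_num(s['mean'], 4)} | {_num(s['sd'], 4)} |")
        lines.append("")

    if report.get("group_first25"):
        lines.append("## First-25-trials repeat")
        lines.append("")
        lines.append("| condition | accuracy (deg, mean ± SEM) |")
        lines.append("|---|---|")
        for cond, g in report["group_first25"].items():
            lines.append(
                f"| {cond} | {g['accuracy_mean_deg']:.2f} ± "
                f"{g['accuracy_sem_deg']:.2f} |"
            )
        lines.append("")

    if report.get("per_participant"):
        lines.append("## Individual-level tests")
        lines.append("")
        for pid, battery in report["per_participant"].items():
            lines.append(f"### {pid}")
            lines.append("")
            lines.append("| test | statistic | z | p | n |")
            lines.append("|---|---|---|---|---|")
            lines.extend(_test_rows(battery))
            lines.append("")

    if report.get("normality"):
        lines.append("## Normality diagnostics (Shapiro-Wilk)")
        lines.append("")
        lines.append("| measure | W | p |")
        lines.append("|---|---|---|")
        for name, t in report["normality"].items():
            lines.append(f"| {name} | {_num(t['statistic'], 4)} | {_p(t['p'])} |")
        lines.append("")

    lines.append(f"Tests performed (no multiplicity correction): {report['n_tests']}")
    lines.append("")
    return "\n".join(lines)
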