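"""Results summary: group comparison rows and a plain-markdown report.

The comparison table mirrors the way two-group results are conventionally
reported: per metric, the lesioned-group mean, the sham mean, their
difference (lesioned minus sham, so deficits are negative), the test used
and its p-value.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import group_compare


def difference_of_means(mean_a: float, mean_b: float) -> float:
    """Group difference on the reported scale: mean_a - mean_b."""
    return mean_a - mean_b


def comparison_row(metric: str, a, b) -> dict:
    """One comparison-table row from two samples (a = lesioned, b = sham)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    test, statistic, p = group_compare(a, b)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return {
        "metric": metric,
        "group_a_mean": mean_a,
        "group_b_mean": mean_b,
        "diff": difference_of_means(mean_a, mean_b),
        "test": test,
        "statistic": statistic,
        "p": p,
    }


def comparison_table(samples: dict[str, tuple]) -> pd.DataFrame:
    """Comparison rows for several metrics: ``{metric: (a_values, b_values)}``."""
    return pd.DataFrame([comparison_row(m, a, b) for m, (a, b) in samples.items()])


def _edge_lines(edges_csv: Path, kind: str) -> list[str]:
    df = pd.read_csv(edges_csv)
    sel = df[df["direction"] == kind]
    if sel.empty:
        return ["- none"]
    return [
        f"- {r.region_a} -- {r.region_b} (dZ={r.delta_z:+.3f}, p={r.p:.4g})"
        for r in sel.itertuples()
    ]


def render_report(out_dir: str | Path) -> str:
    """Render a markdown summary of whatever stage outputs exist in out_dir.

    Stages whose outputs are absent are listed as "not run" rather than
    failing, so a partial pipeline still yields a readable report.
    """
    out_dir = Path(out_dir)
    lines = ["# lesionet run summary", ""]

    lines.append("## Behavioral comparisons (lesioned - sham)")
    beh = out_dir / "behavior_comparison.csv"
    if beh.exists():
        df = pd.read_csv(beh)
        for r in df.itertuples():
            lines.append(
                f"- {r.metric}: {r.group_a_mean:.2f} vs {r.group_b_mean:.2f} "
                f"(diff {r.diff:+.2f}, {r.test}, p={r.p:.4g})"
            )
    else:
        lines.append("- not run")
    lines.append("")

    lines.append("## Lateralization index means per ROI pair (ipsi/contra)")
    lat = out_dir / "lateralization_summary.csv"
    if lat.exists():
        df = pd.read_csv(lat)
        for r in df.itertuples():
            lines.append(
                f"- {r.pair}: ich {r.ich_mean:.3f} vs sham {r.sham_mean:.3f} "
                f"({r.test}, p={r.p:.4g})"
            )
    else:
        lines.append("- not run")
    lines.append("")

    lines.append("## Hematoma course")
    hem = out_dir / "hematoma_summary.csv"
    if hem.exists():
        df = pd.read_csv(hem)
        for r in df.itertuples():
            lines.append(f"- day {r.day}: mean {r.mean:.2f} mm3 (sd {r.sd:.2f}, n={r.n})")
    else:
        lines.append("- not run")
    lines.append("")

    for modality, label in (
        ("volume", "Atrophy-related network"),
        ("suvw", "Metabolic connectivity"),
    ):
        lines.append(f"## {label} (ich vs sham)")
        edges_csv = out_dir / f"edges_{modality}.csv"
        if edges_csv.exists():
            lines.append("Increased edges:")
            lines += _edge_lines(edges_csv, "increased")
            lines.append("Decreased edges:")
            lines += _edge_lines(edges_csv, "decreased")
        else:
            lines.append("- not run")
        lines.append("")

    return "\n".join(lines) + "\n"
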