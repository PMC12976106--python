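"""Contaminant profile reporting: percentage heatmap table and figure of merit.

The heatmap table shows, for the top-k contaminant groups, the percentage
of each group relative to the total filtered reads in each sample, with
per-column cumulative percentages (what the displayed groups jointly cover).
The figure of merit is the cumulative percentage of library reads covered
by the top-n groups as a function of n — the expected depletion payoff per
added LNA probe.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from riboblock.aggregate import AggregationResult, ContaminantGroup


@dataclass
class PercentMatrix:
    """Top-k group percentages per sample, plus per-column cumulative sums."""

    rows: list[str]  # group patterns, descending cross-sample abundance
    cols: list[str]  # sample ids
    values: np.ndarray  # shape (len(rows), len(cols)), percentages
    column_cumulative: np.ndarray  # shape (len(cols),)
    row_biotypes: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.rows, columns=self.cols)
        df.index.name = "pattern"
        return df


@dataclass
class FigureOfMerit:
    """Cumulative targeted percentage vs number of LNA targets."""

    set_size: np.ndarray  # 1..G
    cumulative_pct: np.ndarray  # mean over samples
    per_sample_curves: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        data = {"set_size": self.set_size, "mean_cumulative_pct": self.cumulative_pct}
        for sid, curve in sorted(self.per_sample_curves.items()):
            data[f"cumulative_pct_{sid}"] = curve
        return pd.DataFrame(data)


def _ranked_groups(result: AggregationResult) -> list[ContaminantGroup]:
    return sorted(result.groups, key=lambda g: (-g.total, g.pattern))


def percent_matrix(
    result: AggregationResult,
    totals: dict[str, int],
    top_k: int = 10,
) -> PercentMatrix:
    """Build the heatmap table for the ``top_k`` most abundant groups.

    value(g, s) = 100 * counts[g][s] / totals[s].  Ranking is recomputed
    from cross-sample totals, so the result does not depend on the order
    groups arrive in.  Raises ``ValueError`` for a sample with zero total.
    """
    zero = [s for s, t in sorted(totals.items()) if t <= 0]
    if zero:
        raise ValueError(f"samples with zero filtered-read totals: {zero}")
    groups = _ranked_groups(result)[:top_k]
    cols = sorted(totals)
    values = np.array(
        [[100.0 * g.counts.get(s, 0) / totals[s] for s in cols] for g in groups],
        dtype=float,
    ).reshape(len(groups), len(cols))
    return PercentMatrix(
        rows=[g.pattern for g in groups],
        cols=cols,
        values=values,
        column_cumulative=values.sum(axis=0),
        row_biotypes=[g.dominant_biotype for g in groups],
    )


def figure_of_merit(result: AggregationResult, totals: dict[str, int]) -> FigureOfMerit:
    """Cumulative per-sample percentage curves over groups ranked by abundance.

    The headline curve is the mean across samples; per-sample curves are
    kept alongside.  The curve is non-decreasing and its terminal value is
    the mean total grouped percentage.
    """
    if not result.groups:
        raise ValueError("figure of merit requires at least one group")
    groups = _ranked_groups(result)
    cols = sorted(totals)
    pct = np.array(
        [[100.0 * g.counts.get(s, 0) / totals[s] for s in cols] for g in groups],
        dtype=float,
    )
    cum = np.cumsum(pct, axis=0)
    return FigureOfMerit(
        set_size=np.arange(1, len(groups) + 1),
        cumulative_pct=cum.mean(axis=1),
        per_sample_curves={s: cum[:, j] for j, s in enumerate(cols)},
    )


def export_reports(
    matrix: PercentMatrix,
    fom: FigureOfMerit,
    outdir: str | os.PathLike,
    plot: bool = False,
) -> list[Path]:
    """Write heatmap.tsv and figure_of_merit.tsv (optionally PNG plots) to outdir.

    Numbers are written with 4 decimal places; reruns overwrite
    deterministically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    heat = matrix.to_frame()
    cum_row = pd.DataFrame(
        [matrix.column_cumulative], index=pd.Index(["cumulative"], name="pattern"),
        columns=matrix.cols,
    )
    heat_out = pd.concat([cum_row, heat])
    heat_path = outdir / "heatmap.tsv"
    heat_out.to_csv(heat_path, sep="\t", float_format="%.4f")
    written.append(heat_path)

    fom_path = outdir / "figure_of_merit.tsv"
    fom.to_frame().to_csv(fom_path, sep="\t", index=False, float_format="%.4f")
    written.append(fom_path)

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.8 * len(matrix.cols), 1 + 0.4 * max(len(matrix.rows), 1))
        )
        im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(matrix.cols)), matrix.cols, rotation=45, ha="right")
        ax.set_yticks(range(len(matrix.rows)), matrix.rows, fontsize=6, fontfamily="monospace")
        for j, c in enumerate(matrix.column_cumulative):
            ax.text(j, -0.8, f"{c:.1f}%", ha="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="% of sample reads")
        fig.tight_layout()
        heat_png = outdir / "heatmap.png"
        fig.savefig(heat_png, dpi=150)
        plt.close(fig)
        written.append(heat_png)

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for sid, curve in sorted(fom.per_sample_curves.items()):
            ax.plot(fom.set_size, curve, alpha=0.4, lw=0.8, label=sid)
        ax.plot(fom.set_size, fom.cumulative_pct, color="black", lw=2, label="mean")
        ax.set_xlabel("number of LNA targets")
        ax.set_ylabel("cumulative % of reads targeted")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fom_png = outdir / "figure_of_merit.png"
        fig.savefig(fom_png, dpi=150)
        plt.close(fig)
        written.append(fom_png)

    return written
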