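"""Manhattan and QQ plot data export.

Plot data are pure functions of a scan result and named threshold lines:
Manhattan points carry a cumulative genome coordinate (chromosome offsets
stacked in map order); QQ points pair sorted observed -log10 p-values with
expected uniform quantiles -log10((i - 0.5) / m). Rendering to an image is a
thin optional layer over the exported table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GwasResult


@dataclass(frozen=True)
class PlotData:
    """Deterministic point set for one plot plus named threshold lines."""

    kind: str
    points: pd.DataFrame
    threshold_lines: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.points.to_csv(path, index=False, float_format="%.12g")

    def render(self, path: str) -> None:  # pragma: no cover - optional plotting
        """Render to an image file (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        if self.kind == "manhattan":
            ax.scatter(self.points["cumulative_bp"], self.points["neg_log10_p"], s=4)
            ax.set_xlabel("cumulative position (bp)")
        else:
            ax.scatter(self.points["expected_logp"], self.points["neg_log10_p"], s=4)
            lim = max(self.points["expected_logp"].max(), 1.0)
            ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
            ax.set_xlabel("expected -log10(p)")
        ax.set_ylabel("observed -log10(p)")
        for label, logp in self.threshold_lines.items():
            ax.axhline(logp, lw=0.8, label=label)
        if self.threshold_lines:
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_plot_data(
    result: GwasResult, thresholds: dict[str, float] | None = None, kind: str = "manhattan"
) -> PlotData:
    """Build Manhattan or QQ plot data from a scan result."""
    if len(result.p_value) == 0:
        raise ValueError("empty GWAS result")
    thresholds = dict(thresholds or {})
    neglogp = result.neg_log10_p
    if kind == "manhattan":
        chrom = result.markers.chromosome.astype(str)
        pos = result.markers.position_bp
        order = np.lexsort((pos, chrom))
        offset = 0
        cumulative = np.empty(len(pos), dtype=np.int64)
        for c in pd.unique(chrom[order]):
            sel = order[chrom[order] == c]
            cumulative[sel] = pos[sel] + offset
            offset += int(pos[sel].max())
        points = pd.DataFrame(
            {
                "marker_id": result.markers.marker_id[order],
                "chromosome": chrom[order],
                "position_bp": pos[order],
                "cumulative_bp": cumulative[order],
                "neg_log10_p": neglogp[order],
            }
        )
    elif kind == "qq":
        m = len(neglogp)
        observed = np.sort(neglogp)[::-1]
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        points = pd.DataFrame(
            {"rank": np.arange(1, m + 1), "expected_logp": expected, "neg_log10_p": observed}
        )
    else:
        raise ValueError(f"unknown plot kind {kind!r}; expected 'manhattan' or 'qq'")
    return PlotData(kind=kind, points=points, threshold_lines=thresholds)
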