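"""Baseline-relative fold changes: per-participant ratios, mean log2 per visit.

For every feature, each participant's value at a visit is divided by that
participant's own baseline value; cells of the summary matrix hold the mean
log2 ratio across participants (the heatmap quantity), together with the
number of contributing participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FoldChange", "mean_log2fc"]


@dataclass
class FoldChange:
    """Feature x visit mean log2 ratios vs baseline, with per-cell counts."""

    log2fc: pd.DataFrame
    counts: pd.DataFrame

    def plot(self, path=None, cmap="RdBu_r"):
        """Plain matrix plot of the fold-change grid (no clustering)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vals = self.log2fc.to_numpy(dtype=float)
        vmax = np.nanmax(np.abs(vals)) or 1.0
        fig, ax = plt.subplots(figsize=(4, max(2, 0.12 * len(self.log2fc))))
        im = ax.imshow(vals, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(self.log2fc.shape[1]), self.log2fc.columns)
        ax.set_ylabel("feature")
        fig.colorbar(im, ax=ax, label="mean log2 ratio vs baseline")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig


def mean_log2fc(matrix: pd.DataFrame, samples: pd.DataFrame, baseline: str = "bas") -> FoldChange:
    """Mean log2 ratio to the participant's own baseline, per feature and visit.

    ``matrix`` must be on the raw (pre-log) scale.  A participant contributes
    to a cell only when both the visit value and their baseline value are
    present; participants without a baseline sample are excluded entirely.
    The baseline column is identically zero wherever defined.
    """
    tp = samples["time_point"]
    if baseline not in set(tp):
        raise ValueError(f"no {baseline!r} samples found")
    bas_rows = samples.loc[tp == baseline]
    if bas_rows["subject_id"].duplicated().any():
        raise ValueError("multiple baseline samples for one participant")
    base = matrix.reindex(bas_rows.index)
    base.index = bas_rows["subject_id"].to_numpy()
    aligned = base.reindex(samples["subject_id"].to_numpy()).to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(matrix.to_numpy(dtype=float) / aligned)
    ratios[~np.isfinite(ratios)] = np.nan
    rdf = pd.DataFrame(ratios, index=matrix.index, columns=matrix.columns)

    order = list(dict.fromkeys(tp))
    grouped = rdf.groupby(tp.to_numpy(), observed=True)
    log2fc = grouped.mean().reindex(order).T
    counts = grouped.count().reindex(order).T.astype(int)
    log2fc.columns.name = None
    counts.columns.name = None
    return FoldChange(log2fc=log2fc, counts=counts)
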