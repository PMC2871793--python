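"""Figure-style numeric outputs: z-scored heatmap matrices, LD-score
histogram data and five-number spectral-count summaries.

Figures themselves are optional (matplotlib, behind a flag); the numeric
tables they would show are always written, byte-stable given the seed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["z_transform", "five_number_summary", "ld_histogram_frame", "heatmap_frame"]


def z_transform(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature z-scores: ``(x - mean) / sd`` with sample (n-1) sd.

    Constant rows become all zeros and are returned in the flag list
    instead of raising — a flat feature is a reportable fact, not an
    error, in a heatmap.
    """
    vals = matrix.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    flagged = [str(matrix.index[i]) for i in np.nonzero(sd.ravel() == 0)[0]]
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[(sd == 0).ravel()] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def five_number_summary(values) -> dict:
    """Median, linear-interpolation ("type 7") quartiles, whiskers and
    1.5*IQR outliers."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo) & (v <= hi)]
    return {
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(x) for x in v[(v < lo) | (v > hi)]],
    }


def heatmap_frame(
    matrix: pd.DataFrame,
    groups: pd.Series,
    results_frame: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Z-transformed significant-feature matrix, samples ordered group 1
    block then group 2 block, features by ascending Mann-Whitney p."""
    groups = groups.reindex(matrix.columns)
    order = [c for g in sorted(groups.unique()) for c in matrix.columns[groups == g]]
    out = matrix[order]
    if results_frame is not None and len(results_frame):
        ranks = results_frame.set_index("feature_id")["p_mwu"]
        feat_order = sorted(
            out.index, key=lambda f: float(ranks.get(str(f), np.inf))
        )
        out = out.loc[feat_order]
    return z_transform(out)


def ld_histogram_frame(ld_scores: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-sample LD score with its group label — the data behind an
    LD-value histogram."""
    return pd.DataFrame(
        {
            "sample_id": ld_scores.index,
            "group": groups.reindex(ld_scores.index).to_numpy(),
            "ld_score": ld_scores.to_numpy(),
        }
    )


def maybe_render_figures(outdir: Path, heatmap: pd.DataFrame, ld: pd.DataFrame) -> list[Path]:
    """Render PNG figures when matplotlib is importable; numeric outputs
    are authoritative either way."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover - plotting is optional
        warnings.warn("matplotlib not installed; skipping figure rendering")
        return []
    written = []
    if len(heatmap):
        fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(heatmap))))
        im = ax.imshow(heatmap.to_numpy(), aspect="auto", cmap="coolwarm")
        ax.set_yticks(range(len(heatmap)), heatmap.index, fontsize=6)
        ax.set_xticks(range(heatmap.shape[1]), heatmap.columns, rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, label="z-score")
        p = outdir / "heatmap.png"
        fig.tight_layout()
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    if len(ld):
        fig, ax = plt.subplots()
        for g, sub in ld.groupby("group"):
            ax.hist(sub["ld_score"], bins=10, alpha=0.6, label=str(g))
        ax.set_xlabel("LD value")
        ax.set_ylabel("frequency")
        ax.legend()
        p = outdir / "ld_histogram.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
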