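"""Static figure rendering from the pipeline's TSV exports.

Figures are conveniences over the exported tables — every plotted number
also lives in a TSV, so plots never gate the analysis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_volcano(volcano: pd.DataFrame, path: str | Path) -> Path:
    """log2 fold change vs −log10 p, DAPs highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"].astype(bool)
    ax.scatter(volcano.loc[~sig, "diff"], volcano.loc[~sig, "neg_log10_p"],
               s=4, c="steelblue", alpha=0.5, label="not significant")
    ax.scatter(volcano.loc[sig, "diff"], volcano.loc[sig, "neg_log10_p"],
               s=4, c="crimson", alpha=0.6, label="DAP")
    ax.set_xlabel("log2 fold change HT − LT")
    ax.set_ylabel("−log10 p")
    ax.legend(frameon=False, markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_heatmap(z_matrix: pd.DataFrame, path: str | Path,
                 cmap: str = "RdYlGn_r") -> Path:
    """Z-scored expression heat map (red = abundant, green = depleted by
    default, matching the usual proteomics convention)."""
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(z_matrix.to_numpy(), aspect="auto", cmap=cmap,
                   interpolation="nearest")
    ax.set_xticks(range(len(z_matrix.columns)))
    ax.set_xticklabels(z_matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("channel")
    ax.set_ylabel(f"{len(z_matrix)} proteins")
    fig.colorbar(im, ax=ax, label="row Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_fc_histogram(hist: pd.DataFrame, path: str | Path) -> Path:
    """Histogram of redox-stoichiometry fold change HT/LT."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    widths = hist["bin_right"] - hist["bin_left"]
    ax.bar(hist["bin_left"], hist["count"], width=widths, align="edge",
           color="slategray", edgecolor="white")
    ax.axvline(1.0, color="crimson", linestyle="--", linewidth=1)
    ax.set_xlabel("fold change of redox stoichiometry (HT/LT)")
    ax.set_ylabel("proteins")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def render_default_plots(out_dir: str | Path) -> list[Path]:
    """Render PNGs for any standard exports present in ``out_dir``."""
    out_dir = Path(out_dir)
    made = []
    volcano = out_dir / "volcano.tsv"
    if volcano.exists():
        made.append(plot_volcano(pd.read_csv(volcano, sep="\t"),
                                 out_dir / "volcano.png"))
    heat = out_dir / "heatmap_matrix.tsv"
    if heat.exists():
        z = pd.read_csv(heat, sep="\t").set_index("protein_id")
        made.append(plot_heatmap(z, out_dir / "heatmap.png"))
    hist = out_dir / "redox_fc_histogram.tsv"
    if hist.exists():
        made.append(plot_fc_histogram(pd.read_csv(hist, sep="\t"),
                                      out_dir / "redox_fc_histogram.png"))
    return made
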