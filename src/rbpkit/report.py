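"""Per-experiment diagnostic report: A-vs-B scatter, per-set logos, triage."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .motifs import PFM, plot_logo
from .scoring import KmerTable


def experiment_report(
    table_a: KmerTable,
    table_b: KmerTable,
    motif_a: PFM,
    motif_b: PFM,
    path,
    probability: float | None = None,
    title: str = "",
) -> None:
    """Write a one-page PNG mirroring the standard reproducibility panel:
    Set A vs Set B 7-mer Z-score scatter with both per-set logos and, when
    available, the classifier probability."""
    fig = plt.figure(figsize=(7, 6))
    gs = fig.add_gridspec(3, 2, height_ratios=[4, 1, 1])
    ax = fig.add_subplot(gs[0, :])
    ax.scatter(table_a.zscores, table_b.zscores, s=4, alpha=0.3, color="#444444")
    top_a, _ = table_a.top(3)
    for w in top_a:
        ax.annotate(w, (table_a.z(w), table_b.z(w)), fontsize=7, color="#d62728")
    ax.set_xlabel("Set A 7-mer Z-score")
    ax.set_ylabel("Set B 7-mer Z-score")
    r = np.corrcoef(table_a.zscores, table_b.zscores)[0, 1]
    header = f"{title}  r = {r:.3f}"
    if probability is not None:
        header += f"  P(pass) = {probability:.3f}"
    ax.set_title(header.strip())
    plot_logo(motif_a, ax=fig.add_subplot(gs[1, 0]), title="Set A")
    plot_logo(motif_b, ax=fig.add_subplot(gs[1, 1]), title="Set B")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
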