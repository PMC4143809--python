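"""Manhattan plot for the SNP scan."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan_plot(scan: pd.DataFrame, p_column: str = "p_M1",
                   sig_threshold: float = 5e-8, path: str | None = None,
                   ax=None):
    """-log10(p) against position, chromosome-blocked, with the genome-wide
    significance line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    df = scan.dropna(subset=[p_column]).copy()
    df["neglog10p"] = -np.log10(df[p_column].clip(lower=1e-300))
    offset = 0.0
    ticks, labels = [], []
    for c, (chrom, grp) in enumerate(df.groupby("chrom", sort=True)):
        pos = grp["pos"].to_numpy(float)
        x = pos - pos.min() + offset
        ax.scatter(x, grp["neglog10p"], s=6,
                   color="tab:blue" if c % 2 == 0 else "tab:orange")
        ticks.append(x.mean() if len(x) else offset)
        labels.append(str(chrom))
        offset = (x.max() if len(x) else offset) + 1.0
    ax.axhline(-np.log10(sig_threshold), color="red", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
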