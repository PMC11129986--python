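"""Presentation-only figure generation for saved analysis artifacts.

Figures are a convenience view of the numeric outputs (space-time
heatmaps for simulation archives, parameter-vs-oxygen diagrams for
branch tables, dispersion curves with the critical-wavenumber marker);
nothing numeric is derived here.
"""

from __future__ import annotations

import os

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_run"]


def plot_run(artifact_path: str, outdir: str | None = None) -> list:
    """Render figures for a saved artifact; returns the files written.

    Recognized artifacts: simulation archives (``.npz`` with fields c/u/v),
    branch tables (CSV with a ``c_eq`` column) and dispersion tables (CSV
    with a ``k2`` column).
    """
    outdir = outdir or os.path.dirname(os.path.abspath(artifact_path))
    base = os.path.splitext(os.path.basename(artifact_path))[0]
    written = []
    if artifact_path.endswith(".npz"):
        data = np.load(artifact_path, allow_pickle=False)
        x, t = data["x"], data["times"]
        for name in ("c", "u", "v"):
            fig, ax = plt.subplots(figsize=(7, 4))
            im = ax.pcolormesh(x, t, data[name], shading="auto", cmap="viridis")
            fig.colorbar(im, ax=ax, label=name)
            ax.set_xlabel("x")
            ax.set_ylabel("t")
            path = os.path.join(outdir, f"{base}_{name}.png")
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        return written
    if artifact_path.endswith(".csv"):
        import pandas as pd

        df = pd.read_csv(artifact_path)
        if "c_eq" in df.columns:
            param = df.columns[0]
            fig, ax = plt.subplots(figsize=(6, 4))
            stable = df["stability"] == "stable"
            ax.plot(df.loc[stable, param], df.loc[stable, "c_eq"], "b.", label="stable")
            ax.plot(df.loc[~stable, param], df.loc[~stable, "c_eq"], "r.", label="unstable")
            if "cycle_min" in df.columns:
                ax.plot(df[param], df["cycle_min"], "b-", lw=0.8)
                ax.plot(df[param], df["cycle_max"], "b-", lw=0.8)
            ax.set_xlabel(param)
            ax.set_ylabel("c")
            ax.legend()
            path = os.path.join(outdir, f"{base}_branch.png")
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return [path]
        if "k2" in df.columns:
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.semilogx(df["k2"], df["p0"], label="p0(k^2)")
            ax.axhline(0.0, color="k", lw=0.5)
            neg = df[df["p0"] < 0]
            if len(neg):
                ax.axvline(neg["k2"].iloc[np.argmin(neg["p0"].values)],
                           color="r", ls="--", label="instability band")
            ax.set_xlabel("k^2")
            ax.set_ylabel("p0")
            ax.legend()
            path = os.path.join(outdir, f"{base}_dispersion.png")
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return [path]
    raise ValueError(f"unknown artifact type: {artifact_path}")
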