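"""Cosmetic plotting: PCA/PLS score plots and VIP bar plot (SVG/PNG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_scores", "plot_vip", "plot_report"]


def plot_scores(scores: np.ndarray, groups: list[str], path: str | Path,
                title: str = "Scores") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = np.asarray(groups)
    for g, color in (("term", "tab:red"), ("preterm", "tab:green")):
        sel = groups == g
        ax.scatter(scores[sel, 0], scores[sel, 1], label=g, color=color, s=25)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_vip(names: list[str], vip: np.ndarray, path: str | Path,
             vip_min: float = 1.0) -> None:
    order = np.argsort(vip)
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(names) + 1.5))
    ax.barh(np.array(names)[order], np.asarray(vip)[order], color="tab:blue")
    ax.axvline(vip_min, color="tab:red", ls="--", lw=1)
    ax.set_xlabel("VIP")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_report(report: dict, matrix, config, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    promoted = report.get("promoted", [])
    if promoted and all(r.get("vip") is not None for r in promoted):
        plot_vip([r["metabolite"] for r in promoted],
                 np.array([r["vip"] for r in promoted]),
                 out_dir / "vip.svg")
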