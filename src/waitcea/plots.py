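"""Figure output: CE plane with confidence ellipses, CEAC, VOI curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.patches import Ellipse

from .cea_plane import CEACCurve, IncrementalResult, confidence_ellipse


def plot_ce_plane(inc: IncrementalResult, path: str | Path,
                  coverages: tuple[float, ...] = (0.9, 0.5, 0.1)) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for cov in coverages:
        e = confidence_ellipse(inc, cov)
        ax.add_patch(
            Ellipse(e["center"], e["width"], e["height"], angle=e["angle_deg"],
                    fill=False, color="tab:blue", lw=1,
                    label=f"{int(cov * 100)}%")
        )
    ax.plot(inc.mean_e, inc.mean_c, "o", color="tab:red", ms=4)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("Incremental effectiveness (QALYs)")
    ax.set_ylabel("Incremental cost (SEK)")
    ax.legend(title="Coverage", fontsize=8)
    ax.autoscale_view()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.lambdas, curve.prob_ce)
    ax.set_xscale("log")
    ax.set_ylim(0, 1)
    ax.set_xlabel("Threshold (SEK per QALY)")
    ax.set_ylabel("P(cost-effective)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_voi(voi: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(voi["lam"], voi["evpi_total"], label="EVPI")
    ax.plot(voi["lam"], voi["evppi_e_total"], label="EVPPI (effect)")
    ax.plot(voi["lam"], voi["evppi_c_total"], label="EVPPI (cost)")
    ax.set_xscale("log")
    ax.set_xlabel("Threshold (SEK per QALY)")
    ax.set_ylabel("Total value of information (SEK)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
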