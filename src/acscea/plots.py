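"""Optional figure renderings of the CSV outputs (tornado, CE plane, CEAC)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .uncertainty import CeacCurve, PsaDraws, TornadoEntry


def plot_tornado(entries: list[TornadoEntry], icer_base: float,
                 path: str | Path, top: int = 15) -> None:
    entries = [e for e in entries if not e.infeasible][:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.axvline(icer_base, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in entries])
    ax.set_xlabel("ICER (THB/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(draws: PsaDraws, wtp: float, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws.delta_qaly, draws.delta_cost, s=6, alpha=0.4,
               color="#4878b0")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q, color="crimson", lw=1,
            label=f"WTP {wtp:,.0f} THB/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (THB)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, wtp: float, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.prob_cost_effective, color="#4878b0")
    ax.axvline(wtp, color="crimson", lw=1, ls="--",
               label=f"WTP {wtp:,.0f} THB/QALY")
    ax.set_xlabel("Willingness to pay (THB/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
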