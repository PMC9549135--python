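"""Optional matplotlib figures: Bland-Altman and balance trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agreement import AgreementResult, PairedSample, per_subject_means
from .dbal import BalanceTrajectory


def bland_altman_plot(sample: PairedSample, result: AgreementResult, path: str) -> None:
    """Per-subject difference vs mean with bias and limits of agreement."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(per_subject_means(sample), sample.differences(), color="k")
    for y, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel(f"mean of pair ({sample.units})")
    ax.set_ylabel(f"difference ({sample.units})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def trajectory_plot(trajectory: BalanceTrajectory, path: str) -> None:
    """D'_BAL over the session with the zero line marked."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(trajectory.times, trajectory.d_bal, color="k", lw=1)
    ax.axhline(0.0, linestyle=":", color="gray")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("D'_BAL (m)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
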