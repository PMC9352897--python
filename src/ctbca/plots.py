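"""Bland-Altman and scatter plots for method-comparison results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agreement import AgreementResult, BlandAltmanResult, PairedSample

__all__ = ["plot_bland_altman", "plot_scatter"]


def plot_bland_altman(
    ba: BlandAltmanResult,
    labels: tuple[str, str],
    path: str | Path,
    title: str | None = None,
) -> None:
    """Mean-difference plot with mean line (blue) and limits of agreement (red)."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(ba.means, ba.diffs, s=14, alpha=0.7, edgecolors="none")
    ax.axhline(ba.mean_diff, color="tab:blue", lw=1.5, label=f"mean {ba.mean_diff:.2f}")
    for lo_hi, ci in ((ba.loa_low, ba.ci_loa_low), (ba.loa_high, ba.ci_loa_high)):
        ax.axhline(lo_hi, color="tab:red", lw=1.2, ls="--")
        ax.axhspan(ci[0], ci[1], color="tab:red", alpha=0.12)
    ax.axhspan(ba.ci_mean[0], ba.ci_mean[1], color="tab:blue", alpha=0.12)
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]} (%)")
    ax.set_ylabel(f"{labels[0]} - {labels[1]} (%)")
    ax.set_title(title or f"Bland-Altman: {labels[0]} vs {labels[1]}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_scatter(
    sample: PairedSample,
    agreement: AgreementResult,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Scatter of paired readings with the identity line and r / rho_c."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(sample.x, sample.y, s=14, alpha=0.7, edgecolors="none")
    lo = min(sample.x.min(), sample.y.min())
    hi = max(sample.x.max(), sample.y.max())
    ax.plot([lo, hi], [lo, hi], color="grey", lw=1, ls=":")
    ax.set_xlabel(f"{sample.labels[0]} (%)")
    ax.set_ylabel(f"{sample.labels[1]} (%)")
    ax.set_title(
        title or f"r = {agreement.r:.2f}, ρC = {agreement.ccc:.2f} (n = {agreement.n})"
    )
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
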