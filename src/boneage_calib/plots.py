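"""Optional diagnostic plots (Bland-Altman, correction-curve bands).

Imported lazily by the CLI so matplotlib stays an optional dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .calibration import CalibrationModel
from .metrics import bland_altman
from .resampling import BootstrapSummary


def bland_altman_plot(pred, ref, path: str | Path, title: str = "") -> Path:
    """Scatter of difference vs. mean with the mu +/- 1.96 sigma limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    summary = bland_altman(pred, ref)
    mean = (pred + ref) / 2.0
    diff = pred - ref

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=12, alpha=0.6, edgecolor="none")
    ax.axhline(summary.mu, ls=":", color="k", label=f"mean {summary.mu:.2f}")
    for limit in (summary.lower, summary.upper):
        ax.axhline(limit, ls="--", color="gray")
    ax.set_xlabel("mean of predictor and reference (months)")
    ax.set_ylabel("predictor - reference (months)")
    ax.set_title(f"{title} ({summary.pct_within:.1f}% within limits)".strip())
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def correction_curve_plot(
    summary: BootstrapSummary, model: CalibrationModel, path: str | Path
) -> Path:
    """Bootstrap correction bands per sex with the primary correction line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(summary.curves), figsize=(5 * len(summary.curves), 4),
                             squeeze=False)
    for ax, (sex, band) in zip(axes[0], summary.curves.items()):
        ax.fill_between(band["raw_ba"], band["lower"], band["upper"], alpha=0.3,
                        label="bootstrap 95% band")
        ax.plot(band["raw_ba"], band["median"], ls="--", label="bootstrap median")
        if sex in model.fits:
            ax.plot(summary.grid, model.correction(sex, summary.grid), color="k",
                    label="primary calibration")
        ax.set_title(sex)
        ax.set_xlabel("raw AI bone age (months)")
        ax.set_ylabel("correction: calibrated - raw (months)")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
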