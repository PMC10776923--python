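"""Static figures: calibration surface and sequential-addition curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .evaluate import SequentialCurve
from .stability import SelectionResult

__all__ = ["plot_calibration_surface", "plot_sequential_curve"]


def plot_calibration_surface(result: SelectionResult, path) -> Path:
    """Heatmap of the stability score over (lambda, pi) with the optimum."""
    if not result.calibrated:
        raise ValueError("calibrate the result first")
    fig, ax = plt.subplots(figsize=(7, 4))
    surf = np.where(np.isfinite(result.score_surface), result.score_surface, np.nan)
    im = ax.imshow(surf.T, aspect="auto", origin="lower", cmap="viridis")
    ax.scatter([result.lambda_star_idx], [result.pi_star_idx],
               marker="x", color="red", label="calibrated (lambda*, pi*)")
    ax.set_xlabel("lambda grid index (decreasing penalty)")
    ax.set_ylabel("pi grid index")
    ax.legend(loc="lower right")
    fig.colorbar(im, ax=ax, label="stability score")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_sequential_curve(curve: SequentialCurve, path) -> Path:
    """Mean AUC with 95% CI as stable proteins are added to the baseline."""
    frame = curve.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    x = frame["step"]
    ax.fill_between(x, frame["ci_low"], frame["ci_high"], alpha=0.25)
    ax.plot(x, frame["mean_auc"], marker="o")
    ax.set_xlabel("proteins added (0 = clinical baseline)")
    ax.set_ylabel("mean test AUC")
    ax.set_ylim(0.4, 1.0)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
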