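"""Bland-Altman agreement between two rate-measurement methods.

For paired measurements (a_i, b_i) — here windowed heart rate from the
inductive sensor versus the ECG reference — the Bland-Altman statistics
are the bias (mean of a - b), the sample standard deviation of the
differences, and the limits of agreement bias +/- 1.96 * SD, plotted
against the pair means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgreementStats", "bland_altman", "bland_altman_plot"]


@dataclass(frozen=True)
class AgreementStats:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


def bland_altman(pairs) -> AgreementStats:
    """Bias and 1.96-SD limits of agreement for paired measurements.

    ``pairs`` is a sequence of (a, b); differences are a - b and the SD
    uses the n - 1 (sample) convention.  Requires at least two pairs.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    if arr.shape[0] < 2:
        raise ValueError("need at least two pairs for limits of agreement")
    diffs = arr[:, 0] - arr[:, 1]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementStats(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=arr.shape[0],
    )


def bland_altman_plot(pairs, path, labels: tuple[str, str] = ("method A", "method B")):
    """Write the classical means-vs-differences plot to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(list(pairs), dtype=float)
    stats = bland_altman(arr)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    for y, style, label in (
        (stats.bias, "-", f"bias = {stats.bias:.2f}"),
        (stats.loa_low, "--", f"-1.96 SD = {stats.loa_low:.2f}"),
        (stats.loa_high, "--", f"+1.96 SD = {stats.loa_high:.2f}"),
    ):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.annotate(label, xy=(1.0, y), xycoords=("axes fraction", "data"), fontsize=8,
                    ha="right", va="bottom")
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]}")
    ax.set_ylabel(f"{labels[0]} - {labels[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return stats
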