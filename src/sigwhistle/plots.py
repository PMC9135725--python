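"""Optional figures: SW-ID contour overlays and ordination scatter plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from sigwhistle.sigid import SignatureCatalog, WhistleUnit
from sigwhistle.stats import OrdinationResult


def plot_swid_overlays(catalog: SignatureCatalog, units: list[WhistleUnit],
                       path, max_types: int = 12):
    """Overlay all contours of each SW-ID on a shared time axis.

    The classic catalogue figure: one panel per signature-whistle type, each
    occurrence drawn from its own start time so stereotypy is visible.
    """
    sw_entries = [e for e in catalog.entries if e.status == "SW"][:max_types]
    if not sw_entries:
        raise ValueError("catalogue contains no SW entries to plot")
    ncols = min(4, len(sw_entries))
    nrows = -(-len(sw_entries) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows),
                             squeeze=False, sharey=True)
    units_sorted = sorted(units, key=lambda u: (u.session_id, u.t_start))
    for ax, entry in zip(axes.flat, sw_entries):
        for uid in entry.unit_ids:
            u = units_sorted[uid]
            for c in u.contours:
                ax.plot(c.times - u.t_start, c.freqs / 1000.0, lw=0.8, alpha=0.6)
        ax.set_title(f"{entry.sw_id} (n={len(entry.unit_ids)})", fontsize=9)
        ax.set_xlabel("time (s)", fontsize=8)
        ax.set_ylabel("kHz", fontsize=8)
    for ax in axes.flat[len(sw_entries):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_ordination(result: OrdinationResult, grouping, path):
    """2-D nMDS scatter coloured by a grouping factor, stress annotated."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = {}
    for label, g in zip(result.coords.index, grouping):
        groups.setdefault(g, []).append(label)
    for g, labels in sorted(groups.items()):
        sub = result.coords.loc[labels]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(g), s=25)
    ax.legend(fontsize=8, frameon=False)
    ax.set_xlabel(result.coords.columns[0])
    ax.set_ylabel(result.coords.columns[1])
    ax.set_title(f"nMDS (stress = {result.stress:.2f})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
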