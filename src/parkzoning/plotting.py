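"""Quick-look maps of a fitted zoning run (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from .classify import ZONE_LABELS

_ZONE_COLORS = ListedColormap(
    ["#b30000", "#2c7fb8", "#fd8d3c", "#a1d99b", "#f0f0f0"])  # CHR CLR GHE GLE NONE


def plot_results(results, path=None):
    """Four panels: ERI surface, ESV surface, grade areas, four-zone map."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 9))
    (ax_eri, ax_esv), (ax_bar, ax_zone) = axes
    for ax, surf, label in ((ax_eri, results.eri_surface, "ERI (kriged)"),
                            (ax_esv, results.esv_surface,
                             "ESV (kriged, 1e4 RMB)")):
        if surf is None:
            ax.set_axis_off()
            ax.set_title(f"{label}: skipped")
            continue
        im = ax.imshow(surf.values, cmap="viridis")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(label)
    zr = results.zone_report.zones
    ax_bar.bar(zr["zone"], zr["percent"], color="#888888")
    ax_bar.set_ylabel("% of park area")
    ax_bar.set_title("zone shares")
    im = ax_zone.imshow(results.zoning.values, cmap=_ZONE_COLORS, vmin=1, vmax=5)
    ax_zone.set_title("four-zone map (" + ", ".join(ZONE_LABELS.values()) + ")")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
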