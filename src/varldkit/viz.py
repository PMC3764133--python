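"""Figure helpers: triangular r2 heatmaps and focal-SNP LD profiles."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .ld import LDMatrix, LDProfile  # noqa: E402


def plot_heatmap(ld: LDMatrix, out_path: str, title: str | None = None) -> str:
    """Lower-triangular r2 heatmap, SNPs in position order, scale [0, 1]."""
    r2 = ld.r2.copy()
    mask = np.triu(np.ones_like(r2, dtype=bool), k=1)
    r2[mask] = np.nan
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(r2, vmin=0.0, vmax=1.0, cmap="Reds", origin="upper",
                   interpolation="nearest")
    ax.set_title(title or f"r² heatmap ({ld.method})")
    ax.set_xlabel("SNP index (position order)")
    ax.set_ylabel("SNP index (position order)")
    fig.colorbar(im, ax=ax, label="r²")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_ld_profile(profiles: list[LDProfile], out_path: str) -> str:
    """r2 vs position, one series per population, focal SNP marked."""
    if not profiles:
        raise ValueError("no profiles supplied")
    focal_ids = {p.focal_id for p in profiles}
    if len(focal_ids) != 1:
        raise ValueError(f"profiles mix focal SNPs: {sorted(focal_ids)}")
    focal_id = focal_ids.pop()
    fig, ax = plt.subplots(figsize=(7, 4))
    focal_pos = None
    for p in profiles:
        ax.plot(p.positions / 1e6, p.r2_values, marker="o", markersize=3,
                linewidth=1, label=p.population or "panel")
        k = p.variant_ids.index(focal_id)
        focal_pos = p.positions[k]
    ax.axvline(focal_pos / 1e6, linestyle="--", color="grey")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("r² with focal SNP")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"LD around {focal_id}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
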