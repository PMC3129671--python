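"""Basic track and heatmap plotting for pipeline results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

FLAG_COLORS = {
    "putative_autozygous": "green",
    "low_density": "gold",
    "high_missing": "blue",
    "masked_cnv": "orange",
}


def plot_tracks(result, region, kind, path):
    """Render one track type for ``region = (chromosome, start_bp, end_bp)``.

    ``kind``: segments (per-sample bars, flag-coloured), pe_heatmap
    (grayscale percentile-extent with ext_AUC overlay, grayscale capped at
    the 90th-percentile column maximum), extauc, haplotypes
    (average-linkage-clustered allele image), omega2.
    """
    chrom, lo, hi = str(region[0]), region[1], region[2]
    fig, ax = plt.subplots(figsize=(9, 4))
    if kind == "segments":
        segs = [s for s in result.segset.segments
                if s.chromosome == chrom and s.end_bp >= lo and s.start_bp <= hi]
        if not segs:
            plt.close(fig)
            raise ValueError("empty region")
        ids = sorted({s.sample_id for s in segs})
        ypos = {sid: k for k, sid in enumerate(ids)}
        for s in segs:
            color = next((FLAG_COLORS[f] for f in FLAG_COLORS if f in s.flags),
                         "red")
            ax.hlines(ypos[s.sample_id], s.start_bp, s.end_bp, color=color, lw=2)
        ax.set_ylabel("sample")
    elif kind == "pe_heatmap":
        pop = sorted(result.pemats)[0]
        pm = result.pemats[pop]
        sel = _sel(pm.chromosomes, pm.positions, chrom, lo, hi)
        block = pm.values[sel]
        cap = np.nanmax(block[:, 90]) if block.size else 1.0
        ax.imshow(np.clip(block, 0, cap).T, aspect="auto", origin="lower",
                  cmap="gray_r",
                  extent=[pm.positions[sel][0], pm.positions[sel][-1], 0, 100])
        tr = result.tracks[pop]
        ax2 = ax.twinx()
        ax2.plot(tr.positions[sel], tr.ext_auc[sel], color="crimson", lw=1)
        ax.set_ylabel("percentile")
    elif kind == "extauc":
        for pop in sorted(result.tracks):
            tr = result.tracks[pop]
            sel = _sel(tr.chromosomes, tr.positions, chrom, lo, hi)
            ax.plot(tr.positions[sel], tr.ext_auc[sel], label=pop, lw=1)
        ax.legend()
        ax.set_ylabel("ext_AUC")
    elif kind == "haplotypes":
        if result.panel is None:
            plt.close(fig)
            raise ValueError("no phased panel available")
        chroms = result.gm.chromosomes
        pos = result.gm.positions
        sel = _sel(chroms, pos, chrom, lo, hi)
        block = result.panel.haplotypes[:, sel]
        if block.shape[1] == 0:
            plt.close(fig)
            raise ValueError("empty region")
        order = leaves_list(average(pdist(block, metric="hamming")))
        ax.imshow(block[order], aspect="auto", cmap="binary",
                  interpolation="nearest")
        ax.set_ylabel("haplotype (clustered)")
    elif kind == "omega2":
        if not result.aha_results:
            plt.close(fig)
            raise ValueError("no AHA results")
        pos = result.gm.positions
        om = np.array([r.omega2 for r in result.aha_results])
        sel = _sel(result.gm.chromosomes, pos, chrom, lo, hi)
        ax.plot(pos[sel], om[sel], lw=1)
        ax.set_ylabel(r"CVM $\omega^2$")
    else:
        plt.close(fig)
        raise ValueError(f"unknown plot kind {kind!r}")
    ax.set_xlabel(f"position on {chrom} (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _sel(chroms, positions, chrom, lo, hi):
    sel = (chroms == chrom) & (positions >= lo) & (positions <= hi)
    if not sel.any():
        raise ValueError("empty region")
    return sel
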