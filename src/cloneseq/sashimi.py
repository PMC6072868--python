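"""Sashimi-style quantitative exports: junction arcs and coverage tracks.

A sashimi plot is per-base coverage plus junction-spanning read counts
drawn as arcs.  The numeric tables written here (TSV arcs, bedGraph
coverage) are sufficient to redraw one and are the artefacts downstream
comparisons diff; the rendered figure is optional decoration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .alignment_io import CoverageProfile, JunctionEvidence


def export_sashimi(junctions: Sequence[JunctionEvidence],
                   coverage: CoverageProfile,
                   out_dir: Union[str, Path],
                   chrom: str,
                   sample_id: str = "sample",
                   render: bool = False) -> dict[str, Path]:
    """Write sashimi_junctions.tsv and coverage.bedGraph; optionally a PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / "sashimi_junctions.tsv"
    with open(jpath, "w") as fh:
        fh.write("sample\tchrom\tdonor\tacceptor\tread_support\n")
        for j in junctions:
            fh.write(f"{sample_id}\t{chrom}\t{j.donor_g}\t{j.acceptor_g}"
                     f"\t{j.read_support}\n")
    cpath = out / "coverage.bedGraph"
    _write_bedgraph(coverage, chrom, cpath)
    paths = {"junctions": jpath, "coverage": cpath}
    if render:
        paths["figure"] = _render(junctions, coverage, chrom,
                                  out / "sashimi.png", sample_id)
    return paths


def _write_bedgraph(cov: CoverageProfile, chrom: str, path: Path) -> None:
    """Run-length encoded depth, bedGraph (0-based half-open) intervals."""
    depth = cov.depth
    with open(path, "w") as fh:
        if len(depth) == 0:
            return
        run_start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[run_start]:
                val = int(depth[run_start])
                if val != 0:
                    s = cov.region_start - 1 + run_start
                    e = cov.region_start - 1 + i
                    fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")
                run_start = i


def _render(junctions, coverage, chrom, path: Path, sample_id: str) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(coverage.region_start, coverage.region_end + 1)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.fill_between(x, coverage.depth, step="mid", alpha=0.6)
    ymax = max(int(coverage.depth.max(initial=1)), 1)
    for j in junctions:
        mid = (j.donor_g + j.acceptor_g) / 2
        ax.annotate(str(j.read_support), xy=(mid, ymax * 1.05),
                    ha="center", fontsize=8)
        ax.plot([j.donor_g, mid, j.acceptor_g],
                [0, ymax * 1.0, 0], lw=0.8)
    ax.set_xlabel(f"{chrom} position")
    ax.set_ylabel("depth")
    ax.set_title(sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
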