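"""Sliding-window mutation-density plots.

One line series per taxon group, x = 1-based alignment column of each
window's central-fragment midpoint, y = average mutation index S̄. A
horizontal reference line marks the recommended selection threshold
(default 2). Output is deterministic for a fixed input: fixed figure
geometry and no embedded timestamps where the format allows.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .profiles import MutationProfile  # noqa: E402

logger = logging.getLogger(__name__)

PLOT_FORMATS = ("eps", "pdf", "png", "svg", "tiff")

_NO_TIMESTAMP_METADATA = {
    "pdf": {"CreationDate": None},
    "eps": {"CreationDate": None},
    "svg": {"Date": None},
}


def render_profile_plot(
    profiles: Sequence[MutationProfile],
    out_dir: str | Path,
    project_id: str = "run",
    formats: Iterable[str] = PLOT_FORMATS,
    threshold: float = 2.0,
) -> list[Path]:
    """Render one figure of the given profiles and save it in each
    requested format. Profiles without any defined S̄ value are skipped
    with a warning; returns the written file paths."""
    formats = list(formats)
    unknown = set(formats) - set(PLOT_FORMATS)
    if unknown:
        raise ValueError(f"unsupported plot formats: {sorted(unknown)}")
    drawable = [p for p in profiles if p.S]
    for p in profiles:
        if not p.S:
            logger.warning("profile for %s has no defined index values; skipped", p.group)
    if not drawable:
        raise ValueError("no profile with defined average-index values to plot")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plt.rcParams["svg.hashsalt"] = "lampmask"

    fig, ax = plt.subplots(figsize=(8, 4))
    for p in drawable:
        ax.plot(p.anchor_midpoints, p.S, label=p.group, linewidth=1.5)
    ax.axhline(threshold, color="grey", linestyle="--", linewidth=1,
               label=f"threshold = {threshold:g}")
    ax.set_xlabel("alignment column (central-fragment midpoint, 1-based)")
    ax.set_ylabel("average mutation index")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=8)
    fig.tight_layout()

    stem = "_".join([project_id] + [p.group for p in drawable]) + "_density"
    paths: list[Path] = []
    # pin the embedded creation date so repeated runs are byte-identical
    previous_epoch = os.environ.get("SOURCE_DATE_EPOCH")
    os.environ["SOURCE_DATE_EPOCH"] = "0"
    try:
        for ext in formats:
            path = out_dir / f"{stem}.{ext}"
            kwargs = {}
            metadata = _NO_TIMESTAMP_METADATA.get(ext)
            if metadata is not None:
                kwargs["metadata"] = metadata
            fig.savefig(path, format=ext, **kwargs)
            paths.append(path)
    finally:
        if previous_epoch is None:
            os.environ.pop("SOURCE_DATE_EPOCH", None)
        else:
            os.environ["SOURCE_DATE_EPOCH"] = previous_epoch
    plt.close(fig)
    return paths
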