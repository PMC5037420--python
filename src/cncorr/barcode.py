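"""Event barcodes: a time-ordered colour strip of per-interval region labels.

A barcode has one row per region and one bar per sampling interval, so a
one-hour movie at 1-min spacing draws 60 bars. Regions I-IV are red,
yellow, blue and green; Region V (stationary mode) is black. UNDEFINED
intervals are drawn as gaps and excluded from occurrence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cn_core import REGIONS_FOUR, REGIONS_FIVE, UNDEFINED

__all__ = ["Barcode", "ConsistencyError", "build_barcode", "region_occurrence",
           "pooled_occurrence", "mean_occurrence", "render_barcode", "REGION_COLORS"]

REGION_COLORS = {
    "I": "red",
    "II": "gold",
    "III": "blue",
    "IV": "green",
    "V": "black",
}


class ConsistencyError(ValueError):
    """Labels are inconsistent with the declared region scheme."""


@dataclass
class Barcode:
    cell_id: str
    tau: float  # minutes per bar
    labels: list[str]
    scheme: str = "four"
    color_map: dict = field(default_factory=lambda: dict(REGION_COLORS))

    def __post_init__(self) -> None:
        if self.scheme not in ("four", "five"):
            raise ConsistencyError(f"unknown scheme {self.scheme!r}")
        if len(self.labels) < 1:
            raise ConsistencyError("a barcode needs at least one bar")
        valid = set(self.regions) | {UNDEFINED}
        bad = set(self.labels) - valid
        if bad:
            raise ConsistencyError(
                f"labels {sorted(bad)} not valid for the {self.scheme}-region scheme"
            )

    @property
    def regions(self) -> tuple[str, ...]:
        return REGIONS_FOUR if self.scheme == "four" else REGIONS_FIVE

    def __len__(self) -> int:
        return len(self.labels)


def build_barcode(points: pd.DataFrame, scheme: str = "four", tau: float = 1.0) -> Barcode:
    """Barcode from a CN series table: one label per interval in time order."""
    if len(points) == 0:
        raise ConsistencyError("empty CN series")
    pts = points.sort_values("interval_index")
    cell_ids = pts["cell_id"].unique()
    cell_id = str(cell_ids[0]) if len(cell_ids) == 1 else "pooled"
    return Barcode(cell_id=cell_id, tau=tau, labels=list(pts["region"]), scheme=scheme)


def region_occurrence(barcode: Barcode) -> dict[str, float]:
    """Occurrence fraction of each region among the defined (non-UNDEFINED) bars.

    Fractions sum to 1; regions of the scheme that never occur map to 0.
    """
    labels = [lab for lab in barcode.labels if lab != UNDEFINED]
    if not labels:
        raise ConsistencyError("all bars are UNDEFINED; occurrence is undefined")
    n = len(labels)
    return {r: labels.count(r) / n for r in barcode.regions}


def pooled_occurrence(barcodes: list[Barcode]) -> dict[str, float]:
    """Occurrence over all defined intervals pooled across cells."""
    if not barcodes:
        raise ConsistencyError("no barcodes")
    scheme = barcodes[0].scheme
    labels = [lab for bc in barcodes for lab in bc.labels if lab != UNDEFINED]
    if not labels:
        raise ConsistencyError("all bars are UNDEFINED; occurrence is undefined")
    n = len(labels)
    return {r: labels.count(r) / n for r in (REGIONS_FOUR if scheme == "four" else REGIONS_FIVE)}


def mean_occurrence(barcodes: list[Barcode]) -> dict[str, float]:
    """Per-cell occurrence fractions averaged across cells (unweighted)."""
    if not barcodes:
        raise ConsistencyError("no barcodes")
    occs = [region_occurrence(bc) for bc in barcodes]
    regions = barcodes[0].regions
    return {r: float(np.mean([o[r] for o in occs])) for r in regions}


def render_barcode(barcode: Barcode, path) -> None:
    """Render the barcode to an image: horizontal time axis, one row per region.

    Deterministic for a fixed input and matplotlib backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    regions = barcode.regions
    n_rows = len(regions)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.08 * len(barcode)), 0.45 * n_rows + 0.8))
    for i, region in enumerate(regions):
        row = n_rows - 1 - i  # Region I on top
        for k, lab in enumerate(barcode.labels):
            if lab == region:
                ax.add_patch(
                    plt.Rectangle(
                        (k * barcode.tau, row), barcode.tau, 0.9,
                        color=barcode.color_map[region], linewidth=0,
                    )
                )
    ax.set_xlim(0, len(barcode) * barcode.tau)
    ax.set_ylim(-0.1, n_rows)
    ax.set_yticks([n_rows - 1 - i + 0.45 for i in range(n_rows)])
    ax.set_yticklabels([f"Region {r}" for r in regions])
    ax.set_xlabel("time (min)")
    ax.set_title(f"cell {barcode.cell_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)
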