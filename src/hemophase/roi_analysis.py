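"""Region-of-interest partitioning and ROI-wise spatial averaging.

Regional analysis splits the vessel into named segments (by default the
four aortic regions: ascending aorta, arch, proximal and distal descending
aorta) and reports the spatially averaged value of a quantity per region
and per phase, plus the cycle-time average per region.  Volumetric
quantities (e.g. TKE) are volume-weighted; wall quantities (the WSS family)
are area-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_fields import TimeGrid
from .phase_decomposition import time_average

__all__ = [
    "DEFAULT_REGIONS",
    "ROIPartition",
    "RegionalReport",
    "partition_by_axial_bins",
    "regional_series",
]

DEFAULT_REGIONS = ("AAo", "arch", "proximal DAo", "distal DAo")

EXCLUDED = -1

WHOLE_DOMAIN = "whole domain"


@dataclass
class ROIPartition:
    """Assignment of each element to exactly one named region (or excluded).

    ``assignment`` holds, per cell/face, the index into ``region_names``,
    or ``-1`` for excluded elements.
    """

    region_names: tuple[str, ...]
    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        n = len(self.region_names)
        if self.assignment.min(initial=0) < EXCLUDED or self.assignment.max(initial=-1) >= n:
            raise ValueError("assignment indices out of range")
        for i, name in enumerate(self.region_names):
            if not np.any(self.assignment == i):
                raise ValueError(f"region {name!r} is empty")

    @property
    def n_elements(self) -> int:
        return self.assignment.size


@dataclass
class RegionalReport:
    """ROI-wise spatially averaged time series and their time averages."""

    quantity: str
    units: str
    mode: str
    series: pd.DataFrame          # tidy: region, phase_time, value
    time_averages: dict[str, float] = field(default_factory=dict)

    def region_series(self, region: str) -> np.ndarray:
        sub = self.series[self.series["region"] == region]
        return sub.sort_values("phase_time")["value"].to_numpy()


def partition_by_axial_bins(
    centroids: np.ndarray,
    cuts: np.ndarray,
    axis: np.ndarray | int = 2,
    region_names: tuple[str, ...] | None = None,
) -> ROIPartition:
    """Partition elements into consecutive bins along an axis.

    Parameters
    ----------
    centroids : ndarray, shape (E, 3)
        Cell centroids or wall-face centres.
    cuts : array-like
        Strictly increasing interior cut coordinates; ``len(cuts) + 1``
        regions result, spanning the whole domain.
    axis : int or 3-vector
        Coordinate axis index, or an arbitrary direction onto which
        centroids are projected (a simple centreline surrogate).
    region_names : optional tuple of names, defaults to the four aortic
        regions when there are four bins, else "region 0", ...
    """
    centroids = np.asarray(centroids, dtype=float)
    cuts = np.asarray(cuts, dtype=float)
    if cuts.ndim != 1 or (cuts.size > 1 and np.any(np.diff(cuts) <= 0)):
        raise ValueError("cuts must be strictly increasing")
    if isinstance(axis, (int, np.integer)):
        coord = centroids[:, int(axis)]
    else:
        direction = np.asarray(axis, dtype=float)
        direction = direction / np.linalg.norm(direction)
        coord = centroids @ direction
    assignment = np.digitize(coord, cuts)
    n_regions = cuts.size + 1
    if region_names is None:
        region_names = (
            DEFAULT_REGIONS
            if n_regions == 4
            else tuple(f"region {i}" for i in range(n_regions))
        )
    if len(region_names) != n_regions:
        raise ValueError("need one region name per bin")
    part = ROIPartition(region_names=tuple(region_names), assignment=assignment)
    return part


def regional_series(
    values: np.ndarray,
    partition: ROIPartition,
    weights: np.ndarray,
    grid: TimeGrid,
    quantity: str = "",
    units: str = "",
    mode: str = "phase_averaged",
) -> RegionalReport:
    """Weighted spatial average per region per phase, plus time averages.

    Parameters
    ----------
    values : ndarray, shape (M, E)
        Per-phase, per-element scalar quantity.
    weights : ndarray, shape (E,)
        Cell volumes (volumetric quantities) or face areas (wall
        quantities).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.ndim != 2 or values.shape[1] != partition.n_elements:
        raise ValueError("values must have shape (n_phases, n_elements)")
    if weights.shape != (partition.n_elements,):
        raise ValueError("one weight per element required")
    if values.shape[0] != grid.n_phases:
        raise ValueError("phase extent does not match time grid")

    rows = []
    time_avgs: dict[str, float] = {}
    masks = [partition.assignment == i for i in range(len(partition.region_names))]
    masks.append(partition.assignment != EXCLUDED)  # whole domain
    names = list(partition.region_names) + [WHOLE_DOMAIN]
    for name, mask in zip(names, masks):
        w = weights[mask]
        avg = values[:, mask] @ w / w.sum()
        for t, v in zip(grid.phase_times, avg):
            rows.append({"region": name, "phase_time": t, "value": v})
        time_avgs[name] = float(time_average(avg, grid))
    df = pd.DataFrame(rows, columns=["region", "phase_time", "value"])
    return RegionalReport(
        quantity=quantity,
        units=units,
        mode=mode,
        series=df,
        time_averages=time_avgs,
    )
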