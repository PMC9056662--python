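"""SPXY calibration/prediction partitioning.

SPXY is Kennard-Stone selection on a joint spectral-response distance

    d(i, j) = d_x(i, j) / max d_x  +  d_y(i, j) / max d_y

with Euclidean d_x on spectra and |y_i - y_j| on the reference values, so
the calibration set covers both spaces.  Selection is deterministic: seed
with the pair at maximal joint distance, then repeatedly add the sample
whose minimum distance to the already-chosen set is largest (ties broken by
lowest index).

For an r:1 split the calibration size is ``n - floor(n / (r + 1))`` so the
remainder lands in the calibration set (410 samples at 3:1 -> 308 + 102).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cube_io import SpectraTable
from .errors import ConfigError, PartitionError


@dataclass
class PartitionResult:
    cal_index: np.ndarray
    pred_index: np.ndarray
    ratio: float
    stats: pd.DataFrame | None = None

    def to_csv(self, path, sample_ids=None) -> None:
        n = self.cal_index.size + self.pred_index.size
        ids = sample_ids if sample_ids is not None else [f"s{i:04d}" for i in range(n)]
        sets = np.empty(n, dtype=object)
        sets[self.cal_index] = "cal"
        sets[self.pred_index] = "pred"
        pd.DataFrame({"sample_id": ids, "set": sets}).to_csv(path, index=False)


def cal_size_for_ratio(n: int, ratio: float) -> int:
    """Calibration-set size for an r:1 split: n - floor(n/(r+1))."""
    return n - math.floor(n / (ratio + 1))


def joint_distance_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Max-normalized Euclidean-x plus absolute-y distance matrix."""
    dx = squareform(pdist(x, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        raise PartitionError("all samples identical in x and y; cannot partition")
    d = np.zeros_like(dx)
    if mx > 0:
        d += dx / mx
    if my > 0:
        d += dy / my
    return d


def kennard_stone_order(d: np.ndarray, n_select: int) -> list[int]:
    """Selection order of Kennard-Stone on a precomputed distance matrix.

    The first two entries are the max-distance pair (lower index first);
    each further entry maximizes the minimum distance to the selected set,
    ties resolved toward the lowest index.
    """
    n = d.shape[0]
    i, j = np.unravel_index(np.argmax(d), d.shape)
    first = [min(i, j), max(i, j)]
    selected = list(first)
    mind = np.minimum(d[first[0]], d[first[1]])
    mind[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(mind))  # argmax returns the lowest maximizing index
        selected.append(nxt)
        mind = np.minimum(mind, d[nxt])
        mind[nxt] = -np.inf
    return selected


def spxy_partition(
    data: SpectraTable, cal_fraction: float | None = None, ratio: float | None = None
) -> PartitionResult:
    """Partition a spectra table into calibration and prediction sets.

    Specify either ``cal_fraction`` (calibration size = ceil(frac * n)) or
    ``ratio`` r for an r:1 split with remainder-to-calibration rounding.
    """
    if data.y is None:
        raise ConfigError("SPXY requires reference values (data.y)")
    n = data.n_samples
    if n < 3:
        raise ConfigError("SPXY needs at least 3 samples")
    if (cal_fraction is None) == (ratio is None):
        raise ConfigError("specify exactly one of cal_fraction or ratio")
    if ratio is not None:
        n_cal = cal_size_for_ratio(n, ratio)
        declared = float(ratio)
    else:
        if not 0 < cal_fraction < 1:
            raise ConfigError("cal_fraction must be in (0, 1)")
        n_cal = int(math.ceil(cal_fraction * n))
        declared = cal_fraction / (1 - cal_fraction)
    n_cal = min(max(n_cal, 2), n - 1)

    d = joint_distance_matrix(data.x, data.y)
    order = kennard_stone_order(d, n_cal)
    cal = np.array(sorted(order))
    pred = np.setdiff1d(np.arange(n), cal)
    result = PartitionResult(cal_index=cal, pred_index=pred, ratio=declared)
    result.stats = summarize_partition(data, result)
    return result


def random_partition(
    data: SpectraTable, cal_fraction: float, seed: int | None = 0
) -> PartitionResult:
    """Plain uniform split (testing fallback; the workflow default is SPXY)."""
    n = data.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(math.ceil(cal_fraction * n))
    result = PartitionResult(
        cal_index=np.sort(perm[:n_cal]),
        pred_index=np.sort(perm[n_cal:]),
        ratio=cal_fraction / (1 - cal_fraction),
    )
    result.stats = summarize_partition(data, result)
    return result


def summarize_partition(data: SpectraTable, result: PartitionResult) -> pd.DataFrame:
    """Per-set n/min/max/mean/SD of the reference values (SD with n-1)."""
    rows = []
    for name, idx in (("calibration", result.cal_index), ("prediction", result.pred_index)):
        yv = data.y[idx]
        if yv.size == 1:
            warnings.warn(f"{name} set is a singleton; SD reported as 0", stacklevel=2)
            sd = 0.0
        else:
            sd = float(np.std(yv, ddof=1))
        rows.append(
            {
                "set": name,
                "n": int(yv.size),
                "min": float(yv.min()),
                "max": float(yv.max()),
                "mean": float(yv.mean()),
                "sd": sd,
            }
        )
    return pd.DataFrame(rows)
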