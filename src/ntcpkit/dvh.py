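"""Dose-volume histogram representations, conversions, and metrics.

Two in-memory forms are used throughout the package:

* :class:`DifferentialDVH` — fraction of the structure volume per dose bin;
  the argument of every complication-probability formula.
* :class:`CumulativeDVH` — fraction of the structure receiving at least a
  given dose; the form used for V_x / D_x metrics and plotting.

Volumes are kept as fractions of the structure volume internally; absolute
volumes (cc) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DVHError",
    "DifferentialDVH",
    "CumulativeDVH",
    "make_differential",
    "to_cumulative",
    "to_differential",
    "volume_at_dose",
    "dose_at_volume",
    "summary_metrics",
]

logger = logging.getLogger(__name__)

#: Tolerance on the total-volume-equals-one invariant.
VOLUME_SUM_TOL = 1e-6

#: Raw volume sums within this relative distance of 1 are silently
#: renormalized; larger deviations are treated as absolute-volume input.
RENORM_LIMIT = 0.01

#: Default dose-bin width (Gy) used when a grid spacing must be invented.
DEFAULT_BIN_WIDTH = 0.1


class DVHError(ValueError):
    """Invalid DVH data (shape, ordering, sign, or normalization)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DVHError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise DVHError(f"{name} must contain at least one element")
    if not np.all(np.isfinite(arr)):
        raise DVHError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DifferentialDVH:
    """Fractional volume per dose bin.

    Parameters
    ----------
    bin_dose
        Representative dose of each bin (Gy, strictly ascending, >= 0).
        By convention the bin dose is the lower bin edge.
    bin_volume
        Fraction of the structure volume in each bin; non-negative and
        summing to 1 within :data:`VOLUME_SUM_TOL`.
    structure_label
        Name of the structure the histogram belongs to.
    volume_cc
        Optional absolute structure volume in cubic centimetres.
    """

    bin_dose: np.ndarray
    bin_volume: np.ndarray
    structure_label: str = ""
    volume_cc: Optional[float] = None

    def __post_init__(self) -> None:
        dose = _as_float_array(self.bin_dose, "bin_dose")
        vol = _as_float_array(self.bin_volume, "bin_volume")
        if dose.size != vol.size:
            raise DVHError(
                f"bin_dose and bin_volume lengths differ: {dose.size} != {vol.size}"
            )
        if np.any(dose < 0):
            raise DVHError("bin_dose must be non-negative")
        if np.any(np.diff(dose) <= 0):
            raise DVHError("bin_dose must be strictly ascending")
        if np.any(vol < 0):
            raise DVHError("bin_volume must be non-negative")
        total = float(vol.sum())
        if abs(total - 1.0) > VOLUME_SUM_TOL:
            raise DVHError(
                f"bin_volume must sum to 1 within {VOLUME_SUM_TOL}, got {total!r}"
            )
        dose.setflags(write=False)
        vol.setflags(write=False)
        object.__setattr__(self, "bin_dose", dose)
        object.__setattr__(self, "bin_volume", vol)
        if self.volume_cc is not None and self.volume_cc <= 0:
            raise DVHError("volume_cc must be positive when given")

    def __len__(self) -> int:
        return int(self.bin_dose.size)


@dataclass(frozen=True)
class CumulativeDVH:
    """Fraction of the structure receiving at least each grid dose.

    ``volume_fraction`` must be non-increasing, start at 1 (the whole
    structure receives at least 0 Gy), and stay non-negative.
    """

    dose_grid: np.ndarray
    volume_fraction: np.ndarray
    structure_label: str = ""
    volume_cc: Optional[float] = None

    def __post_init__(self) -> None:
        dose = _as_float_array(self.dose_grid, "dose_grid")
        vol = _as_float_array(self.volume_fraction, "volume_fraction")
        if dose.size != vol.size:
            raise DVHError(
                f"dose_grid and volume_fraction lengths differ: {dose.size} != {vol.size}"
            )
        if np.any(dose < 0):
            raise DVHError("dose_grid must be non-negative")
        if np.any(np.diff(dose) <= 0):
            raise DVHError("dose_grid must be strictly ascending")
        if np.any(np.diff(vol) > VOLUME_SUM_TOL):
            raise DVHError("volume_fraction must be non-increasing")
        if abs(vol[0] - 1.0) > VOLUME_SUM_TOL:
            raise DVHError(
                f"volume_fraction at the lowest dose must be 1, got {vol[0]!r}"
            )
        if vol[-1] < -VOLUME_SUM_TOL:
            raise DVHError("volume_fraction must be non-negative")
        dose.setflags(write=False)
        vol.setflags(write=False)
        object.__setattr__(self, "dose_grid", dose)
        object.__setattr__(self, "volume_fraction", vol)
        if self.volume_cc is not None and self.volume_cc <= 0:
            raise DVHError("volume_cc must be positive when given")

    def __len__(self) -> int:
        return int(self.dose_grid.size)


def make_differential(
    doses,
    volumes,
    label: str = "",
    volume_cc: Optional[float] = None,
) -> DifferentialDVH:
    """Build a validated differential DVH from raw dose/volume columns.

    Bins are sorted ascending by dose; bins sharing the same dose are
    merged. Volume columns summing to 1 within :data:`RENORM_LIMIT` are
    renormalized exactly (with a log message); a larger deviation is an
    error — it usually signals absolute-volume input without ``volume_cc``.
    """
    dose = _as_float_array(doses, "doses")
    vol = _as_float_array(volumes, "volumes")
    if dose.size != vol.size:
        raise DVHError(f"doses and volumes lengths differ: {dose.size} != {vol.size}")
    if np.any(dose < 0):
        raise DVHError("doses must be non-negative")
    if np.any(vol < 0):
        raise DVHError("volumes must be non-negative")

    order = np.argsort(dose, kind="stable")
    dose, vol = dose[order], vol[order]
    uniq, inverse = np.unique(dose, return_inverse=True)
    if uniq.size != dose.size:
        merged = np.zeros(uniq.size)
        np.add.at(merged, inverse, vol)
        dose, vol = uniq, merged

    total = float(vol.sum())
    if abs(total - 1.0) > RENORM_LIMIT:
        raise DVHError(
            f"volumes sum to {total:.6g}; more than {RENORM_LIMIT:.0%} away from 1 "
            "(absolute volumes? supply volume_cc and convert at the I/O layer)"
        )
    if abs(total - 1.0) > VOLUME_SUM_TOL:
        logger.info(
            "renormalizing DVH %r volume sum %.8f -> 1", label or "<unnamed>", total
        )
    vol = vol / total
    return DifferentialDVH(dose, vol, structure_label=label, volume_cc=volume_cc)


def _terminal_step(bin_dose: np.ndarray) -> float:
    if bin_dose.size >= 2:
        return float(np.min(np.diff(bin_dose)))
    return DEFAULT_BIN_WIDTH


def to_cumulative(d: DifferentialDVH) -> CumulativeDVH:
    """Convert differential bins to a cumulative (>= dose) staircase.

    The cumulative value at a grid dose D is the total fractional volume of
    bins at doses >= D.  The grid is the bin-edge grid (0 Gy prepended),
    plus one trailing point one bin-width above the last bin where the
    curve reaches 0.
    """
    dose = d.bin_dose
    cum_above = np.concatenate([np.cumsum(d.bin_volume[::-1])[::-1], [0.0]])
    # cum_above[i] = volume at doses >= dose[i]
    grid = list(dose)
    vals = list(cum_above[:-1])
    if dose[0] > 0:
        # c(0) == c(d_1): reuse the identical float so differencing back
        # yields an exact zero for the empty [0, d_1) interval
        grid.insert(0, 0.0)
        vals.insert(0, float(cum_above[0]))
    grid.append(dose[-1] + _terminal_step(dose))
    vals.append(0.0)
    return CumulativeDVH(
        np.asarray(grid),
        np.asarray(vals),
        structure_label=d.structure_label,
        volume_cc=d.volume_cc,
    )


def to_differential(c: CumulativeDVH) -> DifferentialDVH:
    """Convert a cumulative staircase back to differential bins.

    Each bin takes the volume lost between consecutive grid points and the
    lower grid dose as its representative dose (lower-edge convention).
    Any residual volume at the top of the grid becomes a final bin at the
    last grid dose.  Zero-volume bins are dropped.
    """
    dv = -np.diff(c.volume_fraction)
    doses = c.dose_grid[:-1].copy()
    if c.volume_fraction[-1] > VOLUME_SUM_TOL:
        dv = np.concatenate([dv, [c.volume_fraction[-1]]])
        doses = np.concatenate([doses, [c.dose_grid[-1]]])
    keep = dv > 0
    if not np.any(keep):
        raise DVHError("cumulative DVH carries no volume")
    return make_differential(
        doses[keep], dv[keep], label=c.structure_label, volume_cc=c.volume_cc
    )


def volume_at_dose(c: CumulativeDVH, x: float) -> float:
    """V_x: fraction of the structure receiving at least ``x`` Gy.

    Linear interpolation on the cumulative curve; doses beyond the grid
    return 0.  The metric is closed at x ("equal to or greater than").
    """
    if x < 0:
        raise DVHError("dose must be non-negative")
    if x > c.dose_grid[-1]:
        return 0.0
    v = float(np.interp(x, c.dose_grid, c.volume_fraction))
    return min(max(v, 0.0), 1.0)


def dose_at_volume(c: CumulativeDVH, x: float) -> float:
    """D_x: minimum dose received by the hottest fraction ``x`` of the volume.

    Inverse linear interpolation of the cumulative curve.  On flat
    segments the highest dose attaining the fraction is returned
    (conservative for organ-at-risk reporting).
    """
    if not 0.0 < x <= 1.0:
        raise DVHError("volume fraction must lie in (0, 1]")
    d, v = c.dose_grid, c.volume_fraction
    if x <= v[-1]:
        return float(d[-1])
    # last index with volume_fraction >= x; v is non-increasing
    j = int(np.searchsorted(-v, -x, side="right")) - 1
    if j < 0:
        return float(d[0])
    if v[j] == x or j == len(d) - 1:
        return float(d[j])
    return float(d[j] + (v[j] - x) / (v[j] - v[j + 1]) * (d[j + 1] - d[j]))


def summary_metrics(d: DifferentialDVH) -> dict:
    """Return ``d_max``, ``d_min``, and ``d_mean`` (Gy) of a differential DVH.

    ``d_max``/``d_min`` are the largest/smallest bin doses carrying volume;
    ``d_mean`` is the volume-weighted mean bin dose.
    """
    nz = d.bin_volume > 0
    doses = d.bin_dose[nz]
    return {
        "d_max": float(doses.max()),
        "d_min": float(doses.min()),
        "d_mean": float(np.dot(d.bin_dose, d.bin_volume)),
    }
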