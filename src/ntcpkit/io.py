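"""Delimited-text file formats for DVHs, cohort tables, and comparison output.

DVH files hold one or more blocks.  Each block starts with ``# key: value``
header lines (``structure``, ``type``, ``dose_unit``, ``volume_unit``, and
optionally ``plan``, ``patient``, ``volume_cc``), followed by a
``dose,volume`` column line and the numeric rows.  Blocks are separated by
blank lines.  Doses are written to 3 decimals and volumes to 6, so files
round-trip deterministically.

Cubic-centimetre volume columns are converted to fractions on read using
the declared ``volume_cc``; everything downstream works in fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dvh import (
    CumulativeDVH,
    DifferentialDVH,
    DVHError,
    make_differential,
)
from .stats import CohortNTCP, ComparisonTable

__all__ = [
    "DVHFileError",
    "DVHFileRecord",
    "read_dvh_csv",
    "write_dvh_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_comparison_csv",
]

logger = logging.getLogger(__name__)

_REQUIRED_KEYS = ("structure", "type", "dose_unit", "volume_unit")
_TYPES = ("cumulative", "differential")
_VOLUME_UNITS = ("relative", "cc")


class DVHFileError(DVHError):
    """Malformed DVH file (header, units, or row ordering)."""


@dataclass(frozen=True)
class DVHFileRecord:
    """One parsed file block: header metadata plus the resulting DVH object."""

    dvh: Union[DifferentialDVH, CumulativeDVH]
    kind: str  # "cumulative" | "differential"
    plan: Optional[str] = None
    patient: Optional[str] = None


def _parse_block(lines: list[str], where: str) -> DVHFileRecord:
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for line in lines:
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise DVHFileError(f"{where}: malformed header line {line!r}")
            key, _, value = body.partition(":")
            meta[key.strip().lower()] = value.strip()
        else:
            parts = [p.strip() for p in line.split(",")]
            if parts[0].lower() == "dose":
                continue
            if len(parts) != 2:
                raise DVHFileError(f"{where}: expected 'dose,volume' row, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise DVHFileError(f"{where}: non-numeric row {line!r}") from exc

    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise DVHFileError(f"{where}: header missing keys {missing}")
    kind = meta["type"].lower()
    if kind not in _TYPES:
        raise DVHFileError(f"{where}: unknown DVH type {meta['type']!r}")
    if meta["dose_unit"] != "Gy":
        raise DVHFileError(
            f"{where}: unsupported dose_unit {meta['dose_unit']!r} (expected 'Gy')"
        )
    volume_unit = meta["volume_unit"].lower()
    if volume_unit not in _VOLUME_UNITS:
        raise DVHFileError(
            f"{where}: unsupported volume_unit {meta['volume_unit']!r} "
            f"(expected one of {_VOLUME_UNITS})"
        )
    if not rows:
        raise DVHFileError(f"{where}: block has no data rows")

    dose = np.array([r[0] for r in rows])
    vol = np.array([r[1] for r in rows])
    volume_cc = float(meta["volume_cc"]) if "volume_cc" in meta else None
    if volume_unit == "cc":
        if volume_cc is None:
            raise DVHFileError(
                f"{where}: volume_unit 'cc' requires a 'volume_cc' header for "
                "conversion to fractions"
            )
        vol = vol / volume_cc

    label = meta["structure"]
    if kind == "cumulative":
        if np.any(np.diff(vol) > 1e-9):
            raise DVHFileError(
                f"{where}: cumulative volume column must be non-increasing"
            )
        dvh: Union[DifferentialDVH, CumulativeDVH] = CumulativeDVH(
            dose, vol, structure_label=label, volume_cc=volume_cc
        )
    else:
        dvh = make_differential(dose, vol, label=label, volume_cc=volume_cc)
    return DVHFileRecord(
        dvh=dvh, kind=kind, plan=meta.get("plan"), patient=meta.get("patient")
    )


def read_dvh_csv(path: Union[str, Path]) -> list[DVHFileRecord]:
    """Read every DVH block from a file; validation errors name the block."""
    path = Path(path)
    text = path.read_text()
    blocks: list[list[str]] = []
    current: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(line)
    if current:
        blocks.append(current)
    if not blocks:
        raise DVHFileError(f"{path}: file contains no DVH blocks")
    return [
        _parse_block(block, where=f"{path} block {i + 1}")
        for i, block in enumerate(blocks)
    ]


def _format_block(rec: DVHFileRecord) -> str:
    dvh = rec.dvh
    if isinstance(dvh, CumulativeDVH):
        kind, dose, vol = "cumulative", dvh.dose_grid, dvh.volume_fraction
    else:
        kind, dose, vol = "differential", dvh.bin_dose, dvh.bin_volume
    lines = [
        f"# structure: {dvh.structure_label}",
        f"# type: {kind}",
        "# dose_unit: Gy",
        "# volume_unit: relative",
    ]
    if dvh.volume_cc is not None:
        lines.append(f"# volume_cc: {dvh.volume_cc:g}")
    if rec.plan:
        lines.append(f"# plan: {rec.plan}")
    if rec.patient:
        lines.append(f"# patient: {rec.patient}")
    lines.append("dose,volume")
    lines.extend(f"{d:.3f},{v:.6f}" for d, v in zip(dose, vol))
    return "\n".join(lines)


def write_dvh_csv(
    records: list[Union[DVHFileRecord, DifferentialDVH, CumulativeDVH]],
    path: Union[str, Path],
) -> Path:
    """Write DVH blocks with deterministic formatting; re-readable."""
    path = Path(path)
    wrapped = [
        r
        if isinstance(r, DVHFileRecord)
        else DVHFileRecord(
            dvh=r, kind="cumulative" if isinstance(r, CumulativeDVH) else "differential"
        )
        for r in records
    ]
    if not wrapped:
        logger.warning("writing empty DVH file %s", path)
        path.write_text("dose,volume\n")
        return path
    path.write_text("\n\n".join(_format_block(r) for r in wrapped) + "\n")
    return path


def read_cohort_csv(path: Union[str, Path]) -> CohortNTCP:
    """Read a cohort risk table (patient_id, plan, endpoint, ntcp columns).

    An ``ntcp`` column is taken as fractions in [0, 1]; an ``ntcp_pct``
    column as percent.
    """
    df = pd.read_csv(path)
    if "ntcp_pct" in df.columns and "ntcp" not in df.columns:
        df = df.rename(columns={"ntcp_pct": "ntcp"})
        df["ntcp"] = df["ntcp"] / 100.0
    return CohortNTCP(df)


def write_cohort_csv(c: CohortNTCP, path: Union[str, Path]) -> Path:
    """Write the cohort table with NTCP in percent, one decimal."""
    path = Path(path)
    out = c.table.copy()
    out["ntcp_pct"] = (100.0 * out.pop("ntcp")).round(1)
    out.to_csv(path, index=False)
    return path


def write_comparison_csv(t: ComparisonTable, path: Union[str, Path]) -> Path:
    """Write the plan-comparison summary (and the re-plan contrast) as CSV."""
    path = Path(path)
    summary = t.summary.copy()
    for col in ("mean_pct", "sd_pct", "delta_mean_pct", "delta_sd_pct"):
        summary[col] = summary[col].round(1)
    for col in ("t", "p_two_sided"):
        summary[col] = summary[col].round(6)
    summary.to_csv(path, index=False)
    contrast_path = path.with_name(path.stem + "_contrast" + path.suffix)
    contrast = t.replan_contrast.copy()
    for col in ("delta_mean_pct", "delta_sd_pct"):
        contrast[col] = contrast[col].round(1)
    for col in ("t", "p_two_sided"):
        contrast[col] = contrast[col].round(6)
    contrast.to_csv(contrast_path, index=False)
    return path
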