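"""Plain-text sweep file format.

No public instrument format exists for these measurements, so the
package defines an inspectable delimited-text layout: '#'-prefixed
``key=value`` header lines carrying the acquisition metadata, followed
by a tab-separated table with units fixed in the column names
(``H_Oe  ReM2_emu_per_g  ImM2_emu_per_g  branch``).  Values are
written with nine significant digits, so a write/read round trip is
bit-exact for decimal representations up to that precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datatypes import DriveConditions, FieldSweepBranch, M2Curve

__all__ = ["read_sweep", "write_sweep", "read_curve", "write_curve", "SweepFormatError"]

_COLUMNS = ("H_Oe", "ReM2_emu_per_g", "ImM2_emu_per_g", "branch")
_REQUIRED_KEYS = ("specimen", "h_Oe", "f_Hz", "Fsc_Hz", "T_K")
_CURVE_COLUMNS = ("H_Oe", "ReM2_emu_per_g", "ImM2_emu_per_g")


class SweepFormatError(ValueError):
    """Malformed sweep file (the message names the offending line or key)."""


def _parse_header(lines, path):
    meta = {}
    n_header = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if not body:
            continue
        if "=" not in body:
            raise SweepFormatError(f"{path}: line {i + 1}: header line without '='")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    return meta, n_header


def _require(meta, keys, path):
    for key in keys:
        if key not in meta:
            raise SweepFormatError(f"{path}: missing required metadata key '{key}'")


def write_sweep(branches, path, metadata: dict | None = None) -> None:
    """Write one or more branches of a single specimen/F_sc to a text file."""
    branches = list(branches)
    if not branches:
        raise ValueError("no branches to write")
    first = branches[0]
    seen = set()
    for b in branches:
        if b.direction in seen:
            raise SweepFormatError(f"duplicate branch label '{b.direction}'")
        seen.add(b.direction)
        if b.F_sc != first.F_sc or b.drive != first.drive:
            raise SweepFormatError("branches in one file must share F_sc and drive")

    meta = {
        "specimen": first.label or "unknown",
        "h_Oe": f"{first.drive.h:.9g}",
        "f_Hz": f"{first.drive.f:.9g}",
        "Fsc_Hz": f"{first.F_sc:.9g}",
        "T_K": f"{first.drive.T:.9g}",
    }
    if first.specimen_mass is not None:
        meta["mass_g"] = f"{first.specimen_mass:.9g}"
    if metadata:
        meta.update({k: str(v) for k, v in metadata.items()})

    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for b in branches:
            for H, re, im in zip(b.H, b.re, b.im):
                fh.write(f"{H:.9g}\t{re:.9g}\t{im:.9g}\t{b.direction}\n")


def read_sweep(path) -> list:
    """Read a sweep file; returns one FieldSweepBranch per branch label."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, n_header = _parse_header(lines, path)
    _require(meta, _REQUIRED_KEYS, path)

    body = lines[n_header:]
    if not body:
        raise SweepFormatError(f"{path}: no data rows")
    header = body[0].split("\t")
    if tuple(header) != _COLUMNS:
        raise SweepFormatError(
            f"{path}: line {n_header + 1}: expected columns {'/'.join(_COLUMNS)}"
        )

    try:
        drive = DriveConditions(
            h=float(meta["h_Oe"]), f=float(meta["f_Hz"]), T=float(meta["T_K"]),
            H_grid=np.array([0.0]),
        )
        F_sc = float(meta["Fsc_Hz"])
    except ValueError as err:
        raise SweepFormatError(f"{path}: bad numeric metadata: {err}") from None

    data = {}
    last_branch = None
    for offset, line in enumerate(body[1:], start=n_header + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise SweepFormatError(f"{path}: line {offset}: expected 4 columns")
        try:
            H, re, im = float(parts[0]), float(parts[1]), float(parts[2])
        except ValueError:
            raise SweepFormatError(
                f"{path}: line {offset}: non-numeric value"
            ) from None
        branch = parts[3].strip()
        if branch not in ("direct", "reverse"):
            raise SweepFormatError(
                f"{path}: line {offset}: unknown branch label '{branch}'"
            )
        if branch in data and last_branch != branch:
            raise SweepFormatError(
                f"{path}: line {offset}: duplicate branch block '{branch}'"
            )
        data.setdefault(branch, []).append((H, re, im))
        last_branch = branch

    mass = float(meta["mass_g"]) if "mass_g" in meta else None
    out = []
    for direction, rows in data.items():
        arr = np.array(rows)
        out.append(FieldSweepBranch(
            H=arr[:, 0], re=arr[:, 1], im=arr[:, 2],
            direction=direction, F_sc=F_sc,
            drive=drive.with_grid(np.sort(arr[:, 0])),
            label=meta["specimen"], specimen_mass=mass,
        ))
    return out


def write_curve(curve: M2Curve, path, metadata: dict | None = None) -> None:
    """Write a preprocessed fit-ready curve with its applicability verdict."""
    meta = {
        "specimen": curve.label or "unknown",
        "h_Oe": f"{curve.drive.h:.9g}",
        "f_Hz": f"{curve.drive.f:.9g}",
        "T_K": f"{curve.drive.T:.9g}",
        "applicability": curve.applicability,
    }
    if curve.hysteresis_index is not None:
        meta["hysteresis_index"] = f"{curve.hysteresis_index:.9g}"
    if metadata:
        meta.update({k: str(v) for k, v in metadata.items()})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(_CURVE_COLUMNS) + "\n")
        for H, re, im in zip(curve.H, curve.re, curve.im):
            fh.write(f"{H:.9g}\t{re:.9g}\t{im:.9g}\n")


def read_curve(path) -> M2Curve:
    """Read a preprocessed curve file written by :func:`write_curve`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, n_header = _parse_header(lines, path)
    _require(meta, ("specimen", "h_Oe", "f_Hz", "T_K", "applicability"), path)
    body = lines[n_header:]
    if not body or tuple(body[0].split("\t")) != _CURVE_COLUMNS:
        raise SweepFormatError(f"{path}: expected columns {'/'.join(_CURVE_COLUMNS)}")
    rows = []
    for offset, line in enumerate(body[1:], start=n_header + 2):
        if not line.strip():
            continue
        try:
            rows.append([float(v) for v in line.split("\t")])
        except ValueError:
            raise SweepFormatError(f"{path}: line {offset}: non-numeric value") from None
    arr = np.array(rows)
    drive = DriveConditions(
        h=float(meta["h_Oe"]), f=float(meta["f_Hz"]), T=float(meta["T_K"]),
        H_grid=arr[:, 0],
    )
    return M2Curve(
        H=arr[:, 0], re=arr[:, 1], im=arr[:, 2], drive=drive,
        hysteresis_index=(
            float(meta["hysteresis_index"]) if "hysteresis_index" in meta else None
        ),
        applicability=meta["applicability"],
        label=meta["specimen"],
    )
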