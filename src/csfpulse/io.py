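"""Reading and writing PC-MRI series, masks and cohort tables.

A cardiac-gated phase-contrast series is stored on disk as two 4D NIfTI
files (magnitude and phase, dims rows x cols x 1 x frames) plus a JSON
sidecar carrying the acquisition metadata that the voxel data cannot:
velocity encoding (V_enc, cm/s), pixel spacing (mm), cardiac period (s) and
gating type. Phase is stored in radians in (-pi, pi]; conversion from
vendor-scaled integers is the caller's responsibility.

Cohort tables are plain CSV with one ``metric[unit]`` column per metric and
fixed identity columns (subject_id, group, site, pair_id).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "PCMRISeries",
    "CohortTable",
    "SidecarError",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
]

GATING_TYPES = ("ecg", "ppg")

#: groups used throughout the cohort tables
GROUPS = ("pre_shunt", "post_shunt", "control")
SITES = ("aqueduct", "cistern")

_IDENTITY_COLUMNS = ["subject_id", "group", "site", "pair_id"]


class SidecarError(ValueError):
    """Raised when the JSON sidecar is missing or schema-invalid."""


@dataclass
class PCMRISeries:
    """One cardiac-gated PC-MRI acquisition: magnitude + phase over a cycle.

    Parameters
    ----------
    magnitude : (rows, cols, frames) array, non-negative, arbitrary units.
    phase : (rows, cols, frames) array, radians in (-pi, pi].  The velocity
        encoding maps a velocity of +/- V_enc onto a phase of +/- pi.
    venc_cm_s : velocity encoding parameter in cm/s.
    pixel_spacing_mm : in-plane voxel edge length in mm (square voxels).
    period_s : cardiac period in seconds.
    gating : "ecg" or "ppg" (pulse oximetry).  Latency analyses are only
        comparable across ECG-gated series, where frame 0 is the R-wave.
    frame_times : normalized frame times in [0, 1); uniform by default
        (idealized retrospective gating).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc_cm_s: float
    pixel_spacing_mm: float
    period_s: float
    gating: str = "ecg"
    frame_times: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} != phase shape "
                f"{self.phase.shape}"
            )
        if self.magnitude.ndim != 3:
            raise ValueError("voxel stacks must be rows x cols x frames")
        if self.n_frames < 8:
            raise ValueError(f"need >= 8 frames, got {self.n_frames}")
        if self.magnitude.min() < 0:
            raise ValueError("magnitude must be non-negative")
        lo, hi = self.phase.min(), self.phase.max()
        if lo <= -math.pi - 1e-9 or hi > math.pi + 1e-9:
            raise ValueError(
                f"phase values outside (-pi, pi]: range [{lo:.4g}, {hi:.4g}]; "
                "use rewrap=True on read to normalize"
            )
        if not self.venc_cm_s > 0:
            raise ValueError("venc_cm_s must be positive")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not self.period_s > 0:
            raise ValueError("period_s must be positive")
        if self.gating not in GATING_TYPES:
            raise ValueError(f"unknown gating {self.gating!r}; expected {GATING_TYPES}")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames) / self.n_frames
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm**2

    @property
    def bpm(self) -> float:
        return 60.0 / self.period_s


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap arbitrary radians into (-pi, pi]."""
    wrapped = np.mod(-phi + math.pi, 2 * math.pi)
    return -(wrapped - math.pi)


_SIDECAR_REQUIRED = ("venc_cm_s", "pixel_spacing_mm", "period_s", "gating", "n_frames")


def write_series(series: PCMRISeries, out_dir: str | Path) -> dict[str, Path]:
    """Write a series as magnitude/phase NIfTI pair + JSON sidecar.

    Voxel data is written float32; metadata round-trips losslessly.
    Returns the paths written, keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    affine = np.diag([series.pixel_spacing_mm, series.pixel_spacing_mm, 1.0, 1.0])
    for name, arr in (("magnitude", series.magnitude), ("phase", series.phase)):
        img = nib.Nifti1Image(arr[:, :, None, :].astype(np.float32), affine)
        p = out / f"{name}.nii.gz"
        nib.save(img, p)
        paths[name] = p
    sidecar = {
        "venc_cm_s": series.venc_cm_s,
        "pixel_spacing_mm": series.pixel_spacing_mm,
        "period_s": series.period_s,
        "bpm": series.bpm,
        "gating": series.gating,
        "n_frames": series.n_frames,
        "frame_times": series.frame_times.tolist(),
        "seed": series.seed,
    }
    p = out / "series.json"
    p.write_text(json.dumps(sidecar, indent=2) + "\n")
    paths["sidecar"] = p
    return paths


def read_series(in_dir: str | Path, rewrap: bool = False) -> PCMRISeries:
    """Read a series written by :func:`write_series`.

    Parameters
    ----------
    rewrap : if True, phase values outside (-pi, pi] are wrapped back into
        range instead of raising.
    """
    in_dir = Path(in_dir)
    sidecar_path = in_dir / "series.json"
    if not sidecar_path.exists():
        raise SidecarError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta or meta[key] is None:
            raise SidecarError(f"sidecar missing required field {key!r}")
    if meta["gating"] not in GATING_TYPES:
        raise SidecarError(f"unknown gating string {meta['gating']!r}")
    mag = np.asarray(nib.load(in_dir / "magnitude.nii.gz").dataobj, dtype=float)
    phs = np.asarray(nib.load(in_dir / "phase.nii.gz").dataobj, dtype=float)
    mag, phs = mag[:, :, 0, :], phs[:, :, 0, :]
    if rewrap:
        phs = _wrap_phase(phs)
    ft = meta.get("frame_times")
    return PCMRISeries(
        magnitude=mag,
        phase=phs,
        venc_cm_s=float(meta["venc_cm_s"]),
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
        period_s=float(meta["period_s"]),
        gating=meta["gating"],
        frame_times=None if ft is None else np.asarray(ft, dtype=float),
        seed=meta.get("seed"),
    )


def write_mask(mask: np.ndarray, path: str | Path, pixel_spacing_mm: float = 1.0) -> Path:
    """Write a 2D boolean mask as a uint8 NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(path).dataobj)
    return np.squeeze(arr).astype(bool)


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass
class CohortTable:
    """Per-subject metric rows with group labels; the unit of comparison.

    Wraps a DataFrame with identity columns (subject_id, group, site,
    pair_id) plus one ``metric[unit]`` column per metric, e.g.
    ``area[mm2]``, ``sv_bradley[uL]``, ``pfl[%cycle]``.  ``pair_id`` links
    exactly one pre_shunt and one post_shunt row per site for matched
    pre/post scans.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_IDENTITY_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _IDENTITY_COLUMNS:
            if col not in df.columns:
                df[col] = pd.Series(dtype=object)
        bad_groups = set(df["group"].dropna()) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels {sorted(bad_groups)}")
        bad_sites = set(df["site"].dropna()) - set(SITES)
        if bad_sites:
            raise ValueError(f"unknown site labels {sorted(bad_sites)}")
        key = df[["subject_id", "site", "group"]].astype(str).agg("|".join, axis=1)
        if key.duplicated().any():
            dupes = sorted(key[key.duplicated()].unique())
            raise ValueError(f"duplicate subject_id+site+group rows: {dupes}")
        self.df = df[_IDENTITY_COLUMNS + [c for c in df.columns if c not in _IDENTITY_COLUMNS]]

    @property
    def metrics(self) -> list[str]:
        return [c for c in self.df.columns if c not in _IDENTITY_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    def values_for(self, metric: str, group: str, site: str | None = None) -> np.ndarray:
        sel = self.df["group"] == group
        if site is not None:
            sel &= self.df["site"] == site
        return self.df.loc[sel, metric].to_numpy(dtype=float)

    def paired(self, metric: str, site: str) -> tuple[np.ndarray, np.ndarray, list]:
        """Extract matched (pre_shunt, post_shunt) value pairs for a site.

        Returns (pre, post, pair_ids); rows lacking a complete pair are
        dropped.  Raises if any pair_id links more than one row per group.
        """
        sub = self.df[(self.df["site"] == site) & self.df["pair_id"].notna()]
        pre_rows = sub[sub["group"] == "pre_shunt"]
        post_rows = sub[sub["group"] == "post_shunt"]
        for rows, label in ((pre_rows, "pre_shunt"), (post_rows, "post_shunt")):
            if rows["pair_id"].duplicated().any():
                raise ValueError(f"pair_id maps to multiple {label} rows at site {site}")
        pre_map = dict(zip(pre_rows["pair_id"], pre_rows[metric]))
        post_map = dict(zip(post_rows["pair_id"], post_rows[metric]))
        ids = sorted(set(pre_map) & set(post_map), key=str)
        pre = np.array([pre_map[i] for i in ids], dtype=float)
        post = np.array([post_map[i] for i in ids], dtype=float)
        return pre, post, ids

    def append_row(self, **fields) -> None:
        row = {c: fields.pop(c, None) for c in _IDENTITY_COLUMNS}
        row.update(fields)
        df = pd.concat([self.df, pd.DataFrame([row])], ignore_index=True)
        # re-validate (duplicates etc.)
        self.df = CohortTable(df).df


def write_cohort_table(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path)
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].astype(object).where(df["pair_id"].notna(), None)
    return CohortTable(df)
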