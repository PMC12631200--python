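"""On-disk artifacts: spectra CSV, point-cloud XYZI text, YAML config, JSON reports.

The spectra CSV dialect is comma-separated UTF-8 with a mandatory header:
``tree_id,stage,dp,<wl>,<wl>,...`` where each band column is named by its
wavelength in nm rounded to two decimals. Point clouds are whitespace-
separated text with four float columns x y z intensity; z is assumed
already ground-normalized (height above terrain).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from defoliascan.damage import stage_from_dp
from defoliascan.errors import FormatError, InvalidInputError

META_COLUMNS = ("tree_id", "stage", "dp")


@dataclass
class SpectraTable:
    """Per-tree mean canopy reflectance over a shared wavelength grid.

    Attributes
    ----------
    tree_id : ndarray of str, shape (n,)
    stage : ndarray of int, shape (n,)
        Ordinal damage stage codes (1 mild, 2 moderate, 3 severe).
    dp : ndarray of float, shape (n,)
        Defoliation percentage; NaN allowed when unknown.
    reflectance : ndarray of float, shape (n, B)
        Unitless reflectance in [0, 1].
    wavelengths : ndarray of float, shape (B,)
        Strictly increasing band centers in nm.
    """

    tree_id: np.ndarray
    stage: np.ndarray
    dp: np.ndarray
    reflectance: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.tree_id = np.asarray(self.tree_id, dtype=object)
        self.stage = np.asarray(self.stage, dtype=int)
        self.dp = np.asarray(self.dp, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n = len(self.tree_id)
        if self.reflectance.shape != (n, len(self.wavelengths)):
            raise InvalidInputError(
                f"reflectance shape {self.reflectance.shape} inconsistent with "
                f"{n} trees x {len(self.wavelengths)} bands"
            )
        if self.stage.shape != (n,) or self.dp.shape != (n,):
            raise InvalidInputError("stage/dp length must match tree count")
        if len(self.wavelengths) and np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if np.any(~np.isfinite(self.reflectance)):
            raise InvalidInputError("reflectance contains missing values")
        known = np.isfinite(self.dp)
        if np.any(known):
            expected = stage_from_dp(self.dp[known])
            if np.any(expected != self.stage[known]):
                bad = np.flatnonzero(expected != self.stage[known])[0]
                raise InvalidInputError(
                    f"stage inconsistent with dp for tree {self.tree_id[np.flatnonzero(known)[bad]]}"
                )

    @property
    def n_trees(self) -> int:
        return len(self.tree_id)

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def band_nearest(self, wavelength_nm: float) -> int:
        """Index of the grid band closest to a target wavelength."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def subset(self, rows) -> "SpectraTable":
        """New table restricted to the given row indices."""
        rows = np.asarray(rows)
        return SpectraTable(
            tree_id=self.tree_id[rows],
            stage=self.stage[rows],
            dp=self.dp[rows],
            reflectance=self.reflectance[rows],
            wavelengths=self.wavelengths,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "tree_id": self.tree_id,
            "stage": self.stage,
            "dp": self.dp,
        }
        frame = pd.DataFrame(cols)
        band_names = [f"{w:.2f}" for w in self.wavelengths]
        return pd.concat(
            [frame, pd.DataFrame(self.reflectance, columns=band_names)], axis=1
        )


@dataclass
class TreePointCloud:
    """Single-tree LiDAR returns; z ground-normalized, intensity unitless."""

    tree_id: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.x)
        if any(len(a) != n for a in (self.y, self.z, self.intensity)):
            raise InvalidInputError("point cloud columns must share one length")
        for name, a in (("x", self.x), ("y", self.y), ("z", self.z)):
            if np.any(~np.isfinite(a)):
                raise InvalidInputError(f"non-finite {name} coordinate")
        if np.any(self.intensity < 0):
            raise InvalidInputError("intensity must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.x)

    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class RunConfig:
    """End-to-end pipeline settings (seed fan-out, split, CV, RF, selection)."""

    seed: int = 0
    split_ratio: float = 0.6
    cv_folds: int = 10
    selection_method: str = "isic-spa"  # spa | isic | isic-spa | fixed
    fixed_wavelengths: tuple = (686.0, 759.0, 926.0)
    k_max: int = 10
    n_starts: int | None = 20  # SPA launch bands (None = all)
    accuracy_tol: float = 0.005
    selection_trees: int = 100  # forest size inside selection CV
    rf_trees: int = 500
    rf_seed: int = 42
    alpha: float = 0.01
    outdir: str = "run_output"
    spectra_path: str | None = None
    clouds_dir: str | None = None
    simulate: bool = True
    write_clouds: bool = False

    def __post_init__(self):
        if not 0 < self.split_ratio < 1:
            raise InvalidInputError("split ratio must be in (0, 1)")
        if self.cv_folds < 2:
            raise InvalidInputError("cv_folds must be >= 2")
        if self.selection_method not in ("spa", "isic", "isic-spa", "fixed"):
            raise InvalidInputError(f"unknown selection method {self.selection_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "fixed_wavelengths" in raw:
            raw["fixed_wavelengths"] = tuple(raw["fixed_wavelengths"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["fixed_wavelengths"] = list(data["fixed_wavelengths"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def write_spectra(table: SpectraTable, path) -> None:
    """Write a SpectraTable as the canonical CSV dialect."""
    table.to_frame().to_csv(path, index=False)


def read_spectra(path) -> SpectraTable:
    """Read and validate a spectra CSV; band columns re-sorted ascending."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"spectra file not found: {path}")
    df = pd.read_csv(path)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    band_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not band_cols:
        raise FormatError(f"no band columns found in {path}")
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise FormatError(f"band column header not a wavelength: {exc}") from None
    for col in band_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_row = int(coerced.index[coerced.isna() & df[col].notna()][0])
            raise FormatError(
                f"non-numeric reflectance at row {bad_row}, column {col!r}"
            )
        if df[col].isna().any():
            bad_row = int(df[col].index[df[col].isna()][0])
            raise FormatError(f"missing reflectance at row {bad_row}, column {col!r}")
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    reflectance = df[band_cols].to_numpy(dtype=float)[:, order]
    dp = pd.to_numeric(df["dp"], errors="coerce").to_numpy(dtype=float)
    return SpectraTable(
        tree_id=df["tree_id"].astype(str).to_numpy(dtype=object),
        stage=df["stage"].to_numpy(dtype=int),
        dp=dp,
        reflectance=reflectance,
        wavelengths=wavelengths,
    )


def write_cloud(cloud: TreePointCloud, path) -> None:
    """Write XYZI whitespace text with round-trip-exact float formatting."""
    data = np.column_stack([cloud.x, cloud.y, cloud.z, cloud.intensity])
    np.savetxt(path, data, fmt="%.17g")


def read_cloud(path, tree_id: str | None = None) -> TreePointCloud:
    """Read an XYZI text point cloud.

    Lines must carry at least four whitespace-separated floats
    (x, y, z, intensity); extra columns are ignored with a warning.
    An empty file yields an empty cloud (downstream metric computation
    rejects it).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"point cloud file not found: {path}")
    if tree_id is None:
        tree_id = path.stem
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 4 columns (x y z intensity), "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts[:4]])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from None
            if len(parts) > 4 and lineno == 1:
                warnings.warn(
                    f"{path}: extra columns beyond XYZI ignored", stacklevel=2
                )
    if not rows:
        return TreePointCloud(tree_id, [], [], [], [])
    arr = np.asarray(rows, dtype=float)
    return TreePointCloud(tree_id, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def write_json_report(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
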