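"""Spectra container, CSV/JCAMP-DX readers, and calibration/validation splits.

The wide CSV layout is rows = samples, a sample-id column, an optional class
label column, optional metadata columns (fish id, anatomical region,
replicate index), and one column per wavelength whose header is the bare
wavelength in nm.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Freeze-thaw state vocabulary: fresh, once frozen-thawed, twice frozen-thawed.
CLASSES: tuple[str, ...] = ("fresh", "frozen1", "frozen2")

#: Label for a sample rejected by every class model.
NO_MATCH = "no_match"

#: Metadata column names recognised by default in wide CSV files.
DEFAULT_META_COLUMNS = ("fish_id", "region", "replicate")


@dataclass
class SpectraSet:
    """A set of absorbance spectra on a shared wavelength grid.

    Parameters
    ----------
    wavelengths : array of shape (n_channels,)
        Strictly increasing wavelengths in nm.
    absorbance : array of shape (n_samples, n_channels)
        Absorbance units; finite everywhere.
    sample_ids : list of str
        Unique identifiers, one per row.
    labels : list of str or None
        Per-sample class label from :data:`CLASSES`, or None if unlabeled.
    meta : DataFrame or None
        Optional per-sample metadata (e.g. fish_id, region, replicate),
        index-aligned with the rows.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    labels: list[str] | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {p} columns but there are "
                f"{self.wavelengths.size} wavelengths"
            )
        if n != len(self.sample_ids):
            raise ValueError("sample_ids length does not match absorbance rows")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValueError(
                f"non-finite absorbance for sample {self.sample_ids[bad[0]]!r} "
                f"at wavelength {self.wavelengths[bad[1]]:g} nm"
            )
        if len(set(self.sample_ids)) != n:
            seen: set[str] = set()
            dups: set[str] = set()
            for s in self.sample_ids:
                if s in seen:
                    dups.add(s)
                seen.add(s)
            raise ValueError(f"duplicate sample ids: {sorted(dups)}")
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValueError("labels length does not match absorbance rows")
            unknown = sorted(set(self.labels) - set(CLASSES))
            if unknown:
                raise ValueError(
                    f"unknown class labels {unknown}; expected one of {CLASSES}"
                )
        if self.meta is not None and len(self.meta) != n:
            raise ValueError("meta row count does not match absorbance rows")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset (copy) preserving labels and metadata."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            absorbance=self.absorbance[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            meta=None if self.meta is None else self.meta.iloc[idx].reset_index(drop=True),
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same samples/grid with a replaced absorbance matrix."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            absorbance=np.asarray(absorbance, dtype=float).copy(),
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else list(self.labels),
            meta=None if self.meta is None else self.meta.copy(),
        )

    def class_indices(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("SpectraSet has no labels")
        return np.flatnonzero(np.asarray(self.labels) == label)


@dataclass
class SplitResult:
    """Outcome of a stratified calibration/validation split."""

    calibration: SpectraSet
    validation: SpectraSet
    seed: int
    fraction: float
    group_key: str | None = None

    def manifest(self) -> dict:
        """JSON-ready provenance record of the split."""
        counts = {}
        for name, part in (("calibration", self.calibration), ("validation", self.validation)):
            labels = part.labels or []
            counts[name] = {c: int(sum(1 for l in labels if l == c)) for c in CLASSES}
            counts[name]["total"] = part.n_samples
        return {
            "seed": self.seed,
            "fraction": self.fraction,
            "group_key": self.group_key,
            "counts": counts,
        }


def read_spectra_csv(
    path: str | Path,
    label_column: str = "label",
    id_column: str = "id",
    meta_columns: Sequence[str] = DEFAULT_META_COLUMNS,
    reflectance: bool = False,
) -> SpectraSet:
    """Read a wide-format spectra CSV into a :class:`SpectraSet`.

    Columns other than ``id_column``, ``label_column`` and the recognised
    ``meta_columns`` must have numeric headers (wavelength in nm); anything
    else is a hard error. Wavelength columns may appear in any order and are
    sorted ascending, permuting the absorbance columns consistently.

    With ``reflectance=True`` the stored values are taken as reflectance R
    and converted to apparent absorbance log10(1/R) at load; all downstream
    math operates on absorbance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype={id_column: str})
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    ids = df[id_column].astype(str).tolist()
    dup = sorted({s for s in ids if ids.count(s) > 1})
    if dup:
        raise ValueError(f"duplicate sample ids: {dup}")

    labels = None
    if label_column in df.columns:
        labels = df[label_column].astype(str).tolist()

    wl_cols: list[tuple[float, str]] = []
    meta_present: list[str] = []
    for col in df.columns:
        if col == id_column or col == label_column:
            continue
        if col in meta_columns:
            meta_present.append(col)
            continue
        try:
            wl_cols.append((float(col), col))
        except ValueError:
            raise ValueError(
                f"non-numeric wavelength column header {col!r} "
                f"(declare it in meta_columns if it is metadata)"
            ) from None
    if not wl_cols:
        raise ValueError("no wavelength columns found")
    wl_cols.sort(key=lambda t: t[0])
    wavelengths = np.array([w for w, _ in wl_cols])

    spectral = df[[c for _, c in wl_cols]]
    values = spectral.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"NaN absorbance for sample {ids[r]!r} at wavelength "
            f"{wavelengths[c]:g} nm"
        )
    if reflectance:
        if np.any(values <= 0):
            raise ValueError("reflectance values must be positive for log10(1/R)")
        values = np.log10(1.0 / values)

    meta = df[meta_present].reset_index(drop=True) if meta_present else None
    return SpectraSet(wavelengths, values, ids, labels, meta)


def write_spectra_csv(data: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as a wide CSV (inverse of the reader)."""
    path = Path(path)
    cols: dict[str, object] = {"id": data.sample_ids}
    if data.labels is not None:
        cols["label"] = data.labels
    frame = pd.DataFrame(cols)
    if data.meta is not None:
        frame = pd.concat([frame, data.meta.reset_index(drop=True)], axis=1)
    spectral = pd.DataFrame(
        data.absorbance, columns=[repr(float(w)) for w in data.wavelengths]
    )
    frame = pd.concat([frame, spectral], axis=1)
    frame.to_csv(path, index=False)


def split_calibration_validation(
    data: SpectraSet,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    group_key: str | None = None,
) -> SplitResult:
    """Stratified random calibration/validation split.

    Per class, round(fraction * class size) samples go to calibration. With
    ``group_key`` (a metadata column, e.g. ``fish_id``) all samples sharing a
    key stay on the same side; grouped allocation is greedy, so per-class
    counts can then deviate from the target by up to one group. Deterministic
    for a fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if data.labels is None or any(l is None for l in data.labels):
        raise ValueError("every sample must be labeled before splitting")
    rng = np.random.default_rng(seed)
    labels = np.asarray(data.labels)
    cal_idx: list[int] = []
    val_idx: list[int] = []
    for cls in CLASSES:
        members = np.flatnonzero(labels == cls)
        if members.size == 0:
            continue
        target = int(np.floor(fraction * members.size + 0.5))
        target = min(max(target, 0), members.size)
        if group_key is None:
            perm = rng.permutation(members)
            cal_idx.extend(perm[:target].tolist())
            val_idx.extend(perm[target:].tolist())
        else:
            if data.meta is None or group_key not in data.meta.columns:
                raise ValueError(f"meta column {group_key!r} not present")
            keys = data.meta[group_key].astype(str).to_numpy()
            groups: dict[str, list[int]] = {}
            for i in members:
                groups.setdefault(keys[i], []).append(int(i))
            names = sorted(groups)
            order = rng.permutation(len(names))
            largest = max(len(v) for v in groups.values())
            if largest > max(target, members.size - target):
                warnings.warn(
                    f"group larger than one split side in class {cls!r}; "
                    "kept intact",
                    stacklevel=2,
                )
            placed = 0
            for j in order:
                g = groups[names[j]]
                if placed < target:
                    cal_idx.extend(g)
                    placed += len(g)
                else:
                    val_idx.extend(g)
    cal_idx.sort()
    val_idx.sort()
    return SplitResult(
        calibration=data.subset(cal_idx),
        validation=data.subset(val_idx),
        seed=seed,
        fraction=fraction,
        group_key=group_key,
    )


def write_split(result: SplitResult, outdir: str | Path, stem: str = "spectra") -> None:
    """Write a split as two CSVs plus a JSON manifest (seed, fraction, counts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(result.calibration, outdir / f"{stem}_calibration.csv")
    write_spectra_csv(result.validation, outdir / f"{stem}_validation.csv")
    with open(outdir / f"{stem}_split.json", "w") as fh:
        json.dump(result.manifest(), fh, indent=2, sort_keys=True)


def resample(data: SpectraSet, grid: np.ndarray) -> SpectraSet:
    """Linear interpolation of every spectrum onto a new wavelength grid.

    Intended for merging sets recorded on unequal grids; the target grid must
    lie within the source range (no extrapolation).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < data.wavelengths.min() or grid.max() > data.wavelengths.max():
        raise ValueError("target grid extends beyond the recorded range")
    interp = np.vstack(
        [np.interp(grid, data.wavelengths, row) for row in data.absorbance]
    )
    out = data.with_absorbance(data.absorbance)
    out.wavelengths = grid
    out.absorbance = interp
    out.validate()
    return out


_JCAMP_NUM = re.compile(r"[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")


def read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX single-spectrum reader (XYDATA=(X++(Y..Y)), AFFN).

    Supports a linear X axis: X values are reconstructed from FIRSTX/LASTX/
    NPOINTS (checked against the leading X of each data line), Y values are
    scaled by YFACTOR. Returns (wavelengths, absorbance).
    """
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                break
            header[key] = value.strip()
            continue
        if in_data:
            nums = [float(t) for t in _JCAMP_NUM.findall(line)]
            if nums:
                ys.extend(nums[1:])  # first token is the line's X value
    if not ys:
        raise ValueError("no XYDATA found")
    npoints = int(float(header.get("NPOINTS", len(ys))))
    if npoints != len(ys):
        raise ValueError(f"NPOINTS={npoints} but parsed {len(ys)} Y values")
    firstx = float(header["FIRSTX"]) * float(header.get("XFACTOR", 1.0))
    lastx = float(header["LASTX"]) * float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ys) * yfactor
    return x, y
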