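"""Aquagram: standardized water-band absorbance at water matrix coordinates.

For each chosen wavelength lambda the aquagram value of a sample is

    Aq_lambda = (A_lambda - mu_lambda) / sigma_lambda

where A is the MSC-corrected absorbance and mu/sigma are the mean and
standard deviation over all spectra in the set (pooled across classes,
sample SD with n-1 denominator). Plotted on a radar chart, the profile
visualizes shifts between free / weakly hydrogen-bonded water (lower first
overtone, ~1340-1410 nm) and strongly hydrogen-bonded water (~1440-1520 nm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from freezenir.preprocess import msc
from freezenir.spectra_io import CLASSES, SpectraSet

#: Default water matrix coordinates (nm) in the first overtone of water.
#: A documented convention of this package, chosen inside the aquaphotomics
#: span 1342-1518 nm; see docs/methods.md for the selection rationale.
DEFAULT_COORDINATES: tuple[float, ...] = (
    1342.0, 1364.0, 1374.0, 1384.0, 1396.0, 1404.0,
    1444.0, 1452.0, 1464.0, 1476.0, 1494.0, 1518.0,
)


@dataclass
class AquagramValues:
    coordinates: np.ndarray          # snapped coordinates (nm), = grid channels
    requested: np.ndarray            # coordinates as requested (nm)
    snap_distance: np.ndarray        # |snapped - requested| per coordinate (nm)
    values: np.ndarray               # (n_samples, n_coordinates), standardized
    sample_ids: list[str]
    labels: list[str] | None
    class_means: pd.DataFrame        # rows = classes present, cols = coordinates
    normalization_mean: np.ndarray   # mu_lambda over all spectra (MSC-corrected)
    normalization_sd: np.ndarray     # sigma_lambda over all spectra (ddof=1)


def compute_aquagram(
    data: SpectraSet, coordinates: Sequence[float] = DEFAULT_COORDINATES
) -> AquagramValues:
    """MSC against the set mean, then per-coordinate standardization.

    Coordinates are snapped to the nearest wavelength channel (snap distance
    recorded). Requires at least two spectra and nonzero spread at every
    coordinate.
    """
    if data.n_samples < 2:
        raise ValueError("aquagram needs at least 2 spectra")
    requested = np.asarray(coordinates, dtype=float)
    idx = np.array(
        [int(np.argmin(np.abs(data.wavelengths - c))) for c in requested]
    )
    snapped = data.wavelengths[idx]
    corrected = msc(data, data.absorbance.mean(axis=0))
    A = corrected.absorbance[:, idx]
    mu = A.mean(axis=0)
    sigma = A.std(axis=0, ddof=1)
    zero = np.flatnonzero(sigma <= 1e-12 * (np.abs(mu) + 1.0))
    if zero.size:
        raise ValueError(
            f"zero standard deviation at coordinate {snapped[zero[0]]:g} nm"
        )
    values = (A - mu) / sigma

    if data.labels is not None:
        rows = {}
        for cls in CLASSES:
            members = np.flatnonzero(np.asarray(data.labels) == cls)
            if members.size:
                rows[cls] = values[members].mean(axis=0)
        class_means = pd.DataFrame.from_dict(rows, orient="index", columns=snapped)
    else:
        class_means = pd.DataFrame(columns=snapped)
    return AquagramValues(
        coordinates=snapped,
        requested=requested,
        snap_distance=np.abs(snapped - requested),
        values=values,
        sample_ids=list(data.sample_ids),
        labels=None if data.labels is None else list(data.labels),
        class_means=class_means,
        normalization_mean=mu,
        normalization_sd=sigma,
    )


def export_radar_table(aq: AquagramValues, path: str | Path) -> None:
    """Long-format CSV (sample_id, class, coordinate_nm, value) for plotting."""
    n, m = aq.values.shape
    rows = {
        "sample_id": np.repeat(aq.sample_ids, m),
        "class": np.repeat(
            aq.labels if aq.labels is not None else [""] * n, m
        ),
        "coordinate_nm": np.tile(aq.coordinates, n),
        "value": aq.values.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def export_class_means(aq: AquagramValues, path: str | Path) -> None:
    """Class-average aquagram values, one row per class."""
    out = aq.class_means.copy()
    out.index.name = "class"
    out.columns = [f"{c:g}" for c in out.columns]
    out.to_csv(path)
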