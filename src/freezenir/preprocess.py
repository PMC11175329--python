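"""Spectral pretreatments: Savitzky-Golay second derivative, multiplicative
scatter correction (MSC), and mean centering.

Classification models run on the second derivative of absorbance (removes
baseline offset/slope, sharpens overlapping bands); aquagrams run on
MSC-corrected raw absorbance. Both orderings are recorded in the fitted
model artifacts so prediction re-applies the same treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import savgol_filter

from freezenir.spectra_io import SpectraSet


@dataclass
class PreprocessConfig:
    """Savitzky-Golay / MSC settings.

    sg_window is in channels (odd, >= 5), sg_polyorder the fitted polynomial
    degree, sg_deriv the derivative order (2 throughout this pipeline).
    msc_reference is either the literal string "calibration-mean" or a fixed
    reference spectrum.
    """

    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 2
    msc_reference: np.ndarray | Literal["calibration-mean"] = "calibration-mean"

    def __post_init__(self) -> None:
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 5")
        if self.sg_polyorder < 2:
            raise ValueError("sg_polyorder must be >= 2")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be smaller than sg_window")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must not exceed sg_polyorder")

    def to_dict(self) -> dict:
        return {
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
            "msc_reference": (
                "calibration-mean"
                if isinstance(self.msc_reference, str)
                else list(np.asarray(self.msc_reference, dtype=float)),
            )[0],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        ref = d.get("msc_reference", "calibration-mean")
        if not isinstance(ref, str):
            ref = np.asarray(ref, dtype=float)
        return cls(
            sg_window=int(d.get("sg_window", 11)),
            sg_polyorder=int(d.get("sg_polyorder", 2)),
            sg_deriv=int(d.get("sg_deriv", 2)),
            msc_reference=ref,
        )


def second_derivative(data: SpectraSet, config: PreprocessConfig | None = None) -> SpectraSet:
    """Savitzky-Golay derivative of each spectrum with respect to wavelength.

    The derivative is taken per channel index and scaled by the mean
    wavelength step, so on a uniform grid a quadratic a*lam^2+b*lam+c maps to
    the constant 2a. Edge channels are handled by the boundary polynomial fit
    (scipy's ``mode='interp'``), so the output keeps the full channel count.
    """
    config = config or PreprocessConfig()
    if data.n_channels < config.sg_window:
        raise ValueError(
            f"sg_window={config.sg_window} exceeds channel count {data.n_channels}"
        )
    delta = float(np.mean(np.diff(data.wavelengths)))
    out = savgol_filter(
        data.absorbance,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.sg_deriv,
        delta=delta,
        axis=1,
        mode="interp",
    )
    return data.with_absorbance(out)


def msc(data: SpectraSet, reference: np.ndarray) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference (x ~ b + m*ref, least
    squares over channels) and replaced by (x - b) / m, removing per-sample
    multiplicative gain and additive offset. The reference maps to itself.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (data.n_channels,):
        raise ValueError("reference length must equal the channel count")
    if np.ptp(reference) == 0:
        raise ValueError("reference spectrum must not be constant")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    X = data.absorbance
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(slopes) < 1e-12):
        bad = [data.sample_ids[i] for i in np.flatnonzero(np.abs(slopes) < 1e-12)]
        raise ValueError(f"degenerate spectra (fitted slope ~ 0): {bad}")
    intercepts = X.mean(axis=1) - slopes * reference.mean()
    corrected = (X - intercepts[:, None]) / slopes[:, None]
    return data.with_absorbance(corrected)


def mean_center(
    data: SpectraSet, mean: np.ndarray | None = None
) -> tuple[SpectraSet, np.ndarray]:
    """Subtract a column mean; returns (centered set, mean used).

    When ``mean`` is None the set's own column mean is used (output columns
    then average to zero); pass a stored calibration mean to center new data
    consistently.
    """
    if mean is None:
        mean = data.absorbance.mean(axis=0)
    mean = np.asarray(mean, dtype=float)
    if mean.shape != (data.n_channels,):
        raise ValueError("mean length must equal the channel count")
    return data.with_absorbance(data.absorbance - mean), mean
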