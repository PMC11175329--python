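"""Synthetic carp-like NIR spectra with freeze-thaw effects.

Each spectrum is a sum of Gaussian absorption bands on a 512-channel
900-1700 nm grid plus a linear baseline, all scaled by a per-sample
multiplicative gain (scatter nuisance) with additive white noise. Freeze-thaw
cycles act on the band parameters: the water bands (975, 1210, 1416 nm) lose
intensity with each cycle, the 1416 nm first-overtone band additionally
shifts to a slightly higher wavelength, and the N-H / strongly
hydrogen-bonded water region (1462, 1510 nm) gains intensity. C-H bands
(1164, 1662 nm) are class-invariant controls. Replicates cut from the same
fish piece share a piece-level amplitude effect so grouped splitting can be
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from freezenir.spectra_io import CLASSES, SpectraSet


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band and its per-class modulation."""

    center: float                       # nm
    width_sigma: float                  # nm
    amplitude: float                    # absorbance units
    class_amplitude_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_center_shifts: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")
        if self.amplitude < 0 or min(self.class_amplitude_factors) < 0:
            raise ValueError("amplitudes must be nonnegative")


@dataclass(frozen=True)
class SynthConfig:
    n_per_class: int = 100
    n_channels: int = 512
    wavelength_min: float = 900.0
    wavelength_max: float = 1700.0
    bands: tuple[BandSpec, ...] = ()
    scatter_gain_sd: float = 0.02
    baseline_offset_sd: float = 0.02
    baseline_slope_sd: float = 0.02
    noise_sd: float = 0.0005
    replicate_sd: float = 0.01
    replicates_per_piece: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        for name in (
            "scatter_gain_sd",
            "baseline_offset_sd",
            "baseline_slope_sd",
            "noise_sd",
            "replicate_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def grid(self) -> np.ndarray:
        return np.linspace(self.wavelength_min, self.wavelength_max, self.n_channels)


def default_config(n_per_class: int = 100, seed: int = 0) -> SynthConfig:
    """Study-condition defaults.

    Water bands at 975, 1210 and 1416 nm decay by factors 1.00/0.95/0.91
    across fresh/frozen1/frozen2, the 1416 nm band shifts by 0/+1.5/+2.5 nm,
    the 1462 and 1510 nm bands grow by 1.00/1.04/1.07, and the C-H bands at
    1164 and 1662 nm are class-invariant. Amplitudes, widths and nuisance
    scales are this package's calibration (see docs/methods.md); they are
    sized so that the default three-class scenario is separable but not
    trivially so.
    """
    water = (1.00, 0.95, 0.91)
    nh = (1.00, 1.04, 1.07)
    flat = (1.0, 1.0, 1.0)
    bands = (
        BandSpec(975.0, 18.0, 0.18, water),
        BandSpec(1164.0, 12.0, 0.10, flat),
        BandSpec(1210.0, 16.0, 0.15, water),
        BandSpec(1416.0, 30.0, 0.85, water, (0.0, 1.5, 2.5)),
        BandSpec(1462.0, 30.0, 0.75, nh),
        BandSpec(1510.0, 30.0, 0.45, nh),
        BandSpec(1662.0, 16.0, 0.30, flat),
    )
    return SynthConfig(n_per_class=n_per_class, bands=bands, seed=seed)


def null_config(config: SynthConfig) -> SynthConfig:
    """Negative control: identical class populations (factors 1, shifts 0)."""
    bands = tuple(
        replace(
            b,
            class_amplitude_factors=(1.0, 1.0, 1.0),
            class_center_shifts=(0.0, 0.0, 0.0),
        )
        for b in config.bands
    )
    return replace(config, bands=bands)


def scale_effects(config: SynthConfig, multiplier: float) -> SynthConfig:
    """Scale every class effect (amplitude deltas and shifts) by a multiplier.

    multiplier 0 reproduces :func:`null_config`; 1 is the identity.
    """
    bands = tuple(
        replace(
            b,
            class_amplitude_factors=tuple(
                1.0 + multiplier * (f - 1.0) for f in b.class_amplitude_factors
            ),
            class_center_shifts=tuple(
                multiplier * s for s in b.class_center_shifts
            ),
        )
        for b in config.bands
    )
    return replace(config, bands=bands)


def generate(config: SynthConfig | None = None) -> SpectraSet:
    """Draw a labeled three-class spectra set; deterministic per seed."""
    config = config or default_config()
    if not config.bands:
        raise ValueError("config has no bands")
    rng = np.random.default_rng(config.seed)
    lam = config.grid()
    lam_norm = (lam - lam.mean()) / (lam.max() - lam.min())

    rows = []
    ids: list[str] = []
    labels: list[str] = []
    fish_ids: list[str] = []
    replicates: list[int] = []
    for ci, cls in enumerate(CLASSES):
        n_pieces = int(np.ceil(config.n_per_class / config.replicates_per_piece))
        piece_effects = 1.0 + config.replicate_sd * rng.standard_normal(n_pieces)
        made = 0
        for piece in range(n_pieces):
            for rep in range(config.replicates_per_piece):
                if made >= config.n_per_class:
                    break
                shape = np.zeros_like(lam)
                for b in config.bands:
                    amp = b.amplitude * b.class_amplitude_factors[ci] * piece_effects[piece]
                    center = b.center + b.class_center_shifts[ci]
                    shape += amp * np.exp(-((lam - center) ** 2) / (2 * b.width_sigma**2))
                offset = config.baseline_offset_sd * rng.standard_normal()
                slope = config.baseline_slope_sd * rng.standard_normal()
                gain = 1.0 + config.scatter_gain_sd * rng.standard_normal()
                spectrum = gain * (shape + offset + slope * lam_norm)
                spectrum += config.noise_sd * rng.standard_normal(lam.size)
                rows.append(spectrum)
                ids.append(f"{cls}_p{piece:03d}_r{rep}")
                labels.append(cls)
                fish_ids.append(f"{cls}_piece{piece:03d}")
                replicates.append(rep)
                made += 1
    meta = pd.DataFrame({"fish_id": fish_ids, "replicate": replicates})
    return SpectraSet(
        wavelengths=lam,
        absorbance=np.vstack(rows),
        sample_ids=ids,
        labels=labels,
        meta=meta,
    )
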