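"""Spectral building blocks: spectra, receptor sensitivities and photon catches.

Everything downstream of a photograph or a reflectance measurement reduces to
quantum (photon) catches: the wavelength integral of stimulus reflectance
R(lambda) x illuminant power I(lambda) x receptor sensitivity S(lambda).  This
module fixes the spectral grid used throughout the package — 400 to 700 nm at
1 nm steps, 301 samples — and provides catch integration plus the bundled
standard curves (an LMS cone-sensitivity set, the CIE 1931 XYZ observer and
the D65 illuminant).

Integration is a plain rectangular sum on the 1 nm grid; at this resolution a
trapezoid correction changes catches by well under one part in 10^4 for smooth
spectra, far below every perceptual threshold applied later.  Catches are kept
in arbitrary linear units: receptor-noise distances and cone-catch ratios are
invariant to a common scaling, so no normalization is applied unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "WAVELENGTHS_NM",
    "N_SAMPLES",
    "Spectrum",
    "SensitivitySet",
    "ConeCatch",
    "GridError",
    "SpectrumDomainError",
    "photon_catch",
    "catch_set",
    "load_standard_curves",
]

WAVELENGTHS_NM = np.arange(400, 701, dtype=float)
N_SAMPLES = 301

_REFLECTANCE_TOL = 1e-6


class GridError(ValueError):
    """Spectral data not on the common 400-700 nm, 1 nm grid."""


class SpectrumDomainError(ValueError):
    """Spectral values outside their physical domain (negative, non-finite)."""


def _as_grid_values(values, *, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_SAMPLES,):
        raise GridError(
            f"{what} must have {N_SAMPLES} samples on the 400-700 nm 1 nm grid, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise SpectrumDomainError(f"{what} contains non-finite values")
    if np.any(arr < 0):
        raise SpectrumDomainError(f"{what} contains negative values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A non-negative spectral quantity sampled at 400..700 nm in 1 nm steps.

    Parameters
    ----------
    values
        301 non-negative samples: reflectance in [0, 1] or relative power.
    kind
        "reflectance" enforces values <= 1 (plus a small numerical
        tolerance); "power" places no upper bound.
    """

    values: np.ndarray
    kind: str = "power"

    def __post_init__(self):
        arr = _as_grid_values(self.values, what=f"{self.kind} spectrum")
        if self.kind == "reflectance" and np.any(arr > 1.0 + _REFLECTANCE_TOL):
            raise SpectrumDomainError(
                f"reflectance exceeds 1 (max {arr.max():.6g})"
            )
        object.__setattr__(self, "values", arr)
        self.values.setflags(write=False)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return WAVELENGTHS_NM

    def scaled(self, k: float) -> "Spectrum":
        return Spectrum(self.values * k, kind="power")


@dataclass(frozen=True)
class SensitivitySet:
    """An ordered set of receptor sensitivity curves (>= 3 channels)."""

    channel_names: tuple
    curves: np.ndarray  # (n_channels, 301)

    def __post_init__(self):
        names = tuple(self.channel_names)
        curves = np.asarray(self.curves, dtype=float)
        if curves.ndim != 2 or curves.shape[0] != len(names):
            raise ValueError("one curve per channel required")
        if len(names) < 3:
            raise ValueError("at least 3 channels required")
        for name, c in zip(names, curves):
            _as_grid_values(c, what=f"sensitivity {name!r}")
            if c.max() <= 0:
                raise SpectrumDomainError(f"sensitivity {name!r} is identically zero")
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "curves", curves)
        self.curves.setflags(write=False)

    def __iter__(self):
        for name, c in zip(self.channel_names, self.curves):
            yield name, Spectrum(c)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass(frozen=True)
class ConeCatch:
    """Per-channel quantum catches, strictly positive for lit stimuli."""

    channel_names: tuple
    q: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        self.q.setflags(write=False)

    def __getitem__(self, name: str) -> float:
        return float(self.q[self.channel_names.index(name)])

    def as_array(self) -> np.ndarray:
        return np.array(self.q)


def photon_catch(reflectance: Spectrum, sensitivity: Spectrum,
                 illuminant: Spectrum) -> float:
    """Quantum catch: sum over the 1 nm grid of R(l) * I(l) * S(l).

    Zero only when the pointwise product vanishes everywhere (e.g. zero
    reflectance, or reflectance and sensitivity with disjoint support).
    """
    return float(
        np.sum(reflectance.values * illuminant.values * sensitivity.values)
    )


def catch_set(reflectance: Spectrum, sensitivities: SensitivitySet,
              illuminant: Spectrum, *, normalize: str | None = None) -> ConeCatch:
    """Per-channel photon catches of one stimulus under one illuminant.

    ``normalize=None`` (default) returns raw catches; ``"illuminant"``
    divides each channel by the catch of a perfect (unit) reflector, so a
    white surface scores 1.0 in every channel.  Downstream receptor-noise
    distances and cone-catch ratios are identical either way.
    """
    prod = reflectance.values * illuminant.values
    q = sensitivities.curves @ prod
    if normalize == "illuminant":
        denom = sensitivities.curves @ illuminant.values
        q = q / denom
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")
    return ConeCatch(sensitivities.channel_names, q)


_TABLE_FILES = {
    "stockman_sharpe_lms": ("lms_cone_fundamentals_synthetic.csv", ("LW", "MW", "SW")),
    "cie1931_xyz": ("cie1931_xyz_approx.csv", ("X", "Y", "Z")),
    "d65": ("d65_interpolated.csv", None),
}
_ALIASES = {"lms": "stockman_sharpe_lms", "xyz": "cie1931_xyz"}


def load_standard_curves(which: str):
    """Load a bundled standard table resampled to the common grid.

    ``which`` is one of ``stockman_sharpe_lms`` (alias ``lms``; returns a
    SensitivitySet ordered LW, MW, SW), ``cie1931_xyz`` (alias ``xyz``) or
    ``d65`` (returns a power Spectrum).  The bundled curves are generated
    from closed-form models (see the header comments in the CSV files and
    ``scripts/make_standard_curves.py``); the LMS set is a synthetic
    pigment-nomogram stand-in for measured cone fundamentals.  Loads are
    cached, so repeated calls (and aliases) return the same object.
    """
    key = _ALIASES.get(which, which)
    if key not in _TABLE_FILES:
        raise KeyError(f"unknown standard table {which!r}; "
                       f"choose from {sorted(_TABLE_FILES)}")
    return _load_table(key)


@lru_cache(maxsize=None)
def _load_table(key: str):
    import pandas as pd

    fname, channels = _TABLE_FILES[key]
    ref = resources.files("cyclechrome.data").joinpath(fname)
    with ref.open("r") as fh:
        data = pd.read_csv(fh, comment="#").to_numpy(dtype=float)
    lam = data[:, 0]
    if not np.array_equal(lam, WAVELENGTHS_NM):
        raise GridError(f"bundled table {fname} is not on the standard grid")
    if channels is None:
        return Spectrum(data[:, 1], kind="power")
    return SensitivitySet(channels, data[:, 1:].T)


def read_spectrum_csv(path, kind: str = "reflectance") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV on the standard grid."""
    import pandas as pd

    data = pd.read_csv(path, comment="#").to_numpy(dtype=float)
    if not np.array_equal(data[:, 0], WAVELENGTHS_NM):
        raise GridError(f"{path} is not on the 400-700 nm 1 nm grid")
    return Spectrum(data[:, 1], kind=kind)


def write_spectrum_csv(path, spectrum: Spectrum, value_name: str = "value"):
    with open(path, "w") as fh:
        fh.write(f"wavelength_nm,{value_name}\n")
        for lam, v in zip(WAVELENGTHS_NM, spectrum.values):
            fh.write(f"{lam:.0f},{v:.10g}\n")
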