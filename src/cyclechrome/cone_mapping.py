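"""Polynomial mapping from linearized camera RGB to human cone catches.

A camera's spectral sensitivities differ from human cone fundamentals, so
linearized RGB is not a cone response.  Following the catch-mapping approach
used in calibrated-photography colorimetry, both camera responses and target
responses (LMS cone catches, or CIE XYZ) are computed for a large set of
natural reflectance spectra under a common illuminant, and a polynomial
regression per target channel maps one to the other.  On smooth natural
spectra a degree-2 polynomial in the three camera channels (all cross terms
plus an intercept, 10 terms) routinely reaches R^2 >= 0.999 per channel, the
regime this pipeline requires; the degree is configurable.

Also provides the CIE 1976 L*a*b* transform from XYZ with a D65 2-degree
white point, used for the perceptual-threshold analyses downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .optics import ConeCatch, SensitivitySet, Spectrum, catch_set

__all__ = [
    "MappingModel",
    "LABColor",
    "TrainingError",
    "FittingError",
    "D65_WHITE_XYZ",
    "build_training_pairs",
    "fit_mapping",
    "apply_mapping",
    "xyz_to_lab",
]

log = logging.getLogger(__name__)

#: CIE D65 white point for the 1931 2-degree observer, Y normalized to 100.
D65_WHITE_XYZ = np.array([95.047, 100.0, 108.883])

R2_WARN_THRESHOLD = 0.999


class TrainingError(ValueError):
    """Too few or degenerate training spectra."""


class FittingError(ValueError):
    """Rank-deficient or otherwise unusable regression design."""


def polynomial_terms(degree: int):
    """Monomial exponent triples (i, j, k) with 0 <= i+j+k <= degree.

    Includes the intercept (0,0,0) and all cross terms; degree 2 yields the
    default 10-term basis.
    """
    terms = [
        (i, j, k)
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
        for k in range(degree + 1 - i - j)
    ]
    terms.sort(key=lambda t: (sum(t), t))
    return terms


def _design_matrix(rgb: np.ndarray, terms) -> np.ndarray:
    rgb = np.atleast_2d(np.asarray(rgb, dtype=float))
    cols = [
        rgb[:, 0] ** i * rgb[:, 1] ** j * rgb[:, 2] ** k for (i, j, k) in terms
    ]
    return np.column_stack(cols)


@dataclass(frozen=True)
class LABColor:
    """A CIE 1976 L*a*b* coordinate (L in [0, 100] for in-gamut stimuli)."""

    L: float
    A: float
    B: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.L, self.A, self.B])):
            raise ValueError("LAB components must be finite")
        if self.L < -1e-9:
            raise ValueError(f"L must be non-negative, got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.A, self.B])


@dataclass
class TrainingPairs:
    """Paired camera and target catch triples, one row per spectrum."""

    camera: np.ndarray  # (n, 3)
    target: np.ndarray  # (n, 3)
    camera_names: tuple
    target_names: tuple

    @property
    def n(self) -> int:
        return self.camera.shape[0]


@dataclass
class MappingModel:
    """Per-target-channel polynomial map from camera RGB.

    ``coef`` has one row per target channel over the shared monomial basis
    ``terms``; ``r2`` is the training-set coefficient of determination per
    target; ``floor`` is the small positive value substituted for negative
    predictions (set from the training-target scale).
    """

    terms: list
    coef: np.ndarray  # (n_targets, n_terms)
    r2: np.ndarray  # (n_targets,)
    target_names: tuple
    camera_names: tuple
    floor: np.ndarray  # (n_targets,)
    degree: int

    def to_json(self, path=None) -> str:
        payload = {
            "terms": [list(t) for t in self.terms],
            "coef": self.coef.tolist(),
            "r2": self.r2.tolist(),
            "target_names": list(self.target_names),
            "camera_names": list(self.camera_names),
            "floor": self.floor.tolist(),
            "degree": self.degree,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MappingModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            terms=[tuple(t) for t in payload["terms"]],
            coef=np.array(payload["coef"], dtype=float),
            r2=np.array(payload["r2"], dtype=float),
            target_names=tuple(payload["target_names"]),
            camera_names=tuple(payload["camera_names"]),
            floor=np.array(payload["floor"], dtype=float),
            degree=int(payload["degree"]),
        )


def build_training_pairs(
    spectra,
    camera: SensitivitySet,
    human: SensitivitySet,
    illuminant: Spectrum,
    *,
    min_spectra: int | None = None,
) -> TrainingPairs:
    """Compute paired (camera catch, target catch) rows for a spectrum set.

    Both sides use the same rectangular-sum catch integral under the same
    illuminant.  At least max(40, term count + 1) spectra are required by
    default; spectrum-based training normally uses hundreds.
    """
    spectra = list(spectra)
    if min_spectra is None:
        min_spectra = max(40, len(polynomial_terms(2)) + 1)
    if len(spectra) < min_spectra:
        raise TrainingError(
            f"need at least {min_spectra} training spectra, got {len(spectra)}"
        )
    cam = np.array(
        [catch_set(s, camera, illuminant).q for s in spectra]
    )
    tgt = np.array(
        [catch_set(s, human, illuminant).q for s in spectra]
    )
    return TrainingPairs(cam, tgt, camera.channel_names, human.channel_names)


def fit_mapping(pairs: TrainingPairs, degree: int = 2) -> MappingModel:
    """Least-squares polynomial fit from camera to target catches.

    One regression per target channel on the shared monomial basis.  R^2 is
    reported per target on the training pairs and a warning is logged when
    any falls below 0.999, the calibration regime expected of smooth
    natural-spectrum training sets.
    """
    terms = polynomial_terms(degree)
    if pairs.n < len(terms) + 1:
        raise TrainingError(
            f"need at least {len(terms) + 1} rows for degree {degree}, "
            f"got {pairs.n}"
        )
    X = _design_matrix(pairs.camera, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < len(terms):
        # identify collinear columns via QR pivoting for the error message
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [terms[i] for i in np.where(diag < 1e-9 * diag.max())[0]]
        raise FittingError(
            f"rank-deficient polynomial design (rank {rank} < {len(terms)}); "
            f"near-collinear terms: {bad}"
        )
    coef, *_ = np.linalg.lstsq(X, pairs.target, rcond=None)
    pred = X @ coef
    resid = pairs.target - pred
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum(
        (pairs.target - pairs.target.mean(axis=0)) ** 2, axis=0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    for name, v in zip(pairs.target_names, r2):
        if v < R2_WARN_THRESHOLD:
            log.warning(
                "mapping R^2 for %s is %.6f (< %.3f)", name, v, R2_WARN_THRESHOLD
            )
    floor = 1e-9 * np.abs(pairs.target.mean(axis=0))
    floor = np.where(floor > 0, floor, 1e-12)
    return MappingModel(
        terms=terms,
        coef=coef.T,
        r2=r2,
        target_names=pairs.target_names,
        camera_names=pairs.camera_names,
        floor=floor,
        degree=degree,
    )


def apply_mapping(model: MappingModel, rgb) -> ConeCatch:
    """Evaluate the polynomial map at one RGB triple (or an (n, 3) batch).

    Negative predictions are clamped to a small positive floor (10^-9 of the
    training-target mean) with a logged count: an isolated out-of-gamut
    pixel must not poison log-ratio computations downstream.
    """
    rgb = np.asarray(rgb, dtype=float)
    single = rgb.ndim == 1
    if rgb.shape[-1] != len(model.camera_names):
        raise ValueError(
            f"expected {len(model.camera_names)} camera channels, "
            f"got shape {rgb.shape}"
        )
    if not np.all(np.isfinite(rgb)):
        raise ValueError("camera RGB must be finite")
    X = _design_matrix(rgb, model.terms)
    out = X @ model.coef.T
    n_clamped = int(np.sum(out <= 0))
    if n_clamped:
        log.warning("clamped %d non-positive predicted catches to floor", n_clamped)
        out = np.maximum(out, model.floor)
    if single:
        return ConeCatch(model.target_names, out[0])
    return [ConeCatch(model.target_names, row) for row in out]


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(
        t > delta**3, np.cbrt(t), t / (3.0 * delta**2) + 4.0 / 29.0
    )


def xyz_to_lab(xyz, white=D65_WHITE_XYZ) -> LABColor:
    """CIE 1976 L*a*b* from tristimulus XYZ with an explicit white point.

    Uses the standard two-branch (cube root / linear) transfer function.
    ``xyz`` and ``white`` must share units; the default white is D65 for
    the 2-degree observer.
    """
    xyz = np.asarray(xyz, dtype=float)
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white point must be strictly positive")
    fx, fy, fz = _lab_f(xyz / white)
    L = 116.0 * fy - 16.0
    return LABColor(float(L), float(500.0 * (fx - fy)), float(200.0 * (fy - fz)))
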