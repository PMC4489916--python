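"""Camera linearization, grey-card standardization and cheek-patch extraction.

Consumer cameras respond nonlinearly to scene radiance, so raw pixel values
must first be linearized with a model fitted to photographs of calibrated
grey reflectance standards (nominally eight, spanning 2%-99% reflectance).
The per-channel response model is a monotone power law with offset,
``response = a * reflectance**b + c``, which nests both a purely linear
response (b = 1) and gamma encoding (b ~ 1/2.2); its inverse maps raw pixel
values to reflectance-proportional linear values.  A calibration fit with
R^2 below 0.999 on the standards is flagged, since that is the quality
routinely achieved by this procedure.

Linearized images are then standardized against an in-frame 18% grey card —
each channel rescaled so the card region averages exactly 0.18 — which
removes shot-to-shot lighting variation.  Finally two cheek patches are
located from the pupil coordinates in units of the interpupillary distance
(IPD): each patch is 30% of IPD wide and 26% tall, its top edge 30% of IPD
below the mean pupil height, and its inner (nose-side) edge on the vertical
line through its pupil, extending laterally outward.  Patch means are
averaged patch-wise (mean of the two patch means), giving one RGB triple
per photograph.

Pixel convention: 0-based indices, origin top-left, x rightward, y downward;
patch rectangles are half-open on both axes.  Patch dimensions are rounded
half-away-from-zero to whole pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PatchSpec",
    "LinearizationModel",
    "CalibrationError",
    "GeometryError",
    "StandardizationError",
    "fit_linearization",
    "linearize_image",
    "standardize_to_grey",
    "cheek_patches",
    "mean_patch_rgb",
    "read_tiff",
    "write_tiff",
]

log = logging.getLogger(__name__)

R2_FLAG_THRESHOLD = 0.999


class CalibrationError(ValueError):
    """Degenerate or non-monotone calibration data."""


class GeometryError(ValueError):
    """Patch geometry invalid or outside the image."""


class StandardizationError(ValueError):
    """Grey-card region unusable for standardization."""


def _round_half_away(x) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class PatchSpec:
    """A half-open pixel rectangle [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise GeometryError(f"patch must be at least 1x1, got {self}")

    def validate_inside(self, image: np.ndarray, name: str = "patch"):
        h, w = image.shape[:2]
        if self.x0 < 0 or self.y0 < 0 or self.x0 + self.width > w \
                or self.y0 + self.height > h:
            raise GeometryError(
                f"{name} {self} exits image bounds {w}x{h}"
            )

    @property
    def slices(self):
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("empty image")
    return image


@dataclass
class LinearizationModel:
    """Per-channel inverse of a monotone power-law-with-offset response.

    Forward model per channel: response = a * reflectance**b + c with
    a > 0, b > 0.  ``invert`` maps raw responses back to linear
    reflectance-proportional values; out-of-domain responses are clipped to
    the calibrated range with a logged count.  ``r2`` is the goodness of
    fit on the calibration standards.
    """

    params: np.ndarray  # (3, 3) rows (a, b, c) per channel
    r2: np.ndarray  # (3,)
    response_range: np.ndarray  # (3, 2) calibrated raw-response span

    def invert(self, responses: np.ndarray, channel: int) -> np.ndarray:
        a, b, c = self.params[channel]
        lo, hi = self.response_range[channel]
        x = np.asarray(responses, dtype=float)
        clipped = np.clip(x, min(c, lo), hi)
        n_out = int(np.sum((x < min(c, lo)) | (x > hi)))
        if n_out:
            log.warning(
                "channel %d: clipped %d out-of-domain pixel values", channel, n_out
            )
        return np.power(np.maximum(clipped - c, 0.0) / a, 1.0 / b)


def fit_linearization(responses, reflectances) -> LinearizationModel:
    """Fit the per-channel response inversion from grey-standard photographs.

    ``responses`` is an (n_standards, 3) array of mean raw pixel values and
    ``reflectances`` the n known standard reflectances (fractions).  At
    least four distinct standards are required and responses must be
    strictly monotone in reflectance per channel.
    """
    responses = np.asarray(responses, dtype=float)
    reflectances = np.asarray(reflectances, dtype=float)
    if responses.ndim != 2 or responses.shape[1] != 3:
        raise CalibrationError(
            f"responses must be (n, 3), got shape {responses.shape}"
        )
    n = responses.shape[0]
    if reflectances.shape != (n,):
        raise CalibrationError("one reflectance per standard required")
    if len(np.unique(reflectances)) != n:
        raise CalibrationError("duplicate standard reflectances")
    if n < 4:
        raise CalibrationError(f"need at least 4 standards, got {n}")
    order = np.argsort(reflectances)
    refl = reflectances[order]
    resp = responses[order]

    def forward(r, a, b, c):
        return a * np.power(r, b) + c

    params = np.zeros((3, 3))
    r2 = np.zeros(3)
    rng_span = np.zeros((3, 2))
    for ch in range(3):
        y = resp[:, ch]
        d = np.diff(y)
        if np.all(d == 0):
            raise CalibrationError(f"channel {ch}: responses constant across standards")
        if np.any(d <= 0):
            raise CalibrationError(
                f"channel {ch}: responses not strictly increasing in reflectance"
            )
        span = y[-1] - y[0]
        p0 = (span, 1.0 / 2.2, y[0])
        bounds = ([1e-12, 0.05, -np.inf], [np.inf, 20.0, np.inf])
        popt, _ = curve_fit(forward, refl, y, p0=p0, bounds=bounds, maxfev=20000)
        pred = forward(refl, *popt)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        params[ch] = popt
        r2[ch] = 1.0 - ss_res / ss_tot
        rng_span[ch] = (y[0], y[-1])
        if r2[ch] < R2_FLAG_THRESHOLD:
            log.warning(
                "channel %d linearization R^2 = %.6f (< %.3f)",
                ch, r2[ch], R2_FLAG_THRESHOLD,
            )
    return LinearizationModel(params, r2, rng_span)


def linearize_image(image: np.ndarray, model: LinearizationModel) -> np.ndarray:
    """Apply the fitted response inversion per pixel and channel (float out)."""
    image = _check_image(image)
    out = np.empty(image.shape, dtype=float)
    for ch in range(3):
        out[..., ch] = model.invert(image[..., ch], ch)
    return out


def standardize_to_grey(
    image: np.ndarray, grey_region: PatchSpec, grey_reflectance: float = 0.18
) -> np.ndarray:
    """Rescale each channel so the grey-card region averages the card value.

    Expects an already-linearized image.  Idempotent: standardizing twice
    equals standardizing once.
    """
    image = _check_image(image).astype(float)
    grey_region.validate_inside(image, "grey region")
    region = image[grey_region.slices]
    means = region.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise StandardizationError(
            f"grey-region channel means must be positive, got {means}"
        )
    return image * (grey_reflectance / means)


def cheek_patches(pupil_left, pupil_right, image: np.ndarray):
    """Locate the two cheek patches from pupil coordinates.

    ``pupil_left`` is the pupil with the smaller x (viewer's left).  Returns
    (left PatchSpec, right PatchSpec); raises GeometryError, naming the
    offending patch, if either exits the image.
    """
    image = _check_image(image)
    (lx, ly), (rx, ry) = pupil_left, pupil_right
    if lx > rx:
        (lx, ly), (rx, ry) = (rx, ry), (lx, ly)
    ipd = float(np.hypot(rx - lx, ry - ly))
    if ipd <= 0:
        raise GeometryError("interpupillary distance is zero")
    h, w = image.shape[:2]
    for name, (px, py) in (("left pupil", (lx, ly)), ("right pupil", (rx, ry))):
        if not (0 <= px < w and 0 <= py < h):
            raise GeometryError(f"{name} ({px}, {py}) outside image {w}x{h}")
    width = _round_half_away(0.30 * ipd)
    height = _round_half_away(0.26 * ipd)
    top = _round_half_away((ly + ry) / 2.0 + 0.30 * ipd)
    left_inner = _round_half_away(lx)
    right_inner = _round_half_away(rx)
    left = PatchSpec(left_inner - width, top, width, height)
    right = PatchSpec(right_inner, top, width, height)
    left.validate_inside(image, "left cheek patch")
    right.validate_inside(image, "right cheek patch")
    return left, right


def mean_patch_rgb(image: np.ndarray, left: PatchSpec, right: PatchSpec) -> np.ndarray:
    """Average of the two patch means (patch-wise, not pixel-pooled)."""
    image = _check_image(image)
    left.validate_inside(image, "left patch")
    right.validate_inside(image, "right patch")
    lm = image[left.slices].reshape(-1, 3).mean(axis=0)
    rm = image[right.slices].reshape(-1, 3).mean(axis=0)
    return (lm + rm) / 2.0


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_tiff(path, image: np.ndarray):
    import tifffile

    tifffile.imwrite(path, image)
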