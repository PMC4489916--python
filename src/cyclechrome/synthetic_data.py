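"""Synthetic inputs for every pipeline stage, with known ground truth.

The study this package is built around photographed 22 naturally-cycling
women roughly daily (weekdays only, mean ~13 photographs each) for at least
one full cycle, calibrated the camera against grey reflectance standards,
and mapped cheek-patch color to human cone catches.  None of those raw
materials can be redistributed, so this module generates statistically
comparable stand-ins:

* smooth random reflectance spectra (for training the camera-to-cone map),
* a trichromatic camera with Gaussian-band sensitivities and a power-law
  (gamma-like) intensity response,
* face-like calibration images with a known skin color, pupil coordinates
  and an in-frame 18% grey card,
* multi-participant daily cone-catch series with known Fourier
  coefficients, nested random intercepts and Gaussian noise,
* a clearly-synthetic placeholder conception-risk table.

Every generator is a pure function of its seed and parameters, so reruns
are bit-identical.  Defaults mirror the source study's design: 22
participants, ~13 photos each on weekdays, cycle lengths 26-34 days with
the LH surge 14 days before the cycle's final day (plus or minus a day),
and a sub-threshold redness modulation (maximum receptor-noise distance
below 1 JND, LAB redness amplitude well below 2.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cycle_time, image_pipeline
from .cycle_time import CycleSpec, RiskTable
from .image_pipeline import PatchSpec
from .optics import WAVELENGTHS_NM, SensitivitySet, Spectrum

__all__ = [
    "StudyDesign",
    "CameraModel",
    "gen_spectra",
    "gen_camera",
    "gen_face_image",
    "gen_study",
    "placeholder_risk_table",
]


def gen_spectra(n: int, seed: int, *, skin_bias: bool = False) -> list:
    """Smooth random reflectance spectra in [0, 1] on the standard grid.

    Each spectrum is a logistic squash of a random low-order function (a
    constant plus 2-4 broad Gaussians plus an optional sigmoid edge), which
    guarantees smoothness and the [0, 1] range.  ``skin_bias=True`` adds a
    rising long-wavelength edge near 580 nm, the signature shape of
    blood-perfused skin, keeping downstream color differences in the
    realistic sub-threshold regime.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lam = WAVELENGTHS_NM
    out = []
    for _ in range(n):
        z = rng.uniform(-1.5, 1.0) * np.ones_like(lam)
        for _k in range(rng.integers(2, 4)):
            amp = rng.uniform(-2.0, 2.0)
            mu = rng.uniform(380.0, 720.0)
            sig = rng.uniform(80.0, 200.0)
            z = z + amp * np.exp(-0.5 * ((lam - mu) / sig) ** 2)
        if rng.random() < 0.5 or skin_bias:
            edge = rng.uniform(520.0, 640.0) if not skin_bias else rng.uniform(570.0, 600.0)
            steep = rng.uniform(0.008, 0.03)
            z = z + rng.uniform(0.5, 2.0) * np.tanh(steep * (lam - edge))
        refl = 0.02 + 0.93 / (1.0 + np.exp(-z))
        out.append(Spectrum(refl, kind="reflectance"))
    return out


@dataclass(frozen=True)
class CameraModel:
    """A simulated trichromatic camera.

    ``sensitivities`` are Gaussian bands (R, G, B); the intensity response
    is ``response = full_scale * linear**exponent`` with exponent near
    1/2.2, applied to reflectance-proportional linear values in [0, 1].
    """

    sensitivities: SensitivitySet
    exponent: float
    full_scale: float = 65535.0

    def encode(self, linear: np.ndarray) -> np.ndarray:
        """Nonlinear camera response to linear values in [0, 1]."""
        lin = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
        return self.full_scale * np.power(lin, self.exponent)


def gen_camera(seed: int) -> CameraModel:
    """A random plausible camera: RGB Gaussian bands plus a gamma response."""
    rng = np.random.default_rng(seed)
    centers = rng.normal([605.0, 535.0, 465.0], 5.0)
    widths = rng.uniform(35.0, 55.0, size=3)
    peaks = rng.uniform(0.7, 1.0, size=3)
    lam = WAVELENGTHS_NM
    curves = np.array(
        [p * np.exp(-0.5 * ((lam - c) / w) ** 2)
         for p, c, w in zip(peaks, centers, widths)]
    )
    exponent = float(np.clip(rng.normal(1.0 / 2.2, 0.03), 0.3, 0.7))
    return CameraModel(SensitivitySet(("R", "G", "B"), curves), exponent)


def gen_face_image(
    skin_rgb,
    pupils,
    grey_region: PatchSpec,
    size=(256, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
    camera: CameraModel | None = None,
):
    """A face-like calibration image with known geometry, as 16-bit pixels.

    The image is a uniform skin field (linear reflectance-proportional RGB
    ``skin_rgb``) with optional Gaussian pixel noise, an 18%-grey rectangle
    and dark pupil markers, passed through the camera's nonlinear response.
    Returns ``(image_uint16, sidecar)`` where the sidecar dict carries the
    pupil and grey-card coordinates in the CSV-sidecar convention.
    """
    if camera is None:
        camera = gen_camera(seed)
    w, h = size
    skin = np.asarray(skin_rgb, dtype=float)
    if np.any(skin < 0) or np.any(skin > 1):
        raise ValueError("skin_rgb must be linear values in [0, 1]")
    rng = np.random.default_rng(seed)
    linear = np.broadcast_to(skin, (h, w, 3)).copy()
    if noise_sd > 0:
        linear += rng.normal(0.0, noise_sd, size=linear.shape)
        linear = np.clip(linear, 0.0, 1.0)
    probe = PatchSpec(grey_region.x0, grey_region.y0,
                      grey_region.width, grey_region.height)
    probe.validate_inside(linear, "grey region")
    linear[probe.slices] = 0.18
    (lx, ly), (rx, ry) = pupils
    for px, py in ((lx, ly), (rx, ry)):
        x0, y0 = int(round(px)), int(round(py))
        if not (0 <= x0 < w and 0 <= y0 < h):
            raise image_pipeline.GeometryError(
                f"pupil ({px}, {py}) outside image {w}x{h}"
            )
        linear[max(y0 - 1, 0):y0 + 2, max(x0 - 1, 0):x0 + 2] = 0.01
    encoded = np.round(camera.encode(linear)).astype(np.uint16)
    sidecar = {
        "pupil_lx": lx, "pupil_ly": ly, "pupil_rx": rx, "pupil_ry": ry,
        "grey_x0": grey_region.x0, "grey_y0": grey_region.y0,
        "grey_w": grey_region.width, "grey_h": grey_region.height,
    }
    return encoded, sidecar


def simulate_grey_standards(camera: CameraModel, reflectances=None) -> tuple:
    """Mean responses of the calibrated grey standards under this camera.

    Default reflectances span 99% down to 2%, the usual eight-standard
    Spectralon ladder.  Returns (responses (n, 3), reflectances (n,)).
    """
    if reflectances is None:
        reflectances = np.array([0.99, 0.80, 0.60, 0.40, 0.20, 0.10, 0.05, 0.02])
    reflectances = np.asarray(reflectances, dtype=float)
    resp = camera.encode(reflectances[:, None] * np.ones(3))
    return resp, reflectances


_DEFAULT_REDNESS_COEF = (-0.007, 0.009, 0.004, -0.002)
_DEFAULT_LUMINANCE_COEF = (0.10, -0.05, 0.0, 0.0)


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of a simulated daily-photography cycle study.

    Defaults emulate the source study's conditions: 22 participants, one
    cycle each of 26-34 days, the LH surge 14 days before the final cycle
    day (jittered by up to a day), weekday-only photography averaging ~13
    usable photos, and a redness (LW/MW catch ratio) modulation whose
    amplitude sits below both perceptibility thresholds.  Coefficients are
    in basis order (sin1, cos1, sin2, cos2).
    """

    n_participants: int = 22
    cycles_per_participant: int = 1
    cycle_length_range: tuple = (26, 34)
    lh_jitter: int = 1
    photos_per_participant: int = 13
    photos_jitter: int = 4
    redness_intercept: float = 1.85
    redness_coef: tuple = _DEFAULT_REDNESS_COEF
    redness_participant_sd: float = 0.06
    redness_cycle_sd: float = 0.02
    redness_resid_sd: float = 0.03
    luminance_intercept: float = 65.0
    luminance_coef: tuple = _DEFAULT_LUMINANCE_COEF
    luminance_participant_sd: float = 3.0
    luminance_cycle_sd: float = 1.0
    luminance_resid_sd: float = 1.2
    lab_a_intercept: float = 14.0
    lab_b_intercept: float = 16.0
    seed: int = 0


def _weekday_days(length: int, n_photos: int, rng) -> np.ndarray:
    """Raw days 1..length available on weekdays, thinned to n_photos."""
    offset = int(rng.integers(0, 7))
    avail = np.array(
        [d for d in range(1, length + 1) if (d + offset) % 7 not in (0, 6)]
    )
    n = min(n_photos, len(avail))
    chosen = np.sort(rng.choice(avail, size=n, replace=False))
    return chosen


def gen_study(design: StudyDesign):
    """Simulate an observation table plus its full ground truth.

    Returns ``(observations, truth)``.  The observation table has one row
    per photograph with participant/cycle IDs, raw and adjusted day, the
    redness outcome, back-constructed cone catches (LW/MW reproduces the
    redness outcome exactly), a luminance outcome and LAB coordinates (A is
    a deterministic log-redness map scaled so its cyclic amplitude is
    sub-threshold, matching the regime of real cheek-patch data).  ``truth``
    records every coefficient, variance and random effect drawn.
    """
    d = design
    if d.n_participants < 2 or d.photos_per_participant < 1:
        raise ValueError("infeasible design: need >= 2 participants, >= 1 photo")
    lo, hi = d.cycle_length_range
    if not (2 <= lo <= hi):
        raise ValueError(f"infeasible cycle length range {d.cycle_length_range}")
    rng = np.random.default_rng(d.seed)
    rows = []
    truth_effects = []
    beta_r = np.asarray(d.redness_coef, dtype=float)
    beta_l = np.asarray(d.luminance_coef, dtype=float)
    orders = len(beta_r) // 2
    from .cyclic_stats import fourier_basis

    for p in range(1, d.n_participants + 1):
        u_r = rng.normal(0.0, d.redness_participant_sd)
        u_l = rng.normal(0.0, d.luminance_participant_sd)
        mw_base = rng.normal(1.0, 0.03)
        for c in range(1, d.cycles_per_participant + 1):
            length = int(rng.integers(lo, hi + 1))
            lh = length - 14 + int(rng.integers(-d.lh_jitter, d.lh_jitter + 1))
            lh = int(np.clip(lh, 2, length - 1))
            spec = CycleSpec(lh_day=lh, length=length)
            v_r = rng.normal(0.0, d.redness_cycle_sd)
            v_l = rng.normal(0.0, d.luminance_cycle_sd)
            n_photos = max(
                1, d.photos_per_participant
                + int(rng.integers(-d.photos_jitter, d.photos_jitter + 1))
            )
            days = _weekday_days(length, n_photos, rng)
            adj = np.array([cycle_time.adjust_day(int(dd), spec) for dd in days])
            X = fourier_basis(adj, orders)
            redness = (
                d.redness_intercept + X @ beta_r + u_r + v_r
                + rng.normal(0.0, d.redness_resid_sd, size=len(days))
            )
            luminance = (
                d.luminance_intercept + X @ beta_l + u_l + v_l
                + rng.normal(0.0, d.luminance_resid_sd, size=len(days))
            )
            # catches must stay positive even if an extreme outcome draw is
            # not; the floor only affects the color columns, not the outcome
            r_pos = np.maximum(redness, 0.05 * abs(d.redness_intercept))
            mw = np.full(len(days), mw_base)
            lw = r_pos * mw
            sw = 0.95 * mw
            lab_a = d.lab_a_intercept + 60.0 * np.log(
                r_pos / d.redness_intercept
            )
            lab_b = (
                d.lab_b_intercept + 0.2 * u_l
                + rng.normal(0.0, 0.3, size=len(days))
            )
            for i, dd in enumerate(days):
                rows.append(
                    {
                        "participant_id": f"P{p:02d}",
                        "cycle_id": f"P{p:02d}C{c}",
                        "day": int(dd),
                        "adjusted_day": adj[i],
                        "cycle_length": length,
                        "lh_day": lh,
                        "redness": redness[i],
                        "LW": lw[i],
                        "MW": mw[i],
                        "SW": sw[i],
                        "lab_l": luminance[i],
                        "lab_a": lab_a[i],
                        "lab_b": lab_b[i],
                    }
                )
            truth_effects.append(
                {
                    "participant_id": f"P{p:02d}",
                    "cycle_id": f"P{p:02d}C{c}",
                    "u_redness": u_r,
                    "v_redness": v_r,
                    "u_luminance": u_l,
                    "v_luminance": v_l,
                    "cycle_length": length,
                    "lh_day": lh,
                }
            )
    observations = pd.DataFrame(rows)
    truth = {
        "seed": d.seed,
        "orders": orders,
        "redness": {
            "intercept": d.redness_intercept,
            "coef": list(beta_r),
            "participant_sd": d.redness_participant_sd,
            "cycle_sd": d.redness_cycle_sd,
            "resid_sd": d.redness_resid_sd,
            "effect_size": float(np.sqrt(np.sum(beta_r**2) / 2.0)),
        },
        "luminance": {
            "intercept": d.luminance_intercept,
            "coef": list(beta_l),
            "participant_sd": d.luminance_participant_sd,
            "cycle_sd": d.luminance_cycle_sd,
            "resid_sd": d.luminance_resid_sd,
            "effect_size": float(np.sqrt(np.sum(beta_l**2) / 2.0)),
        },
        "effects": truth_effects,
    }
    return observations, truth


def placeholder_risk_table() -> RiskTable:
    """A smooth synthetic conception-risk table over adjusted days 1..28.

    NOT actuarial data — a unimodal curve peaking in the late-follicular
    days (around adjusted day 12-13), supplied only so that risk-adjusted
    models can be exercised in tests and demonstrations.  Substitute a real
    actuarial table for scientific use.
    """
    days = np.arange(1, 29)
    risk = 0.33 * np.exp(-0.5 * ((days - 12.5) / 2.8) ** 2) + 0.003
    return RiskTable(dict(zip(days.tolist(), risk.tolist())))
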