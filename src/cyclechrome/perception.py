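"""Perceptibility of color differences: receptor-noise JNDs and LAB contrasts.

Two independent models of human discriminability are applied to each pair of
skin colors:

* The Vorobyev-Osorio receptor-noise model.  Receptor signals are log
  quantum catches (the bright-light regime), channel noise is a Weber
  fraction omega_i, and the chromatic distance for a trichromat is

      dS = sqrt( (wS^2 (dfL-dfM)^2 + wM^2 (dfL-dfS)^2 + wL^2 (dfM-dfS)^2)
                 / ((wL wM)^2 + (wL wS)^2 + (wM wS)^2) ),

  with df_i = ln(q_i^a / q_i^b).  dS >= 1 marks a discriminable difference
  under optimal viewing.
* CIELAB axis differences and the Euclidean distance Delta-E, with a
  difference exceeding 2.2 on any single axis taken as noticeable under
  optimal lighting.

Weber fractions may be supplied directly (``weber_direct``, the default —
printed triplets are used verbatim) or derived from relative cone abundances
(``abundance_scaled``): omega_i = omega_ref * sqrt(abundance_ref /
abundance_i) with the most abundant channel as reference, which is how the
receptor-noise framework propagates cone-ratio assumptions.  Channel order
for Weber and abundance triplets is SW:MW:LW, following the convention in
which these triplets are usually printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cone_mapping import LABColor
from .optics import ConeCatch

__all__ = [
    "NoiseModel",
    "LabContrast",
    "ContrastSeries",
    "LAB_THRESHOLD",
    "JND_THRESHOLD",
    "STANDARD_CONE_RATIOS",
    "CONE_RATIO_VARIANTS",
    "jnd",
    "lab_contrast",
    "perceptible_lab",
    "perceptible_jnd",
    "contrast_series",
]

#: A single-axis LAB difference above this is noticeable under optimal light.
LAB_THRESHOLD = 2.2
#: A receptor-noise distance at or above this is discriminable.
JND_THRESHOLD = 1.0

#: Relative cone proportions SW:MW:LW — standard plus the reported human
#: minimum and maximum MW variants.
STANDARD_CONE_RATIOS = (1.0, 0.5, 0.03125)
CONE_RATIO_VARIANTS = {
    "standard": STANDARD_CONE_RATIOS,
    "min": (1.0, 1.0, 0.03125),
    "max": (1.0, 0.06, 0.03125),
}


@dataclass(frozen=True)
class NoiseModel:
    """Receptor-noise parameters; triplets ordered SW:MW:LW.

    mode ``weber_direct`` uses ``weber`` verbatim as the channel noise
    omega; ``abundance_scaled`` derives omega from ``abundance`` by
    square-root scaling off the most abundant channel's Weber fraction.
    """

    weber: tuple = (0.08, 0.02, 0.02)
    abundance: tuple = STANDARD_CONE_RATIOS
    mode: str = "weber_direct"

    def __post_init__(self):
        for name in ("weber", "abundance"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != 3 or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be 3 positive values, got {vals}")
            object.__setattr__(self, name, vals)
        if self.mode not in ("weber_direct", "abundance_scaled"):
            raise ValueError(f"unknown noise mode {self.mode!r}")

    def omegas_swm(self) -> np.ndarray:
        """Effective channel noise (omega_SW, omega_MW, omega_LW)."""
        w = np.array(self.weber)
        if self.mode == "weber_direct":
            return w
        ab = np.array(self.abundance)
        ref = int(np.argmax(ab))
        return w[ref] * np.sqrt(ab[ref] / ab)


def _lms_from_catch(c: ConeCatch) -> np.ndarray:
    names = c.channel_names
    try:
        return np.array([c["LW"], c["MW"], c["SW"]])
    except ValueError:
        if len(names) == 3:  # positional fallback: assume long-to-short order
            return c.as_array()
        raise


def jnd(a: ConeCatch, b: ConeCatch, noise: NoiseModel) -> float:
    """Vorobyev-Osorio chromatic distance between two catch triples.

    Symmetric, zero iff the catches agree up to per-channel common scaling,
    and invariant to illuminant intensity (signals are log ratios).
    """
    qa, qb = _lms_from_catch(a), _lms_from_catch(b)
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("quantum catches must be strictly positive for JNDs")
    df_l, df_m, df_s = np.log(qa / qb)
    w_s, w_m, w_l = noise.omegas_swm()
    num = (
        w_s**2 * (df_l - df_m) ** 2
        + w_m**2 * (df_l - df_s) ** 2
        + w_l**2 * (df_m - df_s) ** 2
    )
    den = (w_l * w_m) ** 2 + (w_l * w_s) ** 2 + (w_m * w_s) ** 2
    return float(np.sqrt(num / den))


class LabContrast(NamedTuple):
    L_diff: float
    A_diff: float
    B_diff: float
    delta_e: float


def lab_contrast(reference: LABColor, sample: LABColor) -> LabContrast:
    """Axis differences and Delta-E, signed as reference minus sample.

    The reference is the day-14 color in cycle analyses, so a positive
    A_diff means the reference day was redder than the sample day.
    """
    d = reference.as_array() - sample.as_array()
    return LabContrast(float(d[0]), float(d[1]), float(d[2]),
                       float(np.sqrt(np.sum(d**2))))


def perceptible_lab(delta: float) -> bool:
    """True iff a single LAB-axis difference exceeds 2.2 in magnitude."""
    return abs(delta) > LAB_THRESHOLD


def perceptible_jnd(ds: float) -> bool:
    """True iff a receptor-noise distance reaches 1 JND."""
    if ds < 0:
        raise ValueError(f"JND distances are non-negative, got {ds}")
    return ds >= JND_THRESHOLD


@dataclass
class ContrastSeries:
    """Per-day contrasts of a color series against a reference cycle day."""

    table: pd.DataFrame  # columns: day, jnd, L_diff, A_diff, B_diff, delta_e
    reference_day: float
    noise: NoiseModel

    @property
    def maxima(self) -> dict:
        return {
            "jnd": float(self.table["jnd"].max()),
            "abs_L_diff": float(self.table["L_diff"].abs().max()),
            "abs_A_diff": float(self.table["A_diff"].abs().max()),
            "abs_B_diff": float(self.table["B_diff"].abs().max()),
            "delta_e": float(self.table["delta_e"].max()),
        }

    @property
    def verdict(self) -> dict:
        m = self.maxima
        return {
            "jnd_perceptible": perceptible_jnd(m["jnd"]),
            "redness_perceptible": perceptible_lab(m["abs_A_diff"]),
            "delta_e_perceptible": m["delta_e"] > LAB_THRESHOLD,
        }


def _interp_reference(days, values, reference_day):
    order = np.argsort(days)
    return np.array(
        [np.interp(reference_day, days[order], np.asarray(v)[order])
         for v in values.T]
    )


def contrast_series(
    observations: Sequence[tuple],
    reference_day: float = 14.0,
    noise: NoiseModel | None = None,
    *,
    reference: tuple | None = None,
) -> ContrastSeries:
    """Contrasts of every observed day against the reference (day-14) color.

    ``observations`` are (adjusted_day, ConeCatch, LABColor) tuples.  The
    reference color pair may be passed explicitly (e.g. evaluated from a
    fitted cycle curve); otherwise an exact day match is used when present,
    falling back to linear interpolation of catches and LAB values over
    adjusted day.
    """
    if noise is None:
        noise = NoiseModel()
    obs = list(observations)
    if not obs:
        raise ValueError("empty observation series")
    days = np.array([float(d) for d, _, _ in obs])
    catches = np.array([_lms_from_catch(c) for _, c, _ in obs])
    labs = np.array([lab.as_array() for _, _, lab in obs])

    if reference is not None:
        ref_catch, ref_lab = reference
        ref_q = _lms_from_catch(ref_catch)
        ref_lab_arr = ref_lab.as_array()
    else:
        exact = np.where(np.isclose(days, reference_day))[0]
        if exact.size:
            i = int(exact[0])
            ref_q, ref_lab_arr = catches[i], labs[i]
        else:
            ref_q = _interp_reference(days, catches, reference_day)
            ref_lab_arr = _interp_reference(days, labs, reference_day)

    ref_catch_obj = ConeCatch(("LW", "MW", "SW"), ref_q)
    ref_lab_obj = LABColor(*ref_lab_arr)
    rows = []
    for day, q, lab in zip(days, catches, labs):
        ds = jnd(ConeCatch(("LW", "MW", "SW"), q), ref_catch_obj, noise)
        lc = lab_contrast(ref_lab_obj, LABColor(*lab))
        rows.append((day, ds, lc.L_diff, lc.A_diff, lc.B_diff, lc.delta_e))
    table = pd.DataFrame(
        rows, columns=["day", "jnd", "L_diff", "A_diff", "B_diff", "delta_e"]
    )
    return ContrastSeries(table, reference_day, noise)
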