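"""Regenerate the bundled spectral tables under src/cyclechrome/data/.

All three tables live on the common 400-700 nm, 1 nm grid (301 samples) and
are produced from closed-form models rather than copied tabulations:

* ``cie1931_xyz_approx.csv`` — the CIE 1931 2-degree color matching
  functions via the multi-lobe piecewise-Gaussian fit of Wyman, Sloan &
  Shirley (2013), accurate to about 1% of peak; tiny negative lobes of the
  fit are clamped at zero.
* ``lms_cone_fundamentals_synthetic.csv`` — synthetic stand-ins for the
  human L/M/S cone fundamentals, built from the Govardovskii et al. (2000)
  A1 visual-pigment nomogram at corneal peak wavelengths 566, 541 and
  441 nm.  These reproduce the peak positions and bandwidths of the
  measured fundamentals but omit pre-receptoral filtering detail.
* ``d65_interpolated.csv`` — the CIE D65 daylight illuminant, PCHIP
  interpolation of the standard 10 nm relative-power tabulation
  (normalized to 100 at 560 nm).

Run from the repository root:  python scripts/make_standard_curves.py
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

GRID = np.arange(400, 701, dtype=float)
OUT = Path(__file__).resolve().parents[1] / "src" / "cyclechrome" / "data"


def _lobe(lam, alpha, mu, sigma_lo, sigma_hi):
    sigma = np.where(lam < mu, sigma_lo, sigma_hi)
    return alpha * np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def cie1931_xyz(lam):
    x = (
        _lobe(lam, 1.056, 599.8, 37.9, 31.0)
        + _lobe(lam, 0.362, 442.0, 16.0, 26.7)
        + _lobe(lam, -0.065, 501.1, 20.4, 26.2)
    )
    y = _lobe(lam, 0.821, 568.8, 46.9, 40.5) + _lobe(lam, 0.286, 530.9, 16.3, 31.1)
    z = _lobe(lam, 1.217, 437.0, 11.8, 36.0) + _lobe(lam, 0.681, 459.0, 26.0, 13.8)
    return np.clip(np.column_stack([x, y, z]), 0.0, None)


def govardovskii_a1(lam, lam_max):
    """A1 visual-pigment absorbance template (alpha + beta band)."""
    x = lam_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lam_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lam_max
    b = -40.5 + 0.195 * lam_max
    beta = 0.26 * np.exp(-(((lam - lam_beta) / b) ** 2))
    s = alpha + beta
    return s / s.max()


# Standard CIE D65 relative spectral power, 10 nm steps, 400-700 nm.
D65_10NM = np.array(
    [
        82.7549, 91.486, 93.4318, 86.6823, 104.865, 117.008, 117.812, 114.861,
        115.923, 108.811, 109.354, 107.802, 104.790, 107.689, 104.405, 104.046,
        100.000, 96.3342, 95.788, 88.6856, 90.0062, 89.5991, 87.6987, 83.2886,
        83.6992, 80.0268, 80.1207, 82.2778, 78.2842, 69.7213, 71.6091,
    ]
)


def d65(lam):
    knots = np.arange(400, 701, 10, dtype=float)
    return PchipInterpolator(knots, D65_10NM)(lam)


def write_csv(path, header_comment, columns, data):
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        fh.write(",".join(columns) + "\n")
        for row in data:
            fh.write(",".join(f"{v:.8g}" for v in row) + "\n")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    lam = GRID

    xyz = cie1931_xyz(lam)
    write_csv(
        OUT / "cie1931_xyz_approx.csv",
        "CIE 1931 2-deg color matching functions, multi-lobe Gaussian fit\n"
        "(Wyman, Sloan & Shirley 2013), negative lobes clamped at 0.\n"
        "Generated by scripts/make_standard_curves.py.",
        ["wavelength_nm", "X", "Y", "Z"],
        np.column_stack([lam, xyz]),
    )

    lms = np.column_stack(
        [govardovskii_a1(lam, p) for p in (566.0, 541.0, 441.0)]
    )
    write_csv(
        OUT / "lms_cone_fundamentals_synthetic.csv",
        "Synthetic human cone spectral sensitivities: Govardovskii et al.\n"
        "(2000) A1 pigment nomogram at corneal peaks 566/541/441 nm, each\n"
        "normalized to unit maximum.  A stand-in for measured cone\n"
        "fundamentals (no pre-receptoral filtering).\n"
        "Generated by scripts/make_standard_curves.py.",
        ["wavelength_nm", "LW", "MW", "SW"],
        np.column_stack([lam, lms]),
    )

    write_csv(
        OUT / "d65_interpolated.csv",
        "CIE standard illuminant D65 relative spectral power, PCHIP\n"
        "interpolation of the 10 nm tabulation (100 at 560 nm).\n"
        "Generated by scripts/make_standard_curves.py.",
        ["wavelength_nm", "power"],
        np.column_stack([lam, d65(lam)]),
    )
    print(f"wrote 3 tables to {OUT}")


if __name__ == "__main__":
    main()
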