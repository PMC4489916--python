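"""Mixed-effects Fourier (trigonometric) regression over the adjusted cycle.

An outcome measured repeatedly across the 28-day adjusted ovulatory cycle is
modeled as a periodic fixed-effect curve plus nested random intercepts:

    y_ijk = mu + sum_h [ beta_h sin(h theta) + gamma_h cos(h theta) ]
            + (covariates) + u_i + v_ij + e_ijk,

where theta = 2*pi*(adjusted_day - 1)/28 is the cycle phase (menses onset at
phase 0), u_i is a participant intercept, v_ij a cycle-within-participant
intercept and e_ijk residual noise.  The default uses the first two harmonic
pairs (h = 1, 2); higher orders are available by configuration.  This is the
natural extension of single-harmonic cosinor rhythmometry to more realistic
cyclic shapes.

Estimation is by maximum likelihood (not REML) so that likelihood-ratio
tests of the fixed Fourier terms are valid: the cycle test compares the full
model against the same model with all harmonic terms removed, giving a
chi-square statistic on 2 x orders degrees of freedom (4 by default).  The
effect size is the standard deviation of the fitted periodic curve over a
full cycle, sqrt(sum of squared Fourier coefficients / 2).  Confidence bands
for the fitted curve use only the covariance of the Fourier coefficients,
deliberately excluding the intercept's uncertainty: the bands describe the
precision of the curve's *shape*, not of the grand mean.

Model fitting is delegated to ``statsmodels`` ``MixedLM``; boundary (zero)
variance components are legitimate outcomes and are reported, not treated as
failures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FourierFit",
    "PERIOD_DAYS",
    "fourier_basis",
    "basis_names",
    "add_fourier_columns",
    "fit_fourier_mixed",
    "lr_cycle_test",
    "effect_size",
    "fitted_curve_ci",
    "ComparabilityError",
]

log = logging.getLogger(__name__)

PERIOD_DAYS = 28.0


class ComparabilityError(ValueError):
    """Models not nested / not fitted comparably for a likelihood-ratio test."""


def fourier_basis(adjusted_day, orders: int = 2) -> np.ndarray:
    """Harmonic regressors at an adjusted day (scalar or array).

    theta = 2*pi*(adjusted_day - 1)/28; returns
    (sin theta, cos theta, sin 2theta, cos 2theta, ...) — shape
    (..., 2*orders).
    """
    day = np.asarray(adjusted_day, dtype=float)
    if np.any(day < 1.0 - 1e-9) or np.any(day > PERIOD_DAYS + 1e-9):
        raise ValueError(f"adjusted days must lie in [1, {PERIOD_DAYS:.0f}]")
    theta = 2.0 * np.pi * (day - 1.0) / PERIOD_DAYS
    cols = []
    for h in range(1, orders + 1):
        cols.append(np.sin(h * theta))
        cols.append(np.cos(h * theta))
    return np.stack(cols, axis=-1)


def basis_names(orders: int = 2) -> list:
    names = []
    for h in range(1, orders + 1):
        names += [f"sin{h}", f"cos{h}"]
    return names


def add_fourier_columns(data: pd.DataFrame, orders: int = 2,
                        day_col: str = "adjusted_day") -> pd.DataFrame:
    out = data.copy()
    B = fourier_basis(out[day_col].to_numpy(), orders)
    for j, name in enumerate(basis_names(orders)):
        out[name] = B[:, j]
    return out


@dataclass
class FourierFit:
    """A fitted mixed-effects Fourier regression.

    ``coef`` holds the 2*orders Fourier coefficients in basis order
    (sin1, cos1, sin2, cos2, ...); ``cov`` is their covariance block.
    Variance components at the boundary are reported as 0.
    """

    intercept: float
    coef: np.ndarray
    cov: np.ndarray
    var_participant: float
    var_cycle: float
    var_resid: float
    loglik: float
    orders: int
    n_obs: int
    method: str = "ML"
    outcome: str = ""
    covariate_coef: dict = field(default_factory=dict)
    converged: bool = True
    has_cycle_component: bool = True

    @property
    def n_fourier_terms(self) -> int:
        return len(self.coef)


def _validate_table(data: pd.DataFrame, outcome: str, covariates,
                    min_participants: int = 2):
    required = {"participant_id", "cycle_id", "adjusted_day", outcome}
    required |= set(covariates)
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"observation table missing columns {sorted(missing)}")
    if data["participant_id"].nunique() < min_participants:
        raise ValueError(
            f"mixed fitting needs at least {min_participants} participants"
        )
    y = data[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"outcome {outcome!r} contains non-finite values")


def fit_fourier_mixed(
    data: pd.DataFrame,
    outcome: str,
    covariates=(),
    include_fourier_terms: bool = True,
    orders: int = 2,
    min_participants: int = 2,
) -> FourierFit:
    """Fit the nested-random-intercept Fourier model by maximum likelihood.

    ``data`` needs columns participant_id, cycle_id, adjusted_day and the
    outcome (plus any covariates).  With ``include_fourier_terms=False``
    the harmonic terms are dropped — the reduced model for the cycle test.
    The cycle-within-participant variance component is included whenever any
    participant contributes more than one cycle; with one cycle per
    participant it is unidentifiable against the participant intercept and
    is omitted (reported as 0).
    """
    import statsmodels.api as sm

    covariates = list(covariates)
    _validate_table(data, outcome, covariates, min_participants)
    if include_fourier_terms:
        n_days = data["adjusted_day"].nunique()
        if n_days < 2 * orders + 1:
            raise ValueError(
                f"need at least {2 * orders + 1} distinct adjusted days for "
                f"{orders} harmonic pairs, got {n_days}"
            )
    df = add_fourier_columns(data, orders)
    fnames = basis_names(orders) if include_fourier_terms else []
    rhs = " + ".join(fnames + covariates) or "1"
    formula = f"{outcome} ~ {rhs}"

    multi_cycle = (
        df.groupby("participant_id")["cycle_id"].nunique().max() > 1
    )
    vc = {"cycle": "0 + C(cycle_id)"} if multi_cycle else None
    model = sm.MixedLM.from_formula(
        formula,
        data=df,
        groups="participant_id",
        re_formula="1",
        vc_formula=vc,
    )
    res = None
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs is fastest but can fail near variance boundaries; fall back
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                res = model.fit(reml=False, method=method, maxiter=2000)
            except np.linalg.LinAlgError as exc:
                errors.append(f"{method}: {exc}")
                continue
            if res.converged and np.isfinite(res.llf):
                break
            errors.append(
                f"{method}: " + ("non-finite log-likelihood"
                                 if res.converged else "did not converge")
            )
            res = None
    if res is None:
        raise RuntimeError(
            "mixed-model fit failed; optimizer diagnostics: " + "; ".join(errors)
        )

    fe = res.fe_params
    coef = np.array([fe[n] for n in fnames]) if fnames else np.zeros(0)
    if fnames:
        cov = np.asarray(res.cov_params().loc[fnames, fnames])
    else:
        cov = np.zeros((0, 0))
    var_participant = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    var_cycle = float(res.vcomp[0]) if multi_cycle and res.vcomp.size else 0.0
    if multi_cycle and var_cycle <= 1e-10:
        log.info("cycle-within-participant variance at boundary (0)")
    covariate_coef = {c: float(fe[c]) for c in covariates}
    return FourierFit(
        intercept=float(fe["Intercept"]),
        coef=coef,
        cov=cov,
        var_participant=max(var_participant, 0.0),
        var_cycle=max(var_cycle, 0.0),
        var_resid=float(res.scale),
        loglik=float(res.llf),
        orders=orders,
        n_obs=int(res.nobs),
        method="ML",
        outcome=outcome,
        covariate_coef=covariate_coef,
        converged=bool(res.converged),
        has_cycle_component=bool(multi_cycle),
    )


def lr_cycle_test(full: FourierFit, reduced: FourierFit):
    """Likelihood-ratio test that the cycle (Fourier) terms are zero.

    Returns (chi2, df, p) with chi2 = 2 * (loglik_full - loglik_reduced)
    clamped at zero and df the number of harmonic terms in the full model
    (4 for the default two pairs, regardless of covariates).
    """
    if full.method != reduced.method:
        raise ComparabilityError("models fitted with different methods")
    if full.n_obs != reduced.n_obs or full.outcome != reduced.outcome:
        raise ComparabilityError(
            "full and reduced models must be fitted to identical rows"
        )
    if reduced.n_fourier_terms != 0:
        raise ComparabilityError("reduced model still contains Fourier terms")
    df = full.n_fourier_terms
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def effect_size(fit: FourierFit) -> float:
    """Standard deviation of the fitted periodic curve over one full cycle.

    For harmonic regression this is sqrt(sum(coef^2) / 2): each sine or
    cosine contributes half its squared amplitude to the curve's variance.
    """
    return float(np.sqrt(np.sum(fit.coef**2) / 2.0))


def fitted_curve_ci(fit: FourierFit, grid) -> pd.DataFrame:
    """Fitted curve with 95% shape-precision bands on a grid of days.

    Pointwise variance is x'Vx with x the harmonic basis vector and V the
    Fourier-coefficient covariance; the intercept's sampling variance is
    excluded, so the bands describe how precisely the curve's shape is
    estimated about the grand mean.
    """
    grid = np.asarray(grid, dtype=float)
    X = fourier_basis(grid, fit.orders)
    eigs = np.linalg.eigvalsh((fit.cov + fit.cov.T) / 2.0) if fit.cov.size else np.zeros(1)
    if eigs.min() < -1e-8 * max(eigs.max(), 1.0):
        raise ValueError("Fourier coefficient covariance is not PSD")
    mean = fit.intercept + X @ fit.coef
    var = np.einsum("ij,jk,ik->i", X, fit.cov, X) if fit.cov.size else np.zeros(len(grid))
    half = 1.96 * np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {"day": grid, "mean": mean, "lower95": mean - half, "upper95": mean + half}
    )
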