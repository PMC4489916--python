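"""End-to-end orchestration: observations -> curves -> contrasts -> verdicts.

``run_study`` takes a seeded configuration, obtains an observation table
(simulated, or supplied by the user), fits the mixed-effects Fourier model
for each requested outcome, runs the likelihood-ratio cycle test, evaluates
fitted curves with confidence bands, and derives day-14 perceptibility
contrasts from the fitted curves — the receptor-noise distance under the
standard, minimum and maximum cone-ratio settings, and the LAB axis
differences against their 2.2 threshold.  Everything lands in a
machine-readable summary (JSON) plus CSV stage outputs; a seeded run is
byte-reproducible.

``reanalyze_s1`` is the matching path for an externally supplied cone-catch
dataset with columns (adjusted cycle day, LW, MW, SW): redness is LW/MW, the
same Fourier model and cycle test are fitted, and day-14 JND contrasts are
reported under all three cone-ratio settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cyclic_stats, perception
from .cone_mapping import LABColor
from .cyclic_stats import (
    effect_size,
    fit_fourier_mixed,
    fitted_curve_ci,
    lr_cycle_test,
)
from .optics import ConeCatch
from .perception import CONE_RATIO_VARIANTS, NoiseModel
from .synthetic_data import StudyDesign, gen_study

__all__ = ["RunConfig", "run_study", "reanalyze_s1", "SchemaError"]

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Input table lacks required columns."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    With no ``observations`` path, a synthetic study is generated from
    ``design`` (seed overridden by ``seed``).  ``outcomes`` are fitted
    independently; ``lab_outcomes`` drive the LAB contrast curves.
    """

    seed: int = 0
    out_dir: str | None = None
    design: StudyDesign | None = None
    observations: str | None = None
    outcomes: tuple = ("redness", "lab_l")
    orders: int = 2
    reference_day: float = 14.0
    covariates: tuple = ()
    weber: tuple = (0.08, 0.02, 0.02)
    weber_alt: tuple = (0.09, 0.02, 0.02)
    curve_grid_step: float = 0.5
    make_figures: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _noise_models(config: RunConfig) -> dict:
    """The noise settings reported side by side in every run.

    ``weber_direct`` uses the printed Weber triplets verbatim; the
    ``abundance_scaled`` variants propagate the standard / minimum /
    maximum cone-ratio assumptions through the square-root noise scaling,
    which is where cone-ratio variation actually changes the answer.
    """
    models = {
        "weber_direct": NoiseModel(weber=config.weber, mode="weber_direct"),
        "weber_direct_alt": NoiseModel(weber=config.weber_alt, mode="weber_direct"),
    }
    for name, ratios in CONE_RATIO_VARIANTS.items():
        models[f"abundance_scaled_{name}"] = NoiseModel(
            weber=config.weber, abundance=ratios, mode="abundance_scaled"
        )
    return models


def _fit_outcome(data, outcome, covariates, orders):
    full = fit_fourier_mixed(data, outcome, covariates, True, orders)
    reduced = fit_fourier_mixed(data, outcome, covariates, False, orders)
    chi2, dof, p = lr_cycle_test(full, reduced)
    return full, {
        "chi2": chi2,
        "df": dof,
        "p": p,
        "effect_size": effect_size(full),
        "intercept": full.intercept,
        "coef": full.coef.tolist(),
        "var_participant": full.var_participant,
        "var_cycle": full.var_cycle,
        "var_resid": full.var_resid,
        "loglik_full": full.loglik,
        "loglik_reduced": reduced.loglik,
    }


def _curve_contrasts(fits, grid, reference_day, noise_models, mw_base, sw_ratio):
    """Day-14 contrasts along the fitted curves.

    Cone catches along the curve are reconstructed from the fitted redness
    (LW/MW) curve with the data-mean MW as base; LAB values come from the
    fitted lab_l/lab_a/lab_b curves.  Returns (per-noise-model max JND,
    contrast table).
    """
    redness_curve = (
        fits["redness"].intercept
        + cyclic_stats.fourier_basis(grid, fits["redness"].orders)
        @ fits["redness"].coef
    )
    lab_curves = {}
    for name in ("lab_l", "lab_a", "lab_b"):
        if name in fits:
            f = fits[name]
            lab_curves[name] = (
                f.intercept + cyclic_stats.fourier_basis(grid, f.orders) @ f.coef
            )
        else:
            lab_curves[name] = np.zeros_like(grid)

    observations = [
        (
            day,
            ConeCatch(("LW", "MW", "SW"),
                      (r * mw_base, mw_base, sw_ratio * mw_base)),
            LABColor(lab_curves["lab_l"][i], lab_curves["lab_a"][i],
                     lab_curves["lab_b"][i]),
        )
        for i, (day, r) in enumerate(zip(grid, redness_curve))
    ]
    max_jnd = {}
    series = None
    for name, noise in noise_models.items():
        cs = perception.contrast_series(
            observations, reference_day=reference_day, noise=noise
        )
        max_jnd[name] = cs.maxima["jnd"]
        if name == "weber_direct":
            series = cs
    return max_jnd, series


def _load_observations(config: RunConfig):
    if config.observations is not None:
        obs = pd.read_csv(config.observations)
        truth = None
    else:
        design = config.design or StudyDesign()
        if design.seed != config.seed:
            design = StudyDesign(**{**asdict(design), "seed": config.seed})
        obs, truth = gen_study(design)
    required = {"participant_id", "cycle_id", "adjusted_day"}
    missing = required - set(obs.columns)
    if missing:
        raise SchemaError(f"observation table missing columns {sorted(missing)}")
    if "redness" not in obs.columns:
        if {"LW", "MW"} <= set(obs.columns):
            obs = obs.assign(redness=obs["LW"] / obs["MW"])
        else:
            raise SchemaError("need a 'redness' column or LW and MW catches")
    return obs, truth


def run_study(config: RunConfig) -> dict:
    """Run the full analysis and return (and optionally write) the bundle.

    The returned dict holds the observation table, per-outcome fits and
    tests, fitted curves with 95% bands, the day-14 contrast series, the
    maximum JND under every noise setting, and perceptibility verdicts.
    """
    obs, truth = _load_observations(config)
    log.info("stage observations: %d rows, %d participants",
             len(obs), obs["participant_id"].nunique())

    fit_outcomes = list(dict.fromkeys(
        list(config.outcomes)
        + [c for c in ("lab_l", "lab_a", "lab_b") if c in obs.columns]
    ))
    fits, outcome_stats, curves = {}, {}, {}
    grid = np.arange(1.0, 28.0 + 1e-9, config.curve_grid_step)
    for outcome in fit_outcomes:
        if outcome not in obs.columns:
            raise SchemaError(f"outcome {outcome!r} not in observation table")
        full, stats_d = _fit_outcome(obs, outcome, list(config.covariates),
                                     config.orders)
        fits[outcome] = full
        outcome_stats[outcome] = stats_d
        curves[outcome] = fitted_curve_ci(full, grid)
        log.info("stage fit[%s]: chi2(%d)=%.3f p=%.4g", outcome,
                 stats_d["df"], stats_d["chi2"], stats_d["p"])

    noise_models = _noise_models(config)
    contrasts, series = None, None
    if "redness" in fits:
        mw_base = float(obs["MW"].mean()) if "MW" in obs.columns else 1.0
        sw_ratio = (
            float((obs["SW"] / obs["MW"]).mean())
            if {"SW", "MW"} <= set(obs.columns) else 0.95
        )
        contrasts, series = _curve_contrasts(
            fits, grid, config.reference_day, noise_models, mw_base, sw_ratio
        )

    verdicts = {}
    if contrasts is not None:
        verdicts["max_jnd_any_setting"] = max(contrasts.values())
        verdicts["jnd_perceptible"] = bool(
            max(contrasts.values()) >= perception.JND_THRESHOLD
        )
    if series is not None:
        m = series.maxima
        verdicts["max_abs_a_diff"] = m["abs_A_diff"]
        verdicts["max_delta_e"] = m["delta_e"]
        verdicts["redness_perceptible"] = bool(
            m["abs_A_diff"] > perception.LAB_THRESHOLD
        )

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_observations": int(len(obs)),
        "n_participants": int(obs["participant_id"].nunique()),
        "n_cycles": int(obs["cycle_id"].nunique()),
        "outcomes": {k: _jsonable(v) for k, v in outcome_stats.items()},
        "max_jnd_by_noise_setting": _jsonable(contrasts) if contrasts else None,
        "verdicts": _jsonable(verdicts),
        "config": _jsonable(config.to_dict()),
    }
    bundle = {
        "observations": obs,
        "truth": truth,
        "fits": fits,
        "curves": curves,
        "contrast_series": series,
        "summary": summary,
    }
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: RunConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["observations"].to_csv(out / "observations.csv", index=False)
    for outcome, curve in bundle["curves"].items():
        curve.to_csv(out / f"curve_{outcome}.csv", index=False)
    if bundle["contrast_series"] is not None:
        bundle["contrast_series"].table.to_csv(
            out / "contrasts_day14.csv", index=False
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config.json", "w") as fh:
        json.dump(_jsonable(config.to_dict()), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if bundle["truth"] is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(_jsonable(bundle["truth"]), fh, indent=2, sort_keys=True)
            fh.write("\n")
    if config.make_figures:
        _write_figures(bundle, out)


def _write_figures(bundle: dict, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for outcome, curve in bundle["curves"].items():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve["day"], curve["mean"], color="k")
        ax.fill_between(curve["day"], curve["lower95"], curve["upper95"],
                        alpha=0.3, color="grey")
        ax.set_xlabel("adjusted cycle day")
        ax.set_ylabel(outcome)
        fig.tight_layout()
        fig.savefig(out / f"curve_{outcome}.png", dpi=150)
        plt.close(fig)
    if bundle["contrast_series"] is not None:
        t = bundle["contrast_series"].table
        fig, ax = plt.subplots(figsize=(6, 4))
        for colname, lbl in (("delta_e", "Delta E"), ("A_diff", "A_diff"),
                             ("jnd", "JND")):
            ax.plot(t["day"], t[colname], label=lbl)
        ax.axhline(perception.LAB_THRESHOLD, ls="--", c="r", lw=0.8)
        ax.axhline(perception.JND_THRESHOLD, ls=":", c="b", lw=0.8)
        ax.set_xlabel("adjusted cycle day")
        ax.set_ylabel("contrast vs day 14")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "contrasts_day14.png", dpi=150)
        plt.close(fig)


_S1_COLUMN_KEYS = {
    "adjusted_day": ("adjustedday", "cycleday", "day", "adjcycleday",
                     "cycledayadjusted", "dayadjusted"),
    "LW": ("lw", "conelw", "l"),
    "MW": ("mw", "conemw", "m"),
    "SW": ("sw", "conesw", "s"),
    "participant_id": ("participant", "participantid", "subject", "id", "woman"),
    "cycle_id": ("cycle", "cycleid"),
}


def _normalize(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum())


def _match_s1_columns(columns) -> dict:
    norm = {_normalize(c): c for c in columns}
    found = {}
    for target, keys in _S1_COLUMN_KEYS.items():
        for k in keys:
            if k in norm:
                found[target] = norm[k]
                break
    return found


def _segment_cycles(adjusted_day: np.ndarray) -> np.ndarray:
    """Delimit cycles at decreases of adjusted day (documented heuristic)."""
    breaks = np.concatenate([[True], np.diff(adjusted_day) < 0])
    return np.cumsum(breaks)


def reanalyze_s1(dataset_path, config: RunConfig | None = None) -> dict:
    """Re-analysis of an adjusted-day cone-catch table (CSV or XLSX).

    Requires columns for adjusted cycle day and the LW, MW, SW catches
    (case/spacing-tolerant).  If participant/cycle identifier columns are
    absent, contiguous runs of non-decreasing adjusted day are treated as
    separate participant-cycles — a heuristic; supply explicit columns when
    available.  Redness is LW/MW; the Fourier mixed model, cycle test and
    day-14 JND contrasts under the three cone-ratio settings are computed
    as in ``run_study``.
    """
    if config is None:
        config = RunConfig()
    path = Path(dataset_path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    cols = _match_s1_columns(raw.columns)
    needed = {"adjusted_day", "LW", "MW", "SW"}
    missing = needed - set(cols)
    if missing:
        raise SchemaError(
            f"dataset {path.name} lacks columns for {sorted(missing)}; "
            f"expected names like 'cycle day (adjusted)', 'LW', 'MW', 'SW' "
            f"(found {list(raw.columns)})"
        )
    df = pd.DataFrame({t: raw[c] for t, c in cols.items()})
    df = df.dropna(subset=["adjusted_day", "LW", "MW", "SW"])
    df["adjusted_day"] = df["adjusted_day"].astype(float).clip(1.0, 28.0)
    if "cycle_id" not in df.columns:
        seg = _segment_cycles(df["adjusted_day"].to_numpy())
        df["cycle_id"] = [f"C{s}" for s in seg]
    if "participant_id" not in df.columns:
        df["participant_id"] = df["cycle_id"]
        log.warning(
            "no participant column: treating each detected cycle as its own "
            "participant"
        )
    df["redness"] = df["LW"] / df["MW"]

    min_participants = 2
    if df["participant_id"].nunique() < 2:
        log.warning("single participant: participant variance will sit at "
                    "the boundary")
        min_participants = 1
    full = fit_fourier_mixed(df, "redness", orders=config.orders,
                             min_participants=min_participants)
    reduced = fit_fourier_mixed(df, "redness", include_fourier_terms=False,
                                orders=config.orders,
                                min_participants=min_participants)
    chi2, dof, p = lr_cycle_test(full, reduced)

    noise_models = {
        name: NoiseModel(weber=config.weber, abundance=ratios,
                         mode="abundance_scaled")
        for name, ratios in CONE_RATIO_VARIANTS.items()
    }
    noise_models["weber_direct"] = NoiseModel(weber=config.weber)
    grid = np.arange(1.0, 28.0 + 1e-9, config.curve_grid_step)
    mw_base = float(df["MW"].mean())
    sw_ratio = float((df["SW"] / df["MW"]).mean())
    fits = {"redness": full}
    max_jnd, _ = _curve_contrasts(fits, grid, config.reference_day,
                                  noise_models, mw_base, sw_ratio)
    result = {
        "n_observations": int(len(df)),
        "n_participants": int(df["participant_id"].nunique()),
        "redness": {
            "chi2": chi2,
            "df": dof,
            "p": p,
            "effect_size": effect_size(full),
            "coef": full.coef.tolist(),
            "intercept": full.intercept,
        },
        "max_jnd_by_noise_setting": _jsonable(max_jnd),
        "max_jnd": float(max(max_jnd.values())),
        "jnd_perceptible": bool(
            max(max_jnd.values()) >= perception.JND_THRESHOLD
        ),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "s1_reanalysis.json", "w") as fh:
            json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
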