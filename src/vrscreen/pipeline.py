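"""End-to-end screening pipeline: read -> window -> reference -> metrics -> fit.

``analyze_experiment`` is the library entry point used by tests, the
sensitivity scan and the CLI alike; ``run_screen`` adds file output
(tidy CSVs, JSON results, diagnostic plots, machine-readable run log).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .binding import (
    BindingFitResult,
    fit_kd_global,
    uncertainty_jackknife,
    uncertainty_noise_replicates,
)
from .metrics import METRICS_WITH_SIGMA, MetricCurve, metric_curve, shannon_binning
from .profiles import (
    ExperimentSet,
    build_apo_reference,
    load_manifest,
    prepare_experiment,
)

__all__ = ["ScreenConfig", "analyze_experiment", "run_screen", "mass_budget"]


@dataclass
class ScreenConfig:
    """Validated configuration of one screening run (one experiment set)."""

    manifest: str
    d_max: float = defaults.D_MAX_NM
    q_window: tuple[float, float] | None = None  # None -> concentration tier
    metric: str = "V_R"
    fit_c: bool = False
    uncertainty: str = "auto"  # auto | jackknife | noise | none
    n_replicates: int = defaults.N_NOISE_REPLICATES
    seed: int = 0
    output_dir: str = "screen_out"
    apo_outlier_threshold: float = defaults.APO_OUTLIER_VR_THRESHOLD

    def __post_init__(self) -> None:
        if self.metric not in ("V_R", "chi_lin", "R_g", "V_c", "V_P"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.uncertainty not in ("auto", "jackknife", "noise", "none"):
            raise ValueError(f"unknown uncertainty method {self.uncertainty!r}")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


def analyze_experiment(
    expt: ExperimentSet,
    metric: str = "V_R",
    fit_c: bool = False,
    apo_outlier_threshold: float = defaults.APO_OUTLIER_VR_THRESHOLD,
) -> tuple[list[MetricCurve], BindingFitResult]:
    """Metric curves against the apo reference, then the global K_D fit."""
    prepared = prepare_experiment(expt)
    reference, discarded = build_apo_reference(
        prepared.apo_profiles,
        outlier_threshold=apo_outlier_threshold,
        d_max=prepared.d_max,
    )
    grid = reference.q
    binning = shannon_binning((grid[0], grid[-1]), grid, prepared.d_max)
    curves = [
        metric_curve(s, reference, metric, binning=binning, fit_c=fit_c)
        for s in prepared.series
    ]
    fit = fit_kd_global(curves, prepared.receptor_concentration)
    fit.diagnostics["discarded_apo_replicates"] = discarded
    return curves, fit


def run_screen(config: ScreenConfig) -> dict:
    """Execute a full screen and write the report bundle.

    Outputs in ``config.output_dir``:

    - ``metrics.csv``     — ligand, ratio, metric value, sigma, flags
    - ``fit_results.csv`` / ``fit_results.json`` — per-ligand K_D and errors
    - ``binding_curves.svg`` — metric vs ratio with the fitted model
    - ``run_log.json``    — config, defaults version, seed, exclusions
    """
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    expt = load_manifest(config.manifest)
    if config.q_window is not None:
        expt.q_window = tuple(config.q_window)
    else:
        expt.q_window = defaults.q_window_for_concentration(
            expt.receptor_concentration
        )
    expt.d_max = config.d_max

    curves, fit = analyze_experiment(
        expt,
        metric=config.metric,
        fit_c=config.fit_c,
        apo_outlier_threshold=config.apo_outlier_threshold,
    )

    method = config.uncertainty
    if method == "auto":
        method = "noise" if config.metric in METRICS_WITH_SIGMA else "jackknife"
    unc_diag: dict = {}
    if method == "noise":
        sigmas, unc_diag = uncertainty_noise_replicates(
            curves,
            n_replicates=config.n_replicates,
            seed=config.seed,
            receptor_concentration=expt.receptor_concentration,
        )
    elif method == "jackknife":
        sigmas, unc_diag = uncertainty_jackknife(
            curves, receptor_concentration=expt.receptor_concentration
        )
    else:
        sigmas = {lig: float("nan") for lig in fit.ligands}
    for lig, s in sigmas.items():
        fit.ligands[lig].sigma_log10_KD = s

    rows = []
    for c in curves:
        extras = c.extras.get("fitted_c", [])
        for i, (ratio, value) in enumerate(zip(c.ratios, c.values)):
            rows.append(
                dict(
                    ligand=c.ligand_id,
                    ratio=ratio,
                    metric=c.metric_name,
                    value=value,
                    sigma=(
                        c.uncertainties[i]
                        if c.uncertainties is not None
                        else float("nan")
                    ),
                    c=extras[i] if i < len(extras) else float("nan"),
                    excluded=False,
                    reason="",
                )
            )
        for ratio, reason in c.excluded:
            rows.append(
                dict(
                    ligand=c.ligand_id, ratio=ratio, metric=c.metric_name,
                    value=float("nan"), sigma=float("nan"), c=float("nan"),
                    excluded=True, reason=reason,
                )
            )
    metrics_df = pd.DataFrame(rows).sort_values(["ligand", "ratio"])
    metrics_df.to_csv(out / "metrics.csv", index=False, float_format="%.10g")

    fit_rows = [
        dict(
            ligand=lf.ligand_id,
            K_D_molar=lf.K_D,
            log10_KD=lf.log10_KD,
            sigma_log10_KD=lf.sigma_log10_KD,
            X_apo=fit.X_apo,
            X_holo=lf.X_holo,
            n_points_used=lf.n_points_used,
            at_bound=lf.at_bound,
        )
        for lf in fit.ligands.values()
    ]
    fit_df = pd.DataFrame(fit_rows)
    fit_df.to_csv(out / "fit_results.csv", index=False, float_format="%.10g")
    (out / "fit_results.json").write_text(json.dumps(fit_rows, indent=2))

    _plot_binding_curves(curves, fit, out / "binding_curves.svg")

    n_used = int(sum(len(c.ratios) for c in curves))
    n_excl = int(sum(len(c.excluded) for c in curves))
    run_log = dict(
        config=asdict(config),
        defaults_version=defaults.DEFAULTS_VERSION,
        q_window=list(expt.q_window),
        d_max=expt.d_max,
        receptor_concentration=expt.receptor_concentration,
        apo_outlier_rule=(
            "V_R against pointwise-median profile > "
            f"{config.apo_outlier_threshold}"
        ),
        uncertainty_method=method,
        points_used=n_used,
        points_excluded=n_excl,
        exclusions=[
            dict(ligand=c.ligand_id, ratio=r, reason=reason)
            for c in curves
            for r, reason in c.excluded
        ],
        discarded_apo_replicates=fit.diagnostics.get(
            "discarded_apo_replicates", []
        ),
        uncertainty_diagnostics=_jsonable(unc_diag),
    )
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return dict(curves=curves, fit=fit, metrics=metrics_df, fit_table=fit_df,
                run_log=run_log)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _plot_binding_curves(curves, fit, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .binding import model_metric

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ratios, values, sig = c.active()
        (line,) = ax.plot(ratios, values, "o", label=c.ligand_id)
        if sig is not None:
            ax.errorbar(ratios, values, yerr=sig, fmt="none",
                        ecolor=line.get_color(), alpha=0.5)
        lf = fit.ligands[c.ligand_id]
        grid = np.linspace(0, max(ratios.max(), 1.0), 200)
        model = [
            model_metric(fit.X_apo, lf.X_holo, lf.log10_KD, r,
                         fit.receptor_concentration)
            for r in grid
        ]
        ax.plot(grid, model, "-", color=line.get_color(), alpha=0.7)
    ax.set_xlabel("ligand : receptor ratio")
    ax.set_ylabel(curves[0].metric_name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def mass_budget(
    receptor_concentration: float,
    molar_mass_kda: float,
    volume_per_point_ul: float,
    n_points: int,
) -> float:
    """Protein mass consumed by one titration, in mg (two decimals).

    mass = concentration [mol/l] x molar mass [g/mol] x volume [l] x points.
    """
    if receptor_concentration < 0 or molar_mass_kda < 0 or volume_per_point_ul < 0:
        raise ValueError("mass budget inputs must be nonnegative")
    grams = (
        receptor_concentration
        * (molar_mass_kda * 1000.0)
        * (volume_per_point_ul * 1e-6)
        * n_points
    )
    return round(grams * 1000.0, 2)
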