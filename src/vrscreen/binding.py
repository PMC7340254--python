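"""Two-state binding equilibrium and global K_D fitting from metric curves.

A receptor R and ligand L in fast two-state exchange obey mass action,

    K_D = [R][L] / [RL],

so at total concentrations R_t, L_t the complex concentration is the
admissible root of a quadratic (``solve_bound_fraction``).  Because the
scattering metrics vary pseudo-linearly with the bound population, a metric
X measured along a titration ladder is modelled as

    X(ratio) = X_apo + (X_holo - X_apo) * [RL] / R_t,

and for each experiment set the parameters {X_apo (shared), X_holo(L),
log10 K_D(L)} are fitted jointly over all ligands by Powell minimization,
with log10 K_D box-constrained to within four decades of the receptor
concentration (a constant-receptor titration carries no information beyond
that range).

Two uncertainty estimators translate measurement error into sigma(log10 K_D):
Gaussian noise replicates for metrics that carry per-point sigma, and
single-point-removal (jackknife) for those that do not (V_R, V_P).  In both,
replicates whose fitted apo-holo difference deviates more than 3 sigma from
the ensemble mean are discarded as fit failures before the spread is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .metrics import MetricCurve

__all__ = [
    "TwoStateSystem",
    "BindingFitResult",
    "solve_bound_fraction",
    "model_metric",
    "fit_kd_global",
    "uncertainty_noise_replicates",
    "uncertainty_jackknife",
]

KD_BOX_DECADES = 4.0
DEFAULT_NOISE_REPLICATES = 1000


@dataclass
class TwoStateSystem:
    receptor_total: float
    ligand_total: float
    K_D: float

    def __post_init__(self) -> None:
        if self.receptor_total < 0 or self.ligand_total < 0:
            raise ValueError("total concentrations must be nonnegative")
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")


def solve_bound_fraction(system: TwoStateSystem) -> tuple[float, float, float]:
    """Equilibrium ([RL], [R]_free, [L]_free) from the mass-action quadratic.

    [RL] is the smaller root of x^2 - (R+L+K)x + RL = 0, written in the
    numerically stable form x = 2RL / (b + sqrt(b^2 - 4RL)) to avoid
    cancellation when K_D dominates.  Conservation holds to rounding.
    """
    r, l, k = system.receptor_total, system.ligand_total, system.K_D
    if r == 0 or l == 0:
        return 0.0, r, l
    b = r + l + k
    disc = b * b - 4.0 * r * l
    disc = max(disc, 0.0)  # analytic nonnegativity, guarded for rounding
    rl = 2.0 * r * l / (b + math.sqrt(disc))
    rl = min(rl, r, l)
    return rl, r - rl, l - rl


@dataclass
class LigandFit:
    ligand_id: str
    K_D: float
    log10_KD: float
    sigma_log10_KD: float | None
    X_holo: float
    n_points_used: int
    at_bound: bool


@dataclass
class BindingFitResult:
    X_apo: float
    ligands: dict[str, LigandFit]
    receptor_concentration: float
    objective: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def model_metric(
    X_apo: float,
    X_holo: float,
    log10_KD: float,
    ratio: float,
    receptor_total: float,
) -> float:
    """Linear metric model at one titration point."""
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    rl, _, _ = solve_bound_fraction(
        TwoStateSystem(receptor_total, ratio * receptor_total, 10.0**log10_KD)
    )
    return X_apo + (X_holo - X_apo) * (rl / receptor_total)


def _bound_fraction_vec(ratios: np.ndarray, receptor_total: float, kd: float):
    l = ratios * receptor_total
    b = receptor_total + l + kd
    disc = np.maximum(b * b - 4.0 * receptor_total * l, 0.0)
    rl = np.where(
        l > 0, 2.0 * receptor_total * l / (b + np.sqrt(disc)), 0.0
    )
    return np.minimum(rl, np.minimum(receptor_total, l)) / receptor_total


def fit_kd_global(
    curves: list[MetricCurve],
    receptor_concentration: float | None = None,
    kd_box_decades: float = KD_BOX_DECADES,
    warm_start: np.ndarray | None = None,
) -> BindingFitResult:
    """Global fit of {X_apo, X_holo(L), log10 K_D(L)} over one experiment set.

    Residuals are weighted by the metric's per-point sigma where available,
    unweighted otherwise.  Starts are deterministic — log10 K_D at the
    receptor concentration and offset by +/-2 decades (the likelihood is
    flat far from [R], so multiple starts guard against spurious interior
    optima), with metric endpoints read off the curve ends — and the best
    objective is kept.  ``warm_start`` adds one further start, used by the
    replicate-based uncertainty estimators to seed each refit from the
    full-data solution.  The K_D box is enforced by clipping inside the
    objective, so the search cannot exploit values beyond the bounds.
    """
    if not curves:
        raise ValueError("no metric curves to fit")
    r_tot = receptor_concentration or curves[0].receptor_concentration
    if r_tot is None or r_tot <= 0:
        raise ValueError("receptor concentration must be positive")

    data = []
    for c in curves:
        ratios, values, sig = c.active()
        if len(values) < 3 or ratios.min() > 0 or ratios.max() <= 1:
            raise ValueError(
                f"curve {c.ligand_id!r}: need >=3 points spanning ratio 0 and >1"
            )
        w = None
        if sig is not None and np.all(np.isfinite(sig)) and np.all(sig > 0):
            w = 1.0 / sig
        data.append((c.ligand_id, ratios, values, w))

    n_lig = len(data)
    n_points = sum(len(d[1]) for d in data)
    if n_points < 1 + 2 * n_lig:
        raise ValueError(
            f"{n_points} points cannot constrain {1 + 2 * n_lig} parameters"
        )

    log_r = math.log10(r_tot)
    lo, hi = log_r - kd_box_decades, log_r + kd_box_decades

    def objective(theta: np.ndarray) -> float:
        x_apo = theta[0]
        total = 0.0
        for i, (_, ratios, values, w) in enumerate(data):
            x_holo = theta[1 + i]
            kd = 10.0 ** np.clip(theta[1 + n_lig + i], lo, hi)
            f = _bound_fraction_vec(ratios, r_tot, kd)
            resid = values - (x_apo + (x_holo - x_apo) * f)
            if w is not None:
                resid = resid * w
            total += float(np.dot(resid, resid))
        return total

    # deterministic start: apo value from ratio-0 points, holo from curve ends
    apo0 = float(np.mean([v[ratios == 0].mean() for _, ratios, v, _ in data]))
    holo0 = [float(values[np.argmax(ratios)]) for _, ratios, values, _ in data]

    def solve(theta0: np.ndarray):
        return minimize(
            objective, theta0, method="Powell",
            options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": 5000},
        )

    def cold_start(off: float) -> np.ndarray:
        theta0 = np.array([apo0] + holo0 + [log_r + off] * n_lig)
        theta0[1 + n_lig :] = np.clip(theta0[1 + n_lig :], lo, hi)
        return theta0

    if warm_start is not None:
        # replicate refits: the full-data solution is almost always in the
        # right basin; one cold start guards against it drifting
        starts = [np.asarray(warm_start, dtype=float), cold_start(0.0)]
    else:
        starts = [cold_start(off) for off in (0.0, -2.0, 2.0)]

    res = None
    for theta0 in starts:
        attempt = solve(theta0)
        if res is None or attempt.fun < res.fun:
            res = attempt

    theta = res.x

    def ligand_ssr(i: int, x_apo: float, x_holo: float, lkd: float) -> float:
        _, ratios, values, w = data[i]
        f = _bound_fraction_vec(ratios, r_tot, 10.0**lkd)
        resid = values - (x_apo + (x_holo - x_apo) * f)
        if w is not None:
            resid = resid * w
        return float(np.dot(resid, resid))

    def best_x_holo(i: int, x_apo: float, lkd: float) -> float:
        # X_holo enters linearly: closed-form weighted least squares
        _, ratios, values, w = data[i]
        f = _bound_fraction_vec(ratios, r_tot, 10.0**lkd)
        ww = w**2 if w is not None else np.ones(len(f))
        denom = float(np.sum(ww * f * f))
        if denom <= 0:
            return x_apo
        return x_apo + float(np.sum(ww * f * (values - x_apo))) / denom

    ligands = {}
    x_apo_hat = float(theta[0])
    for i, (lig, ratios, _, _) in enumerate(data):
        lkd = float(np.clip(theta[1 + n_lig + i], lo, hi))
        x_holo = float(theta[1 + i])
        # degenerate-affinity rule: when pinning K_D at the weak-binding box
        # bound explains this ligand's curve essentially as well as freeing
        # it (improvement below one noise degree of freedom, F-test-like),
        # binding is not resolvable and the sensitivity limit is reported
        # rather than an arbitrary point inside the flat likelihood valley
        x_holo_weak = best_x_holo(i, x_apo_hat, hi)
        s_fit = ligand_ssr(i, x_apo_hat, x_holo, lkd)
        s_weak = ligand_ssr(i, x_apo_hat, x_holo_weak, hi)
        nu = max(len(data[i][1]) - 3, 1)
        if s_weak <= s_fit * (1.0 + 1.0 / nu) + 1e-30:
            lkd, x_holo = hi, x_holo_weak
        ligands[lig] = LigandFit(
            ligand_id=lig,
            K_D=10.0**lkd,
            log10_KD=lkd,
            sigma_log10_KD=None,
            X_holo=x_holo,
            n_points_used=len(ratios),
            at_bound=bool(lkd <= lo + 1e-3 or lkd >= hi - 1e-3),
        )
    hit = any(lf.at_bound for lf in ligands.values())
    return BindingFitResult(
        X_apo=float(theta[0]),
        ligands=ligands,
        receptor_concentration=r_tot,
        objective=float(res.fun),
        converged=bool(res.success),
        diagnostics={"n_points": n_points, "any_at_bound": bool(hit)},
    )


def _theta_of(fit: BindingFitResult, curves: list[MetricCurve]) -> np.ndarray:
    """Parameter vector of a fit, ordered to match ``curves``."""
    holos = [fit.ligands[c.ligand_id].X_holo for c in curves]
    kds = [fit.ligands[c.ligand_id].log10_KD for c in curves]
    return np.array([fit.X_apo] + holos + kds)


def _sigma_with_discard(
    log_kds: np.ndarray, deltas: np.ndarray
) -> tuple[float, int]:
    """Spread of log10 K_D replicates after the >3-sigma apo-holo discard.

    A replicate is dropped when its fitted apo-holo difference lies more
    than 3 ensemble standard deviations from the ensemble mean (single
    pass).  Returns (sigma, number discarded).
    """
    if len(log_kds) == 0:
        return float("nan"), 0
    mu, sd = float(np.mean(deltas)), float(np.std(deltas))
    if sd > 0:
        keep = np.abs(deltas - mu) <= 3.0 * sd
    else:
        keep = np.ones(len(deltas), dtype=bool)
    n_disc = int(np.sum(~keep))
    return float(np.std(log_kds[keep])), n_disc


def uncertainty_noise_replicates(
    curves: list[MetricCurve],
    n_replicates: int = DEFAULT_NOISE_REPLICATES,
    seed: int | None = None,
    receptor_concentration: float | None = None,
) -> tuple[dict[str, float], dict]:
    """sigma(log10 K_D) per ligand from Gaussian noise replicates.

    Each replicate perturbs every metric value by N(0, sigma_point) and
    refits the whole set.  Requires metrics that carry per-point sigma.
    """
    for c in curves:
        if c.uncertainties is None:
            raise ValueError(
                f"metric {c.metric_name!r} carries no per-point sigma; "
                "use uncertainty_jackknife instead"
            )
    rng = np.random.default_rng(seed)
    names = [c.ligand_id for c in curves]
    base = fit_kd_global(curves, receptor_concentration)
    warm = _theta_of(base, curves)
    log_kds = {n: [] for n in names}
    deltas = {n: [] for n in names}
    n_failed = 0
    for _ in range(n_replicates):
        perturbed = []
        for c in curves:
            sig = np.nan_to_num(c.uncertainties, nan=0.0)
            pc = MetricCurve(
                metric_name=c.metric_name,
                ligand_id=c.ligand_id,
                ratios=c.ratios,
                values=c.values + rng.normal(0.0, 1.0, len(c.values)) * sig,
                uncertainties=c.uncertainties,
                receptor_concentration=c.receptor_concentration,
            )
            perturbed.append(pc)
        try:
            fit = fit_kd_global(
                perturbed, receptor_concentration, warm_start=warm
            )
        except ValueError:
            n_failed += 1
            continue
        for n in names:
            log_kds[n].append(fit.ligands[n].log10_KD)
            deltas[n].append(fit.ligands[n].X_holo - fit.X_apo)

    sigmas, discards = {}, {}
    for n in names:
        sigmas[n], discards[n] = _sigma_with_discard(
            np.array(log_kds[n]), np.array(deltas[n])
        )
    diag = {"n_replicates": n_replicates, "n_failed": n_failed,
            "discarded": discards}
    frac_lost = max(
        (discards[n] + n_failed) / max(n_replicates, 1) for n in names
    )
    if frac_lost > 0.5:
        diag["instability_warning"] = (
            f"{frac_lost:.0%} of replicates unusable; fit is ill-constrained"
        )
    return sigmas, diag


def uncertainty_jackknife(
    curves: list[MetricCurve],
    receptor_concentration: float | None = None,
) -> tuple[dict[str, float], dict]:
    """sigma(log10 K_D) per ligand by single titration-point removal.

    One replicate removes one point of one ligand's curve and refits the
    whole set; a ligand's sigma is the spread of its own N removal
    replicates (N points on its curve), after the 3-sigma apo-holo discard.
    """
    sigmas, discards, failures = {}, {}, {}
    for c in curves:
        if len(c.active()[0]) < 4:
            raise ValueError(
                f"curve {c.ligand_id!r} needs >=4 points for jackknife"
            )
    base = fit_kd_global(curves, receptor_concentration)
    warm = _theta_of(base, curves)
    for target in curves:
        log_kds, deltas = [], []
        n_fail = 0
        for j in range(len(target.values)):
            keep = np.ones(len(target.values), dtype=bool)
            keep[j] = False
            reduced = MetricCurve(
                metric_name=target.metric_name,
                ligand_id=target.ligand_id,
                ratios=target.ratios[keep],
                values=target.values[keep],
                uncertainties=(
                    None if target.uncertainties is None
                    else target.uncertainties[keep]
                ),
                receptor_concentration=target.receptor_concentration,
            )
            replicate = [reduced if c is target else c for c in curves]
            try:
                fit = fit_kd_global(
                    replicate, receptor_concentration, warm_start=warm
                )
            except ValueError:
                n_fail += 1
                continue
            log_kds.append(fit.ligands[target.ligand_id].log10_KD)
            deltas.append(fit.ligands[target.ligand_id].X_holo - fit.X_apo)
        sigmas[target.ligand_id], discards[target.ligand_id] = _sigma_with_discard(
            np.array(log_kds), np.array(deltas)
        )
        failures[target.ligand_id] = n_fail
    return sigmas, {"discarded": discards, "refit_failures": failures}
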