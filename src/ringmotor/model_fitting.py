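"""Weighted nonlinear fitting of velocity data to the kinetic model families.

All fits are weighted least squares with weights 1/SEM², carried out with
lmfit on the closed-form velocity functions from :mod:`ringmotor.fv_models`.
Standard errors come from the Jacobian-based covariance at the optimum.
The multi-exponential linear model is prone to local minima, so its fit uses
deterministic multi-start (log-spaced rate grids); the best chi² wins, ties
broken by the smaller parameter-vector norm.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .energetics import DEFAULT_SCALE, ThermalScale
from . import fv_models as fv

__all__ = [
    "VelocityPoint",
    "FitResult",
    "velocity_table",
    "fit_mm_hill",
    "fit_competitive_inhibition",
    "fit_force_velocity",
    "km_vmax_vs_force",
    "compare_models",
]

log = logging.getLogger(__name__)

#: Canonical force bins (pN): twelve half-open intervals used for
#: consolidated force-velocity curves.
CANONICAL_FORCE_BIN_EDGES = np.array(
    [2.0, 4.0, 6.0, 8.0, 10.0, 13.0, 16.0, 20.0, 25.0, 30.0, 40.0, 45.0, 50.0]
)

VELOCITY_TABLE_COLUMNS = [
    "force_bin_center", "atp", "adp", "pi", "velocity", "sem", "n_obs",
]


@dataclass(frozen=True)
class VelocityPoint:
    """One pause-free velocity measurement in a (force bin, buffer) cell."""

    force_bin_center: float   # pN
    atp: float                # μM
    velocity: float           # bp/s
    sem: float                # bp/s
    adp: float = 0.0          # μM
    pi: float = 0.0           # μM
    n_obs: int = 1

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if self.n_obs > 1 and self.sem <= 0:
            raise ValueError("sem must be positive when n_obs > 1")


def velocity_table(points: list[VelocityPoint]) -> pd.DataFrame:
    """Tabulate velocity points with the documented column order."""
    return pd.DataFrame(
        [{c: getattr(p, c) for c in VELOCITY_TABLE_COLUMNS} for p in points]
    )


def points_from_table(df: pd.DataFrame) -> list[VelocityPoint]:
    """Inverse of :func:`velocity_table`."""
    return [
        VelocityPoint(
            force_bin_center=float(r.force_bin_center), atp=float(r.atp),
            adp=float(r.adp), pi=float(r.pi), velocity=float(r.velocity),
            sem=float(r.sem), n_obs=int(r.n_obs),
        )
        for r in df.itertuples()
    ]


@dataclass
class FitResult:
    """Converged parameter estimates with uncertainties and fit quality."""

    model: str
    params: dict[str, float]
    standard_errors: dict[str, float]
    chi2: float
    dof: int
    converged: bool
    covariance: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof if self.dof > 0 else np.nan

    @property
    def aic(self) -> float:
        """Akaike score on the chi² statistic: chi² + 2·k."""
        k = len(self.params) - len(self.extra.get("pinned", ()))
        return self.chi2 + 2 * k

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "standard_errors": dict(self.standard_errors),
            "chi2": float(self.chi2),
            "dof": int(self.dof),
            "converged": bool(self.converged),
        }


def _result_from_lmfit(model_name: str, out: lmfit.minimizer.MinimizerResult,
                       pinned: tuple[str, ...] = ()) -> FitResult:
    params = {name: float(p.value) for name, p in out.params.items()}
    errors = {
        name: float(p.stderr) if p.stderr is not None else np.nan
        for name, p in out.params.items()
    }
    converged = bool(out.success) and out.errorbars
    if not out.success:
        log.warning("fit (%s) did not converge: %s", model_name, out.message)
    return FitResult(
        model=model_name,
        params=params,
        standard_errors=errors,
        chi2=float(out.chisqr),
        dof=int(out.nfree),
        converged=converged,
        covariance=getattr(out, "covar", None),
        extra={"pinned": pinned, "n_points": out.ndata},
    )


def _weights(points: list[VelocityPoint]) -> np.ndarray:
    sem = np.array([p.sem for p in points], dtype=float)
    if np.any(sem <= 0):
        # single-observation cells: unit weights so they still contribute
        sem = np.where(sem > 0, sem, np.nanmax(sem[sem > 0], initial=1.0))
    return 1.0 / sem


# --------------------------------------------------------------------------
# substrate-response fits
# --------------------------------------------------------------------------

def fit_mm_hill(points: list[VelocityPoint]) -> tuple[FitResult, FitResult]:
    """Fit an ATP titration at fixed force to Michaelis-Menten and Hill forms.

    Returns ``(mm_fit, hill_fit)``. The Hill fit reports the cooperativity
    coefficient ``n`` with its standard error; n consistent with 1 indicates
    strictly sequential single-site ATP binding.
    """
    atp_levels = {p.atp for p in points}
    if len(atp_levels) < 4:
        raise ValueError("need >= 4 distinct [ATP] values for an MM/Hill fit")
    atp = np.array([p.atp for p in points])
    v = np.array([p.velocity for p in points])
    w = _weights(points)
    vmax0, km0 = float(v.max()), float(np.median(atp))

    def resid_mm(pars):
        m = fv.MMParams(pars["vmax"].value, pars["km"].value)
        return (fv.v_mm(atp, m) - v) * w

    def resid_hill(pars):
        h = fv.HillParams(pars["vmax"].value, pars["khalf"].value, pars["n"].value)
        return (fv.v_hill(atp, h) - v) * w

    p_mm = lmfit.Parameters()
    p_mm.add("vmax", value=vmax0, min=1e-9)
    p_mm.add("km", value=km0, min=1e-9)
    mm = _result_from_lmfit("michaelis_menten", lmfit.minimize(resid_mm, p_mm))

    p_h = lmfit.Parameters()
    p_h.add("vmax", value=mm.params["vmax"], min=1e-9)
    p_h.add("khalf", value=max(mm.params["km"], 1e-6), min=1e-9)
    p_h.add("n", value=1.0, min=0.05, max=8.0)
    hill = _result_from_lmfit("hill", lmfit.minimize(resid_hill, p_h))

    # degenerate titration: velocity flat in [ATP] drives K_M to the boundary
    if mm.params["km"] < 1e-6 * km0:
        mm.converged = False
        mm.extra["boundary"] = "km -> 0 (velocity insensitive to [ATP])"
    return mm, hill


def fit_competitive_inhibition(
    point_sets: dict[float, list[VelocityPoint]],
) -> FitResult:
    """Global competitive-inhibition fit across ATP titrations at several [ADP].

    ``point_sets`` maps [ADP] (μM) to the titration measured at that ADP
    level. Vmax, K_M0 and K_i are shared across all sets. The result also
    carries the per-[ADP] apparent K_M values and the linear regression of
    K_M,app on [ADP] (slope = K_M0/K_i, intercept = K_M0).
    """
    adps = sorted(point_sets)
    if len(adps) < 3 or 0.0 not in point_sets:
        raise ValueError("need >= 3 distinct [ADP] levels including 0")
    if len(set(adps)) != len(adps):
        raise ValueError("[ADP] levels must be distinct")

    atp = np.concatenate([[p.atp for p in point_sets[a]] for a in adps])
    adp = np.concatenate([[a] * len(point_sets[a]) for a in adps])
    v = np.concatenate([[p.velocity for p in point_sets[a]] for a in adps])
    w = np.concatenate([_weights(point_sets[a]) for a in adps])

    def resid(pars):
        m = fv.InhibitionParams(pars["vmax"].value, pars["km0"].value, pars["ki"].value)
        return (fv.v_inhibited(atp, adp, m) - v) * w

    pars = lmfit.Parameters()
    pars.add("vmax", value=float(v.max()), min=1e-9)
    pars.add("km0", value=float(np.median(atp)), min=1e-9)
    pars.add("ki", value=100.0, min=1e-9)
    res = _result_from_lmfit("competitive_inhibition", lmfit.minimize(resid, pars))

    # per-[ADP] apparent K_M and its linear trend
    km_app = {}
    for a in adps:
        try:
            mm, _ = fit_mm_hill(point_sets[a])
            km_app[a] = mm.params["km"]
        except ValueError:
            continue
    if len(km_app) >= 2:
        A = np.vstack([np.ones(len(km_app)), np.array(list(km_app))]).T
        coef, *_ = np.linalg.lstsq(A, np.array(list(km_app.values())), rcond=None)
        res.extra["km_apparent"] = km_app
        res.extra["km_vs_adp_intercept"] = float(coef[0])
        res.extra["km_vs_adp_slope"] = float(coef[1])
    return res


# --------------------------------------------------------------------------
# force-velocity fits
# --------------------------------------------------------------------------

_FAMILY_DEFAULTS: dict[str, dict[str, float]] = {
    "single": {"vmax": 5000.0, "p": 0.9, "dx": 0.1},
    "linear": {},    # starts built per-dataset / multi-start
    "branched": {},
}


def _linear_start_grid() -> list[dict[str, float]]:
    """Deterministic multi-start grid for the linear family."""
    grid = []
    for kH0, kL0, beta in itertools.product(
        (3e4, 3e5, 3e6), (1e3, 1e4), (1.0, 4.0)
    ):
        grid.append(
            {"k0": 4e3, "alpha": 4.7, "kL0": kL0, "beta": beta,
             "dxL": 1.0, "kH0": kH0, "dxH": 0.4}
        )
    return grid


def _branched_start_grid() -> list[dict[str, float]]:
    grid = []
    for kA0, p0 in itertools.product((1e4, 1e5), (0.3, 0.7)):
        grid.append(
            {"k0": 4e3, "alpha": 4.7, "p0": p0, "dxC": 0.5,
             "kA0": kA0, "dxA": 1.0, "kB0": 3e5, "dxB": 0.4}
        )
    return grid


def fit_force_velocity(
    points: list[VelocityPoint],
    family: str,
    fixed: dict[str, float] | None = None,
    scale: ThermalScale = DEFAULT_SCALE,
) -> FitResult:
    """Weighted fit of a force-velocity dataset to one model family.

    Parameters
    ----------
    points : velocity measurements; [ATP] may vary between points.
    family : "single", "linear" or "branched".
    fixed : parameter pins, e.g. ``{"d": 2.0}`` to fix the step size.
    """
    fixed = dict(fixed or {})
    forces = np.array([p.force_bin_center for p in points])
    atp = np.array([p.atp for p in points])
    v = np.array([p.velocity for p in points])
    w = _weights(points)

    if np.unique(forces).size < 2:
        raise ValueError("rank-deficient design: need >= 2 distinct forces")

    if family == "single":
        n_free = 3 - len(fixed)
    elif family == "linear":
        n_free = 8 - len(fixed)
    elif family == "branched":
        n_free = 9 - len(fixed)
    else:
        raise ValueError(f"unknown model family {family!r}")
    if len(points) < n_free + 2:
        raise ValueError(
            f"need >= {n_free + 2} points to fit {family} with {n_free} free params"
        )

    if family == "single":
        def resid(pars):
            m = fv.SingleTransitionParams(
                pars["vmax"].value, pars["p"].value, pars["dx"].value)
            return (fv.v_single(forces, m, scale) - v) * w

        pars = lmfit.Parameters()
        start = {**_FAMILY_DEFAULTS["single"], "vmax": float(v.max()) * 1.2}
        start.update(fixed)
        pars.add("vmax", value=start["vmax"], min=1e-9, vary="vmax" not in fixed)
        pars.add("p", value=min(max(start["p"], 1e-3), 1.0), min=0.0, max=1.0,
                 vary="p" not in fixed)
        pars.add("dx", value=start["dx"], min=0.0, vary="dx" not in fixed)
        out = lmfit.minimize(resid, pars)
        return _result_from_lmfit("single", out, pinned=tuple(fixed))

    if family == "linear":
        param_names = ("d", "k0", "alpha", "kL0", "beta", "dxL", "kH0", "dxH")
        grid = _linear_start_grid()

        def resid(pars):
            m = fv.LinearModelParams(*(pars[n].value for n in param_names))
            return (fv.v_linear(forces, atp, m, scale) - v) * w

        builder = _build_linear_pars
    else:
        param_names = ("d", "k0", "alpha", "p0", "dxC", "kA0", "dxA", "kB0", "dxB")
        grid = _branched_start_grid()

        def resid(pars):
            m = fv.BranchedModelParams(*(pars[n].value for n in param_names))
            return (fv.v_branched(forces, atp, m, scale) - v) * w

        builder = _build_branched_pars

    best: lmfit.minimizer.MinimizerResult | None = None
    best_key = (np.inf, np.inf)
    for start in grid:
        pars = builder(start, fixed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                out = lmfit.minimize(resid, pars)
            except Exception:  # singular starts on extreme grids
                continue
        vec = np.array([p.value for p in out.params.values()])
        key = (out.chisqr, float(np.linalg.norm(vec)))
        if key < best_key:
            best, best_key = out, key
    if best is None:
        raise RuntimeError(f"all multi-start fits failed for family {family!r}")
    return _result_from_lmfit(family, best, pinned=tuple(fixed))


def _build_linear_pars(start: dict, fixed: dict) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    merged = {"d": 2.0, **start, **fixed}
    pars.add("d", value=merged["d"], min=1e-9, vary="d" not in fixed)
    for name in ("k0", "alpha", "kL0", "kH0"):
        pars.add(name, value=merged[name], min=1e-12, vary=name not in fixed)
    pars.add("beta", value=merged["beta"], min=0.0, vary="beta" not in fixed)
    for name in ("dxL", "dxH"):
        pars.add(name, value=merged[name], min=0.0, max=10.0,
                 vary=name not in fixed)
    return pars


def _build_branched_pars(start: dict, fixed: dict) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    merged = {"d": 2.0, **start, **fixed}
    pars.add("d", value=merged["d"], min=1e-9, vary="d" not in fixed)
    for name in ("k0", "alpha", "kA0", "kB0"):
        pars.add(name, value=merged[name], min=1e-12, vary=name not in fixed)
    pars.add("p0", value=merged["p0"], min=0.0, max=1.0, vary="p0" not in fixed)
    for name in ("dxC", "dxA", "dxB"):
        pars.add(name, value=merged[name], min=0.0, max=10.0,
                 vary=name not in fixed)
    return pars


# --------------------------------------------------------------------------
# derived quantities and model comparison
# --------------------------------------------------------------------------

def km_vmax_vs_force(
    points_by_force: dict[float, list[VelocityPoint]],
) -> pd.DataFrame:
    """Per-force-bin Michaelis-Menten parameters and the ratio V_max/K_M.

    Returns a table with one row per force bin: F, V_max ± SE, K_M ± SE,
    and V_max/K_M with its first-order propagated SE. Bins lacking an
    adequate ATP titration are skipped with a logged warning.
    """
    rows = []
    for force in sorted(points_by_force):
        pts = points_by_force[force]
        try:
            mm, _ = fit_mm_hill(pts)
        except ValueError as exc:
            log.warning("force bin %.1f pN skipped: %s", force, exc)
            continue
        vmax, km = mm.params["vmax"], mm.params["km"]
        se_v, se_k = mm.standard_errors["vmax"], mm.standard_errors["km"]
        ratio = vmax / km
        if mm.covariance is not None and np.all(np.isfinite([se_v, se_k])):
            cov_vk = mm.covariance[0, 1]
            se_ratio = abs(ratio) * np.sqrt(
                (se_v / vmax) ** 2 + (se_k / km) ** 2 - 2 * cov_vk / (vmax * km)
            )
        else:
            se_ratio = np.nan
        rows.append(
            {"force": force, "vmax": vmax, "vmax_se": se_v,
             "km": km, "km_se": se_k,
             "vmax_over_km": ratio, "vmax_over_km_se": se_ratio}
        )
    return pd.DataFrame(rows)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the *same* data by the Akaike score on chi².

    Rows are sorted best-first and carry chi², dof, AIC and ΔAIC relative
    to the best model.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_points = {f.extra.get("n_points") for f in fits}
    if len(n_points) != 1:
        raise ValueError("fits were not performed on identical data")
    df = pd.DataFrame(
        [{"model": f.model, "chi2": f.chi2, "dof": f.dof, "aic": f.aic}
         for f in fits]
    ).sort_values("aic", ignore_index=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["preferred"] = df.index == 0
    return df
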