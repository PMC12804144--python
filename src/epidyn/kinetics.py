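"""Biolayer-interferometry sensorgrams and 1:1 Langmuir kinetics.

A sensorgram records the optical-thickness response R(t) (nm) of a
sensor carrying an immobilised receptor while an analyte at
concentration C associates (0 <= t < t_a) and then dissociates in
analyte-free buffer (t >= t_a). Under the 1:1 Langmuir model with
association rate k_a (1/(M s)), dissociation rate k_d (1/s) and
saturation response R_max (nm)::

    association:   R(t) = R_eq * (1 - exp(-(k_a C + k_d) t)),
                   R_eq = R_max * C / (C + K_D),   K_D = k_d / k_a
    dissociation:  R(t) = R(t_a) * exp(-k_d (t - t_a))

The global fit shares (k_a, k_d, R_max) across all concentrations and
both phases, in log-parameterisation (positivity by construction), with
a multi-start grid around data-driven initial values. A fit is flagged
``poor_fit`` when it fails to converge or its overall R^2 falls below a
quality threshold (default 0.9) - affinities are not reported from poor
fits. Steady-state affinity is fitted separately from the equilibrium
plateau responses R_eq(C) = R_max C / (C + K_D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .errors import FitError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Sensorgram",
    "KineticParams",
    "GlobalFitResult",
    "model_response",
    "reference_subtract",
    "global_fit",
    "equilibrium_responses",
    "steady_state_fit",
    "sensorgrams_to_frame",
    "frame_to_sensorgrams",
]


@dataclass(frozen=True)
class Sensorgram:
    """One response trace at a single analyte concentration."""

    time: np.ndarray  # s, strictly increasing, spanning both phases
    response: np.ndarray  # nm
    concentration: float  # M
    t_assoc: float  # s; association on [0, t_assoc), dissociation after
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
        if self.time.shape != self.response.shape:
            raise InputError("time and response differ in length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise InputError("time must be strictly increasing")
        if self.concentration < 0:
            raise InputError("analyte concentration must be >= 0")
        if self.t_assoc <= 0:
            raise InputError("association window must have positive duration")

    @property
    def association_mask(self) -> np.ndarray:
        return self.time < self.t_assoc

    @property
    def dissociation_mask(self) -> np.ndarray:
        return ~self.association_mask


@dataclass(frozen=True)
class KineticParams:
    """1:1 binding rate constants and saturation response."""

    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float  # nm

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise InputError("ka, kd and rmax must all be positive")

    @property
    def kD(self) -> float:
        """Equilibrium dissociation constant K_D = k_d / k_a (M)."""
        return self.kd / self.ka


@dataclass(frozen=True)
class GlobalFitResult:
    """Outcome of a global 1:1 fit across concentrations."""

    params: KineticParams
    kD: float  # M
    per_curve_rss: dict[str, float]
    r_squared: float
    se: dict[str, float]  # standard errors: ka, kd, rmax, kD
    converged: bool
    poor_fit: bool
    r2_threshold: float
    n_points: int


def model_response(
    p: KineticParams, concentration: float, t: np.ndarray | float, t_assoc: float
) -> np.ndarray:
    """Noise-free 1:1 Langmuir response (nm) at time(s) ``t``."""
    if concentration < 0:
        raise InputError("analyte concentration must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time must be >= 0")
    if concentration == 0.0:
        return np.zeros_like(t)
    k_obs = p.ka * concentration + p.kd
    r_eq = p.rmax * concentration / (concentration + p.kD)
    assoc = r_eq * (1.0 - np.exp(-k_obs * np.minimum(t, t_assoc)))
    out = np.where(
        t < t_assoc,
        r_eq * (1.0 - np.exp(-k_obs * t)),
        assoc * np.exp(-p.kd * np.maximum(t - t_assoc, 0.0)),
    )
    return out


def reference_subtract(sample: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Pointwise subtraction of a reference trace on the same time grid."""
    if sample.time.shape != reference.time.shape or not np.allclose(
        sample.time, reference.time
    ):
        raise InputError("sample and reference time grids differ")
    return replace(sample, response=sample.response - reference.response)


def _kd_init(curve: Sensorgram) -> float:
    """k_d guess from a log-linear fit to the dissociation tail."""
    mask = curve.dissociation_mask
    t = curve.time[mask]
    r = curve.response[mask]
    keep = r > 1e-4
    if keep.sum() < 3:
        return 1e-2
    slope = np.polyfit(t[keep], np.log(r[keep]), 1)[0]
    return max(-slope, 1e-6)


def _ka_init(curves: list[Sensorgram], kd0: float) -> float:
    """k_a from the slope of observed association rate vs concentration."""
    k_obs, concs = [], []
    for c in curves:
        mask = c.association_mask
        t, r = c.time[mask], c.response[mask]
        r_inf = r[-1]
        if r_inf <= 1e-4:
            continue
        y = 1.0 - r / (r_inf * 1.02)  # slight headroom keeps the log defined
        keep = y > 1e-3
        if keep.sum() < 3:
            continue
        k_obs.append(-np.polyfit(t[keep], np.log(y[keep]), 1)[0])
        concs.append(c.concentration)
    if len(k_obs) < 2:
        return 1e3
    slope = np.polyfit(concs, k_obs, 1)[0]
    return max(slope, 1e-3)


def global_fit(
    curves: list[Sensorgram],
    r2_threshold: float = 0.9,
    multistart_factors: tuple[float, ...] = (0.1, 1.0, 10.0),
) -> GlobalFitResult:
    """Global least-squares 1:1 fit sharing (k_a, k_d, R_max).

    Parameters are optimised in log space (enforcing positivity) with a
    multi-start grid of ``multistart_factors`` around data-driven
    initial values for k_a and k_d. K_D = k_d/k_a is reported with a
    standard error propagated from the local quadratic approximation at
    the optimum.

    Raises
    ------
    FitError
        If fewer than two distinct concentrations are supplied, or a
        curve lacks one of the phases.
    """
    concs = sorted({c.concentration for c in curves if c.concentration > 0})
    if len(concs) < 2:
        raise FitError("global fit needs >= 2 distinct analyte concentrations")
    fit_curves = sorted(
        (c for c in curves if c.concentration > 0),
        key=lambda c: (-c.concentration, c.label),
    )
    for c in fit_curves:
        if not c.association_mask.any() or not c.dissociation_mask.any():
            raise FitError(f"curve {c.label!r} lacks an association or dissociation phase")

    kd0 = _kd_init(fit_curves[0])
    ka0 = _ka_init(fit_curves, kd0)
    rmax0 = max(max(c.response.max() for c in fit_curves), 1e-3) * 1.1

    all_resp = np.concatenate([c.response for c in fit_curves])

    def residuals(logp: np.ndarray) -> np.ndarray:
        p = KineticParams(*np.exp(logp))
        # evaluated on time since curve start, so a uniform time offset
        # applied consistently to all curves leaves the fit unchanged
        return np.concatenate(
            [
                model_response(
                    p, c.concentration, c.time - c.time[0], c.t_assoc - c.time[0]
                )
                - c.response
                for c in fit_curves
            ]
        )

    best = None
    for fa in multistart_factors:
        for fd in multistart_factors:
            x0 = np.log([ka0 * fa, kd0 * fd, rmax0])
            try:
                res = least_squares(residuals, x0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise FitError("all optimisation starts failed")

    params = KineticParams(*np.exp(best.x))
    converged = bool(best.success)
    resid = best.fun
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((all_resp - all_resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    per_curve: dict[str, float] = {}
    offset = 0
    for c in fit_curves:
        n = c.time.size
        per_curve[c.label or f"{c.concentration:.3g} M"] = float(
            resid[offset : offset + n] @ resid[offset : offset + n]
        )
        offset += n

    se = _standard_errors(best, params)
    poor = (not converged) or not (np.isfinite(r2) and r2 >= r2_threshold)
    if poor:
        logger.warning("poor global fit: converged=%s R2=%.4f", converged, r2)
    return GlobalFitResult(
        params=params,
        kD=params.kD,
        per_curve_rss=per_curve,
        r_squared=r2,
        se=se,
        converged=converged,
        poor_fit=poor,
        r2_threshold=r2_threshold,
        n_points=all_resp.size,
    )


def _standard_errors(res, params: KineticParams) -> dict[str, float]:
    # Covariance of log-parameters from the Gauss-Newton approximation.
    n, k = res.fun.size, res.x.size
    if n <= k:
        return {key: float("nan") for key in ("ka", "kd", "rmax", "kD")}
    s2 = 2.0 * res.cost / (n - k)
    try:
        cov_log = s2 * np.linalg.inv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return {key: float("nan") for key in ("ka", "kd", "rmax", "kD")}
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    # delta method: se(x) = x * se(log x); log KD = log kd - log ka
    var_log_kd_over_ka = cov_log[1, 1] + cov_log[0, 0] - 2.0 * cov_log[0, 1]
    return {
        "ka": params.ka * se_log[0],
        "kd": params.kd * se_log[1],
        "rmax": params.rmax * se_log[2],
        "kD": params.kD * float(np.sqrt(max(var_log_kd_over_ka, 0.0))),
    }


def equilibrium_responses(
    curves: list[Sensorgram], tail_fraction: float = 0.1
) -> list[tuple[float, float]]:
    """(C, R_eq) points; R_eq is the mean response over the final
    ``tail_fraction`` of each association window."""
    points = []
    for c in curves:
        if c.concentration <= 0:
            continue
        mask = c.association_mask & (c.time >= (1.0 - tail_fraction) * c.t_assoc)
        if not mask.any():
            raise InputError(f"curve {c.label!r} has no samples in the plateau window")
        points.append((c.concentration, float(c.response[mask].mean())))
    return points


def steady_state_fit(points: list[tuple[float, float]]) -> tuple[float, float]:
    """Fit R_eq = R_max C / (C + K_D); returns (K_D in M, R_max in nm)."""
    if len({c for c, _ in points}) < 3:
        raise FitError("steady-state fit needs >= 3 distinct concentrations")
    conc = np.array([c for c, _ in points])
    req = np.array([r for _, r in points])
    if np.allclose(req, req[0]):
        raise FitError("degenerate steady-state data: all responses equal")

    def hyperbola(c, kD, rmax):
        return rmax * c / (c + kD)

    p0 = (np.median(conc), req.max() * 1.2)
    popt, _ = curve_fit(hyperbola, conc, req, p0=p0, maxfev=10000)
    kD, rmax = float(popt[0]), float(popt[1])
    if kD <= 0 or rmax <= 0:
        raise FitError("steady-state fit returned non-physical parameters")
    return kD, rmax


_CSV_COLUMNS = ["time_s", "response_nm", "conc_M", "phase", "curve_id"]


def sensorgrams_to_frame(curves: list[Sensorgram]) -> pd.DataFrame:
    """Tidy long-form table (time_s, response_nm, conc_M, phase, curve_id)."""
    rows = []
    for c in curves:
        phase = np.where(c.association_mask, "assoc", "dissoc")
        rows.append(
            pd.DataFrame(
                {
                    "time_s": c.time,
                    "response_nm": c.response,
                    "conc_M": c.concentration,
                    "phase": phase,
                    "curve_id": c.label or f"{c.concentration:.3g}M",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[_CSV_COLUMNS]


def frame_to_sensorgrams(df: pd.DataFrame) -> list[Sensorgram]:
    """Inverse of :func:`sensorgrams_to_frame`."""
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"sensorgram table lacks column(s): {sorted(missing)}")
    curves = []
    for label, g in df.groupby("curve_id", sort=False):
        g = g.sort_values("time_s")
        assoc = g[g["phase"] == "assoc"]
        t_assoc = (
            float(g[g["phase"] == "dissoc"]["time_s"].min())
            if (g["phase"] == "dissoc").any()
            else float(assoc["time_s"].max()) + 1e-9
        )
        curves.append(
            Sensorgram(
                time=g["time_s"].to_numpy(),
                response=g["response_nm"].to_numpy(),
                concentration=float(g["conc_M"].iloc[0]),
                t_assoc=t_assoc,
                label=str(label),
            )
        )
    return curves
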