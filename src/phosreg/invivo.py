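"""Xenograft efficacy and pharmacodynamics statistics.

Tumor volume from caliper diameters, tumor growth inhibition (TGI) against the
vehicle group, two-sided Dunnett many-to-one comparisons computed by numerical
integration of the multivariate-t acceptance region, a linear dose-trend test,
and target-inhibition readouts from flow-cytometry MFI with a viability
exclusion rule.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.optimize import brentq

__all__ = [
    "tumor_volume",
    "tgi",
    "dunnett",
    "dunnett_critical_value",
    "max_abs_t_cdf",
    "dose_trend",
    "pd_inhibition",
]


def tumor_volume(L: float | np.ndarray, W: float | np.ndarray) -> float | np.ndarray:
    """Ellipsoid-approximation volume ``V = L * W**2 / 2`` (mm^3).

    ``L`` is the long and ``W`` the short diameter; swapped inputs are
    auto-ordered with a warning.
    """
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0) or np.any(L <= 0):
        raise ValueError("diameters must be positive")
    if np.any(W > L):
        warnings.warn("short diameter exceeds long diameter; auto-ordering", stacklevel=2)
        L, W = np.maximum(L, W), np.minimum(L, W)
    v = L * W**2 / 2.0
    return float(v) if v.ndim == 0 else v


def tgi(treated: np.ndarray, vehicle: np.ndarray) -> float:
    """Tumor growth inhibition: ``(1 - mean(V_treated)/mean(V_vehicle)) * 100``."""
    treated = np.asarray(treated, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    mv = vehicle.mean()
    if mv == 0:
        raise ValueError("vehicle mean volume is zero")
    return (1.0 - treated.mean() / mv) * 100.0


def max_abs_t_cdf(q: float, lambdas: np.ndarray, df: int, n_hermite: int = 80) -> float:
    """``P(max_j |T_j| <= q)`` for equicoordinate many-to-one t statistics.

    The statistics share the control-group mean: ``T_j = Z_j / S`` with
    ``Z_j = lambda_j * Z0 + sqrt(1 - lambda_j^2) * X_j`` for independent
    standard normals and ``S^2 ~ chi2_df / df``; ``lambda_j^2 = n_j/(n_j+n_0)``.
    Conditioning on ``Z0`` (Gauss-Hermite nodes) and integrating the chi
    density of ``S`` by adaptive quadrature gives a deterministic probability
    to ~1e-6.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_hermite)
    wnorm = weights / math.sqrt(2.0 * math.pi)
    root1m = np.sqrt(1.0 - lambdas**2)

    def inner(s: float) -> float:
        hi = (q * s - np.outer(nodes, lambdas)) / root1m
        lo = (-q * s - np.outer(nodes, lambdas)) / root1m
        probs = np.prod(stats.norm.cdf(hi) - stats.norm.cdf(lo), axis=1)
        return float(np.dot(wnorm, probs))

    # density of S where S = sqrt(chi2_df / df)
    log_c = (df / 2.0) * math.log(df / 2.0) - math.lgamma(df / 2.0) + math.log(2.0)

    def integrand(s: float) -> float:
        log_dens = log_c + (df - 1.0) * math.log(s) - df * s * s / 2.0
        return math.exp(log_dens) * inner(s)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-8, epsrel=1e-8, limit=200)
    return min(max(val, 0.0), 1.0)


def _group_arrays(groups: dict[str, np.ndarray], control: str):
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    treated_names = [g for g in groups if g != control]
    if not treated_names:
        raise ValueError("need at least one non-control group")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return arrays, treated_names


def dunnett(groups: dict[str, np.ndarray], control: str) -> pd.Series:
    """Two-sided Dunnett-adjusted p-values for each group versus the control.

    Uses the pooled equal-variance error term; the adjusted p-value of group j
    is ``1 - P(max_i |T_i| <= |t_j|)`` under the joint multivariate-t null
    with plug-in correlations from the group sizes (equicorrelation 0.5 in the
    balanced case).
    """
    arrays, treated_names = _group_arrays(groups, control)
    n0 = arrays[control].size
    k = len(treated_names)
    n_total = sum(v.size for v in arrays.values())
    df = n_total - (k + 1)
    pooled_var = (
        sum((v.size - 1) * v.var(ddof=1) for v in arrays.values()) / df
    )
    m0 = arrays[control].mean()
    tstats, lambdas = [], []
    for g in treated_names:
        v = arrays[g]
        se = math.sqrt(pooled_var * (1.0 / v.size + 1.0 / n0))
        tstats.append((v.mean() - m0) / se)
        lambdas.append(math.sqrt(v.size / (v.size + n0)))
    lambdas = np.asarray(lambdas)
    pvals = [1.0 - max_abs_t_cdf(abs(t), lambdas, df) for t in tstats]
    return pd.Series(pvals, index=treated_names, name="p_adjusted")


def dunnett_critical_value(
    n_treated_groups: int,
    df: int,
    alpha: float = 0.05,
    lambdas: np.ndarray | None = None,
) -> float:
    """Two-sided critical value q with ``P(max |T_j| > q) = alpha``."""
    if lambdas is None:
        lambdas = np.full(n_treated_groups, math.sqrt(0.5))
    return brentq(
        lambda q: max_abs_t_cdf(q, lambdas, df) - (1.0 - alpha), 0.5, 20.0, xtol=1e-6
    )


def dose_trend(volumes: np.ndarray, doses: np.ndarray) -> tuple[float, float]:
    """OLS of final-day tumor volume on dose over the treated groups.

    Returns (slope, two-sided p-value of the slope).
    """
    doses = np.asarray(doses, dtype=float)
    if np.unique(doses).size < 2:
        raise ValueError("need >= 2 dose levels")
    res = stats.linregress(doses, np.asarray(volumes, dtype=float))
    return float(res.slope), float(res.pvalue)


def pd_inhibition(
    records: pd.DataFrame, control_group, dead_cutoff: float = 30.0
) -> pd.Series:
    """Target-inhibition percent per group from stimulated-minus-unstimulated MFI.

    Records with a dead-cell (7-AAD-positive) percentage strictly above
    ``dead_cutoff`` are excluded. The per-animal signal is
    ``MFI_stimulated - MFI_unstimulated``; group inhibition is
    ``(1 - mean signal / mean control signal) * 100``.
    """
    keep = records[records["dead_pct"] <= dead_cutoff]
    if control_group not in set(keep["group"]):
        raise ValueError("all control records excluded or control group absent")
    signal = keep["mfi_stimulated"] - keep["mfi_unstimulated"]
    mean_sig = signal.groupby(keep["group"]).mean()
    ctrl = mean_sig[control_group]
    if ctrl == 0:
        raise ValueError("control group mean signal is zero")
    return ((1.0 - mean_sig / ctrl) * 100.0).rename("inhibition_pct")
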