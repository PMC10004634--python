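"""Kinase-panel and cellular pharmacology arithmetic.

Covers the biochemical inhibition formula, logistic IC50 fitting (4PL, 2PL and
sigmoid-Emax variants on log10 concentration), censored fold-selectivity
relative to a reference kinase, competition-binding hit calling at a percent
inhibition cutoff, and the multi-criteria annotation rule for cell-system
biomarker profiles.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .simulate import logistic4

__all__ = [
    "PlateControls",
    "LogisticFit",
    "SelectivityEntry",
    "BiomapReadout",
    "percent_inhibition",
    "fit_logistic",
    "selectivity_ratio",
    "kinome_hits",
    "biomap_annotate",
]


@dataclass(frozen=True)
class PlateControls:
    """Raw plate signals: compound well A, no-enzyme background B, vehicle C."""

    A: float
    B: float
    C: float


def percent_inhibition(controls: PlateControls) -> float:
    """``[1 - (A - B) / (C - B)] * 100``; may fall outside [0, 100]."""
    if controls.C == controls.B:
        raise ValueError("undefined: vehicle response equals background (C == B)")
    return (1.0 - (controls.A - controls.B) / (controls.C - controls.B)) * 100.0


@dataclass(frozen=True)
class LogisticFit:
    model: str
    ic50_nM: float
    hill: float
    top: float
    bottom: float
    ci95: tuple[float, float] | None
    converged: bool
    extrapolated: bool
    rss: float


def _model_funcs(model: str):
    if model == "4PL":
        def f(c, log_ic50, hill, top, bottom):
            return logistic4(c, 10.0**log_ic50, hill, top, bottom)
        names = ("log_ic50", "hill", "top", "bottom")
    elif model == "2PL":
        # inhibition constrained to run 0 -> 100
        def f(c, log_ic50, hill):
            return logistic4(c, 10.0**log_ic50, hill, 100.0, 0.0)
        names = ("log_ic50", "hill")
    elif model == "sigmoid_Emax":
        def f(c, log_ic50, hill, emax):
            return logistic4(c, 10.0**log_ic50, hill, emax, 0.0)
        names = ("log_ic50", "hill", "emax")
    else:
        raise ValueError(f"unknown model {model!r}")
    return f, names


def fit_logistic(
    data: pd.DataFrame,
    model: str = "4PL",
    ci: bool = True,
) -> LogisticFit:
    """Least-squares logistic fit of response on log10 concentration.

    ``data`` needs ``concentration_nM`` and ``response`` columns. Vehicle rows
    (concentration 0) are retained and anchor the zero-dose asymptote, which is
    how a vehicle point plotted at "-infinity" enters the regression. The 95%
    CI of the IC50 is a t-interval on log10(IC50) from the fit covariance,
    back-transformed. A fit with a non-positive Hill slope (response falling
    with concentration where inhibition should rise) is flagged unconverged.
    """
    conc = data["concentration_nM"].to_numpy(dtype=float)
    resp = data["response"].to_numpy(dtype=float)
    func, names = _model_funcs(model)
    n_params = len(names)
    if len(np.unique(conc)) < n_params:
        raise ValueError(
            f"{model} needs >= {n_params} distinct concentrations, got {len(np.unique(conc))}"
        )

    pos = conc[conc > 0]
    log_mid = float(np.median(np.log10(pos)))
    p0 = {
        "4PL": [log_mid, 1.0, resp.max(), resp.min()],
        "2PL": [log_mid, 1.0],
        "sigmoid_Emax": [log_mid, 1.0, max(resp.max(), 1e-6)],
    }[model]

    try:
        popt, pcov = curve_fit(func, conc, resp, p0=p0, maxfev=50000)
        ok = np.all(np.isfinite(popt))
    except RuntimeError:
        popt = np.full(n_params, np.nan)
        pcov = np.full((n_params, n_params), np.nan)
        ok = False

    params = dict(zip(names, popt))
    ic50 = 10.0 ** params["log_ic50"] if ok else math.nan
    hill = params.get("hill", math.nan)
    top = params.get("top", params.get("emax", 100.0))
    bottom = params.get("bottom", 0.0)
    # an inhibition readout must rise with concentration: positive hill and,
    # for the full model, top above bottom (the symmetric re-parameterization
    # with swapped asymptotes is the wrong-sign fit)
    rises = hill > 0 and (model != "4PL" or top > bottom) and (
        model != "sigmoid_Emax" or top > 0
    )
    converged = bool(ok and np.isfinite(ic50) and rises)

    rss = float(np.sum((resp - func(conc, *popt)) ** 2)) if ok else math.nan
    ci95 = None
    if ci and converged:
        dof = max(len(resp) - n_params, 1)
        se = math.sqrt(max(pcov[0, 0], 0.0))
        tq = stats.t.ppf(0.975, dof)
        ci95 = (10.0 ** (params["log_ic50"] - tq * se), 10.0 ** (params["log_ic50"] + tq * se))

    extrapolated = bool(converged and not (pos.min() <= ic50 <= pos.max()))
    return LogisticFit(
        model=model,
        ic50_nM=float(ic50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        ci95=ci95,
        converged=converged,
        extrapolated=extrapolated,
        rss=rss,
    )


@dataclass(frozen=True)
class SelectivityEntry:
    kinase: str
    ic50: str  # as printed, possibly ">x"
    fold: str  # formatted fold-selectivity, possibly censored
    fold_raw: float  # uncensored numeric ratio (lower bound when censored)
    censored: bool


_CENSOR_RE = re.compile(r"^\s*>\s*(\S+)\s*$")


def _round_fold(value: float) -> str:
    """Panel formatting: >= 1 rounds half-up to an integer, < 1 to one decimal."""
    if value >= 1:
        return str(int(Decimal(repr(value)).quantize(Decimal("1"), ROUND_HALF_UP)))
    return str(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def selectivity_ratio(ic50_kinase: str | float, ic50_ref: float, kinase: str = "") -> SelectivityEntry:
    """Fold-selectivity ``IC50(kinase) / IC50(reference)`` with censoring algebra.

    A right-censored potency ``">x"`` divided by a positive uncensored
    reference yields the censored fold ``">round(x/ref)"``. The raw float
    ratio is always retained alongside the formatted string.
    """
    if not (isinstance(ic50_ref, (int, float)) and ic50_ref > 0):
        raise ValueError("reference IC50 must be a positive uncensored number")
    censored = False
    if isinstance(ic50_kinase, str):
        m = _CENSOR_RE.match(ic50_kinase)
        if m:
            censored = True
            value = float(m.group(1))
        else:
            value = float(ic50_kinase)
    else:
        value = float(ic50_kinase)
    if value <= 0:
        raise ValueError("kinase IC50 must be positive")
    ratio = value / ic50_ref
    fold = _round_fold(ratio)
    return SelectivityEntry(
        kinase=kinase,
        ic50=str(ic50_kinase),
        fold=f">{fold}" if censored else fold,
        fold_raw=ratio,
        censored=censored,
    )


def kinome_hits(
    records: pd.DataFrame, inhibition_cutoff: float = 65.0
) -> pd.DataFrame:
    """Kinases inhibited strictly beyond the cutoff in a competition-binding panel.

    ``records`` needs ``kinase`` and ``pct_ctrl`` columns; percent inhibition is
    ``100 - pct_ctrl``. The result is sorted by descending inhibition with the
    kinase name as tie-break, so it is invariant to input order.
    """
    out = records[["kinase"]].copy()
    out["inhibition_pct"] = 100.0 - records["pct_ctrl"].to_numpy(dtype=float)
    hits = out[out["inhibition_pct"] > inhibition_cutoff]
    return hits.sort_values(
        ["inhibition_pct", "kinase"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class BiomapReadout:
    """One biomarker profile: log10 treated/vehicle ratios by ascending concentration."""

    system: str
    biomarker: str
    log10_ratios: tuple[float, ...]
    outside_envelope: tuple[bool, ...]
    antiproliferative: bool = False


def biomap_annotate(readout: BiomapReadout, effect_size: float = 0.1) -> bool:
    """Annotation rule for biomarker activity.

    Annotated when two or more *consecutive* concentrations change in the same
    direction, lie outside their significance envelope, and at least one of
    them exceeds the effect size (|log10 ratio| > ``effect_size``).
    Antiproliferative readouts require a single qualifying point.
    """
    r = np.asarray(readout.log10_ratios, dtype=float)
    outside = np.asarray(readout.outside_envelope, dtype=bool)
    if r.size != outside.size:
        raise ValueError("ratio and envelope vectors must align")
    if readout.antiproliferative:
        return bool(np.any(outside & (np.abs(r) > effect_size)))
    if r.size < 2:
        raise ValueError("need readouts at >= 2 concentrations")
    for i in range(r.size - 1):
        a, b = r[i], r[i + 1]
        if outside[i] and outside[i + 1] and a * b > 0:
            if max(abs(a), abs(b)) > effect_size:
                return True
    return False
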