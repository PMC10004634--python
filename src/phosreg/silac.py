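"""Empirical-null regulation calling for label-swapped SILAC phosphoproteomics.

The central computation of the package: given class-I phosphosites quantified in
two SILAC replicates with inverted labeling, fit a Gaussian to the histogram of
log2-transformed ratios, derive symmetric significance thresholds at ``mu +/- k*sigma``
(k = 2.5 by default), and call a site regulated only when *both* replicate ratios
fall beyond the same threshold.

Phosphosite tables are plain :class:`pandas.DataFrame` objects with the columns

``protein, gene, position, residue, sequence_window, localization_prob,
ratio_rep1, ratio_rep2_raw`` (and ``ratio_rep2`` once harmonized).

Ratios are treatment/control on the linear scale; replicate 2 may be stored as
the raw heavy/light ratio of a label-swapped experiment, in which case
:func:`harmonize_label_swap` inverts it onto the treatment/control scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GaussianNull",
    "ThresholdSet",
    "RegulationSummary",
    "SITE_COLUMNS",
    "filter_class1",
    "harmonize_label_swap",
    "fit_gaussian_null",
    "derive_thresholds",
    "call_regulation",
    "summarize_regulation",
    "residue_composition",
    "overlap_regulated",
]

#: canonical column order of a phosphosite table
SITE_COLUMNS = [
    "protein",
    "gene",
    "position",
    "residue",
    "sequence_window",
    "localization_prob",
    "ratio_rep1",
    "ratio_rep2_raw",
]


@dataclass(frozen=True)
class GaussianNull:
    """Gaussian fitted by least squares to the histogram of log2 ratios."""

    mu_log2: float
    sigma_log2: float
    mode: str  # "pooled_single_ratios" or "ratio_of_ratios"
    n_bins: int
    fit_rss: float
    amplitude: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_log2) or self.sigma_log2 <= 0:
            raise ValueError(f"sigma_log2 must be positive, got {self.sigma_log2}")


@dataclass(frozen=True)
class ThresholdSet:
    """Linear-scale ratio cutoffs derived from a Gaussian null.

    ``up_thr = 2**(mu + k*sigma)``, ``down_thr = 2**(mu - k*sigma)``; for a
    centered null (mu = 0) the two are exact reciprocals.
    """

    k: float
    up_thr: float
    down_thr: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.down_thr <= 0 or self.down_thr > self.up_thr:
            raise ValueError("need 0 < down_thr <= up_thr")


@dataclass(frozen=True)
class RegulationSummary:
    n_down_sites: int
    n_down_proteins: int
    n_up_sites: int
    n_up_proteins: int
    pct_down: float
    pct_up: float
    sty_pct: tuple[float, float, float] | None = None


def filter_class1(records: pd.DataFrame, min_prob: float = 0.75) -> pd.DataFrame:
    """Keep class-I sites: S/T/Y residues localized with probability >= ``min_prob``.

    The probability boundary is inclusive; row order is preserved.
    """
    keep = records["residue"].isin(["S", "T", "Y"]) & (
        records["localization_prob"] >= min_prob
    )
    return records.loc[keep].copy()


def harmonize_label_swap(records: pd.DataFrame, rep2_swapped: bool = True) -> pd.DataFrame:
    """Put both replicate ratios on the treatment/control scale.

    When the second replicate used an inverted labeling scheme its raw
    heavy/light ratio is the control/treatment ratio, so the effective
    treatment/control ratio is its reciprocal. The harmonized value is stored
    in a new ``ratio_rep2`` column which doubles as the state flag: calling
    this function on an already-harmonized table is a no-op.
    """
    if "ratio_rep2" in records.columns:
        return records.copy()
    raw = records["ratio_rep2_raw"]
    bad = raw.notna() & (raw <= 0)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} non-positive raw rep2 ratio(s)")
    out = records.copy()
    out["ratio_rep2"] = 1.0 / raw if rep2_swapped else raw.astype(float)
    return out


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_null(
    records: pd.DataFrame,
    mode: str = "pooled_single_ratios",
    n_bins: int | str = "auto",
) -> GaussianNull:
    """Fit a Gaussian to the histogram of log2 ratios by least squares.

    Parameters
    ----------
    records
        Harmonized phosphosite table (``ratio_rep1`` and ``ratio_rep2`` present).
    mode
        ``"pooled_single_ratios"`` (default) pools log2 of all single-replicate
        treatment/control ratios; the fitted sigma is then on the scale on which
        the thresholds are applied. ``"ratio_of_ratios"`` fits log2(rep1/rep2)
        per site, whose spread reflects only between-replicate disagreement.
    n_bins
        Number of histogram bins, or ``"auto"`` for Freedman-Diaconis binning.

    The fit is unweighted least squares of a three-parameter Gaussian
    (amplitude, mu, sigma) on bin counts versus bin centers.
    """
    if mode not in ("pooled_single_ratios", "ratio_of_ratios"):
        raise ValueError(f"unknown mode {mode!r}")
    r1 = records["ratio_rep1"].to_numpy(dtype=float)
    r2 = records["ratio_rep2"].to_numpy(dtype=float)
    both = np.isfinite(r1) & np.isfinite(r2)
    if both.sum() < 100:
        raise ValueError("need >= 100 sites quantified in both replicates")
    if mode == "ratio_of_ratios":
        sample = np.log2(r1[both] / r2[both])
    else:
        sample = np.log2(np.concatenate([r1[both], r2[both]]))
    if np.ptp(sample) == 0:
        raise ValueError("degenerate sample: all ratios identical")

    if n_bins == "auto":
        edges = np.histogram_bin_edges(sample, bins="fd")
    else:
        edges = np.histogram_bin_edges(sample, bins=int(n_bins))
    counts, edges = np.histogram(sample, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    p0 = (float(counts.max()), float(np.median(sample)), float(np.std(sample)))
    try:
        popt, _ = curve_fit(_gauss, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological histograms
        raise ValueError(f"Gaussian fit did not converge: {exc}") from exc
    amp, mu, sigma = popt
    sigma = abs(float(sigma))
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError("Gaussian fit returned degenerate sigma")
    rss = float(np.sum((counts - _gauss(centers, *popt)) ** 2))
    return GaussianNull(
        mu_log2=float(mu),
        sigma_log2=sigma,
        mode=mode,
        n_bins=len(counts),
        fit_rss=rss,
        amplitude=float(amp),
    )


def derive_thresholds(null: GaussianNull, k: float = 2.5) -> ThresholdSet:
    """Linear ratio cutoffs at ``mu +/- k*sigma`` on the log2 scale."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    up = 2.0 ** (null.mu_log2 + k * null.sigma_log2)
    down = 2.0 ** (null.mu_log2 - k * null.sigma_log2)
    return ThresholdSet(k=k, up_thr=up, down_thr=down)


def call_regulation(records: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Direction calls under the dual-replicate consistency rule.

    ``down`` iff both replicate ratios are strictly below ``down_thr``; ``up``
    iff both are strictly above ``up_thr``; everything else — discordant
    directions, a single exceedance, or a missing replicate — is ``unchanged``.
    """
    r1 = records["ratio_rep1"].to_numpy(dtype=float)
    r2 = records["ratio_rep2"].to_numpy(dtype=float)
    present = np.isfinite(r1) & np.isfinite(r2)
    down = present & (r1 < thresholds.down_thr) & (r2 < thresholds.down_thr)
    up = present & (r1 > thresholds.up_thr) & (r2 > thresholds.up_thr)
    direction = np.where(down, "down", np.where(up, "up", "unchanged"))
    out = records[["gene", "position", "residue"]].copy()
    out["direction"] = direction
    out["ratio_rep1"] = r1
    out["ratio_rep2"] = r2
    if "protein" in records.columns:
        out["protein"] = records["protein"].to_numpy()
    return out


def summarize_regulation(calls: pd.DataFrame, n_quantified: int) -> RegulationSummary:
    """Site/protein counts by direction and percentages of all quantified sites.

    Protein distinctness is keyed on the gene symbol, falling back to the
    protein name where the gene is missing. Percentages are rounded to one
    decimal place.
    """
    if n_quantified <= 0:
        raise ValueError("n_quantified must be positive")
    key = calls["gene"].astype("string")
    if "protein" in calls.columns:
        key = key.fillna(calls["protein"].astype("string"))
    down = calls["direction"] == "down"
    up = calls["direction"] == "up"
    n_down = int(down.sum())
    n_up = int(up.sum())
    return RegulationSummary(
        n_down_sites=n_down,
        n_down_proteins=int(key[down].nunique()),
        n_up_sites=n_up,
        n_up_proteins=int(key[up].nunique()),
        pct_down=round(100.0 * n_down / n_quantified, 1),
        pct_up=round(100.0 * n_up / n_quantified, 1),
    )


def residue_composition(records: pd.DataFrame) -> tuple[float, float, float]:
    """Percent of phospho-Ser, -Thr and -Tyr among the sites, one-decimal rounding."""
    if len(records) == 0:
        raise ValueError("empty input")
    res = records["residue"]
    n = len(res)
    return tuple(round(100.0 * (res == aa).sum() / n, 1) for aa in ("S", "T", "Y"))


def overlap_regulated(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, direction: str
) -> list[tuple]:
    """Site keys (gene, position, residue) regulated in ``direction`` in both call sets."""
    def keys(calls: pd.DataFrame) -> set[tuple]:
        sel = calls[calls["direction"] == direction]
        return set(zip(sel["gene"], sel["position"], sel["residue"]))

    return sorted(keys(calls_a) & keys(calls_b), key=lambda t: (str(t[0]), t[1], t[2]))
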