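"""Synthetic inputs with the statistical structure the analysis pipeline assumes.

Every generator is seed-deterministic (``numpy.random.default_rng``) and returns
plain pandas objects in the same dialects the readers in :mod:`phosreg.io`
consume, so each pipeline stage can be exercised end to end without external
data.

The SILAC generator emulates a two-replicate label-swap design: every site has
a shared true log2 effect (0 for null sites, ``+/- effect_log2`` for regulated
ones, plus a biological per-site component) observed in each replicate with
independent technical noise. The per-replicate marginal spread of null-site
log2 ratios equals ``null_sigma_log2``, so a Gaussian fitted to the pooled
histogram recovers the generating sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .silac import SITE_COLUMNS

__all__ = [
    "SilacSimConfig",
    "SimTruth",
    "gen_silac_dataset",
    "gen_dose_response",
    "gen_expression",
    "gen_growth_curves",
]


@dataclass(frozen=True)
class SilacSimConfig:
    """Parameters of the synthetic SILAC phosphosite experiment.

    ``null_sigma_log2`` is the marginal standard deviation of null-site log2
    ratios per replicate (default 0.223, the value implied by ratio thresholds
    of 1.472 / 0.679 at 2.5 sigma). ``replicate_noise_log2`` is the technical
    scatter of each replicate around the shared per-site value; the remaining
    null variance is a shared biological component, which is what makes the
    two replicates correlated. ``sty_props`` are the Ser/Thr/Tyr proportions
    of a deep phosphoproteome (default 84.6 / 14.4 / 1.0 %).
    """

    n_sites: int = 10000
    frac_regulated: float = 0.0
    prob_up: float = 0.5  # fraction of regulated sites that are upregulated
    effect_log2: float = 1.0
    null_sigma_log2: float = 0.223
    replicate_noise_log2: float = 0.1
    sty_props: tuple[float, float, float] = (0.846, 0.144, 0.010)
    sites_per_protein: float = 1.9  # mean multiplicity, matching deep phosphoproteomes
    loc_prob_below: float = 0.15  # mass of localization probabilities < 0.75
    label_swap_rep2: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0 <= self.frac_regulated < 1):
            raise ValueError("frac_regulated must be in [0, 1)")
        if not (0 <= self.prob_up <= 1):
            raise ValueError("prob_up must be in [0, 1]")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        if self.null_sigma_log2 <= 0:
            raise ValueError("null_sigma_log2 must be positive")
        if self.replicate_noise_log2 < 0:
            raise ValueError("replicate_noise_log2 must be nonnegative")
        if abs(sum(self.sty_props) - 1.0) > 1e-9:
            raise ValueError("sty_props must sum to 1")
        if self.sites_per_protein < 1:
            raise ValueError("sites_per_protein must be >= 1")
        if self.replicate_noise_log2 > self.null_sigma_log2:
            raise ValueError(
                "replicate_noise_log2 cannot exceed null_sigma_log2 "
                "(the technical part of the null variance)"
            )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a generated SILAC dataset."""

    label: np.ndarray  # "up" / "down" / "null" per site
    true_effect_log2: np.ndarray = field(repr=False)


def gen_silac_dataset(config: SilacSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a label-swapped two-replicate SILAC phosphosite table.

    Returns the site table (``ratio_rep2_raw`` stored as the as-measured
    heavy/light ratio, i.e. inverted when ``label_swap_rep2``) and the
    ground-truth labels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    regulated = rng.random(n) < config.frac_regulated
    sign = np.where(rng.random(n) < config.prob_up, 1.0, -1.0)
    true_effect = np.where(regulated, sign * config.effect_log2, 0.0)
    label = np.where(true_effect > 0, "up", np.where(true_effect < 0, "down", "null"))

    # Null sites carry a shared per-site biological component sized so their
    # marginal per-replicate sd equals null_sigma_log2; regulated sites sit
    # exactly at their planted effect (the SimTruth value) plus technical
    # replicate noise only. The shared component is what correlates the two
    # label-swapped replicates.
    shared_sd = math.sqrt(
        max(config.null_sigma_log2**2 - config.replicate_noise_log2**2, 0.0)
    )
    shared = np.where(regulated, 0.0, rng.normal(0.0, shared_sd, size=n))
    log2_rep1 = true_effect + shared + rng.normal(0.0, config.replicate_noise_log2, n)
    log2_rep2 = true_effect + shared + rng.normal(0.0, config.replicate_noise_log2, n)

    ratio_rep1 = 2.0**log2_rep1
    ratio_rep2 = 2.0**log2_rep2
    ratio_rep2_raw = 1.0 / ratio_rep2 if config.label_swap_rep2 else ratio_rep2

    residues = rng.choice(np.array(["S", "T", "Y"]), size=n, p=list(config.sty_props))
    # bimodal localization probabilities: confident sites near 1, a minority
    # below the class-I cutoff so the filter is exercised
    low = rng.random(n) < config.loc_prob_below
    loc_prob = np.where(
        low, rng.uniform(0.2, 0.7499, n), 0.75 + 0.25 * rng.beta(5.0, 1.0, n)
    )

    # sites share proteins at the configured mean multiplicity
    n_proteins = max(1, round(n / config.sites_per_protein))
    protein_idx = rng.integers(1, n_proteins + 1, size=n)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    left = ["".join(aa[rng.integers(0, 20, 6)]) for _ in range(n)]
    right = ["".join(aa[rng.integers(0, 20, 6)]) for _ in range(n)]
    windows = [l + r + rgt for l, r, rgt in zip(left, residues, right)]

    records = pd.DataFrame(
        {
            "protein": [f"Protein{i}" for i in protein_idx],
            "gene": [f"GENE{i}" for i in protein_idx],
            "position": rng.integers(1, 1500, size=n),
            "residue": residues,
            "sequence_window": windows,
            "localization_prob": loc_prob,
            "ratio_rep1": ratio_rep1,
            "ratio_rep2_raw": ratio_rep2_raw,
        },
        columns=SITE_COLUMNS,
    )
    return records, SimTruth(label=label, true_effect_log2=true_effect)


def logistic4(conc: np.ndarray, ic50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    """Four-parameter logistic response; concentration 0 maps to the zero-dose asymptote."""
    conc = np.asarray(conc, dtype=float)
    out = np.empty_like(conc)
    zero = conc == 0
    out[zero] = bottom if hill > 0 else top
    c = conc[~zero]
    out[~zero] = bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)
    return out


def gen_dose_response(
    ic50: float,
    hill: float,
    top: float,
    bottom: float,
    concs: list[float] | np.ndarray,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Concentration-response readouts on a 4PL curve plus Gaussian noise."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ValueError("concs must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        mean = logistic4(concs, ic50, hill, top, bottom)
        resp = mean + rng.normal(0.0, noise_sd, size=concs.size)
        rows.append(
            pd.DataFrame(
                {"concentration_nM": concs, "response": resp, "replicate": rep + 1}
            )
        )
    return pd.concat(rows, ignore_index=True)


def gen_expression(
    n_probes: int,
    n_per_group: int | tuple[int, int],
    n_de: int,
    lfc: float | np.ndarray,
    seed: int = 0,
    base_mean_log2: float = 8.0,
    base_sd_log2: float = 2.0,
    within_sd_log2: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Two-group linear-scale expression matrix with planted differential probes.

    ``lfc`` is the signed log2 shift applied to the treated group for the first
    ``n_de`` probes; pass an array of length ``n_de`` for mixed directions.
    Returns (matrix probes x samples, group labels per sample, true lfc per probe).
    """
    if n_de > n_probes:
        raise ValueError("n_de cannot exceed n_probes")
    n_veh, n_trt = (
        (n_per_group, n_per_group) if isinstance(n_per_group, int) else n_per_group
    )
    rng = np.random.default_rng(seed)
    lfc = np.broadcast_to(np.asarray(lfc, dtype=float), (n_de,))
    true_lfc = np.zeros(n_probes)
    true_lfc[:n_de] = lfc

    probe_mean = rng.normal(base_mean_log2, base_sd_log2, size=n_probes)
    log2 = probe_mean[:, None] + rng.normal(
        0.0, within_sd_log2, size=(n_probes, n_veh + n_trt)
    )
    log2[:, n_veh:] += true_lfc[:, None]
    samples = [f"vehicle_{i+1}" for i in range(n_veh)] + [
        f"treated_{i+1}" for i in range(n_trt)
    ]
    probes = [f"probe_{i+1}" for i in range(n_probes)]
    matrix = pd.DataFrame(2.0**log2, index=probes, columns=samples)
    groups = pd.Series(
        ["vehicle"] * n_veh + ["treated"] * n_trt, index=samples, name="group"
    )
    return matrix, groups, pd.Series(true_lfc, index=probes, name="true_lfc")


def gen_growth_curves(
    doses: list[float],
    inhibition_fracs: list[float],
    n_animals: int,
    days: list[int],
    seed: int = 0,
    v0_mm3: float = 150.0,
    growth_rate: float = 0.12,
    noise_sd_log: float = 0.2,
    aspect_ratio: float = 1.3,
) -> pd.DataFrame:
    """Longitudinal xenograft table with exponential growth inhibited per dose.

    The mean trajectory of dose ``d`` is ``v0 * exp(growth_rate * (1 - inhib_d) * t)``
    with lognormal per-animal baseline and per-measurement noise. Diameters are
    back-computed from volume with ``V = L * W**2 / 2`` at a fixed aspect ratio,
    so the volume formula round-trips.
    """
    if len(doses) != len(inhibition_fracs):
        raise ValueError("doses and inhibition_fracs must have equal length")
    rng = np.random.default_rng(seed)
    rows = []
    for dose, inhib in zip(doses, inhibition_fracs):
        rate = growth_rate * (1.0 - inhib)
        for a in range(n_animals):
            baseline = v0_mm3 * rng.lognormal(0.0, noise_sd_log)
            for day in days:
                v = baseline * math.exp(rate * day) * rng.lognormal(0.0, noise_sd_log)
                w = (2.0 * v / aspect_ratio) ** (1.0 / 3.0)
                rows.append(
                    {
                        "animal": f"d{dose}_a{a+1}",
                        "group": dose,
                        "day": day,
                        "L_mm": aspect_ratio * w,
                        "W_mm": w,
                    }
                )
    return pd.DataFrame(rows)
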