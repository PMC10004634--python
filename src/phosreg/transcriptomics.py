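"""Microarray differential expression, relative qPCR quantification, and GSEA.

The differential-expression path follows the standard single-color workflow:
per-sample scaling to the 75th-percentile intensity, Welch's unequal-variance
t-test on log2 values, Benjamini-Hochberg q-values, and fold-change/p cutoffs
for the up/down probe lists. Enrichment analysis is the weighted
Kolmogorov-Smirnov running-sum statistic with a *gene-wise* permutation null:
the ranked list stays fixed and set membership is re-drawn at random, which
avoids the inflated false-positive rate of phenotype permutation when a large
fraction of the transcriptome responds to treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "normalize_75th",
    "welch_de",
    "classify_de",
    "ddct",
    "signal_to_noise",
    "enrichment_score",
    "gsea_genewise",
    "enrichment_records",
]


def normalize_75th(
    matrix: pd.DataFrame, target: float | str = "geomean"
) -> pd.DataFrame:
    """Scale each sample so its 75th-percentile intensity hits a common target.

    ``matrix`` is probes x samples on the linear scale, strictly positive.
    ``target="geomean"`` (default) uses the geometric mean of the per-sample
    75th percentiles as the common value; pass a positive float for a fixed
    scaling target (under which the operation is exactly invariant to
    rescaling any single sample).
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("intensities must be strictly positive")
    q75 = np.percentile(values, 75, axis=0)
    if target == "geomean":
        ref = float(np.exp(np.mean(np.log(q75))))
    else:
        ref = float(target)
        if ref <= 0:
            raise ValueError("target must be positive")
    return matrix * (ref / q75)


def welch_de(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-probe Welch t-test on log2 values with BH correction.

    ``groups`` maps sample -> {"vehicle", "treated"}; the fold change is the
    ratio of linear-scale geometric means (treated / vehicle), i.e.
    ``2**(mean log2 treated - mean log2 vehicle)``. Returns a DataFrame indexed
    by probe with ``fold_change``, ``p`` and ``q`` columns.
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    trt = matrix.loc[:, (groups == "treated").to_numpy()]
    veh = matrix.loc[:, (groups == "vehicle").to_numpy()]
    if trt.shape[1] < 2 or veh.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    log_t = np.log2(trt.to_numpy(dtype=float))
    log_v = np.log2(veh.to_numpy(dtype=float))
    t, p = stats.ttest_ind(log_t, log_v, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical probes
    fc = 2.0 ** (log_t.mean(axis=1) - log_v.mean(axis=1))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"fold_change": fc, "p": p, "q": q}, index=matrix.index)


def classify_de(
    de: pd.DataFrame, fc_hi: float = 2.0, fc_lo: float = 0.5, p_max: float = 0.01
) -> tuple[pd.Index, pd.Index]:
    """Up/down probe lists at strict fold-change and nominal-p cutoffs."""
    sig = de["p"] < p_max
    up = de.index[sig & (de["fold_change"] > fc_hi)]
    down = de.index[sig & (de["fold_change"] < fc_lo)]
    return up, down


def ddct(records: pd.DataFrame, control_group: str = "vehicle") -> pd.Series:
    """Relative expression per group by the 2^-ddCt method.

    ``records`` needs ``group``, ``ct_target`` and ``ct_reference`` columns.
    dCt = Ct_target - Ct_reference per sample; ddCt of a group is its mean dCt
    minus the control group's mean dCt; fold change = 2**(-ddCt).
    """
    if control_group not in set(records["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    dct = records["ct_target"] - records["ct_reference"]
    mean_dct = dct.groupby(records["group"]).mean()
    ddct_values = mean_dct - mean_dct[control_group]
    return (2.0**-ddct_values).rename("fold_change")


def signal_to_noise(
    matrix: pd.DataFrame, groups: pd.Series, sd_floor_frac: float = 0.2
) -> pd.Series:
    """Signal-to-noise ranking metric (treated vs vehicle) on log2 values.

    ``(m_t - m_v) / (s_t + s_v)`` with each group's standard deviation bounded
    below by ``sd_floor_frac * |mean|`` (and by ``sd_floor_frac`` when the mean
    is zero), the conventional variance floor of enrichment tools.
    """
    groups = groups.reindex(matrix.columns)
    log_x = np.log2(matrix.to_numpy(dtype=float))
    t_mask = (groups == "treated").to_numpy()
    v_mask = (groups == "vehicle").to_numpy()

    def summ(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = block.mean(axis=1)
        s = block.std(axis=1, ddof=1)
        floor = np.where(np.abs(m) > 0, sd_floor_frac * np.abs(m), sd_floor_frac)
        return m, np.maximum(s, floor)

    m_t, s_t = summ(log_x[:, t_mask])
    m_v, s_v = summ(log_x[:, v_mask])
    return pd.Series((m_t - m_v) / (s_t + s_v), index=matrix.index, name="s2n")


def _es_from_positions(
    positions: np.ndarray, abs_metric_ranked: np.ndarray, n_genes: int, p: float
) -> np.ndarray:
    """Enrichment-score extrema for one or many membership draws.

    ``positions``: (n_draws, set_size) 0-based ranks of set members (unsorted
    allowed). The running sum rises by ``|r|**p`` (normalized over the set's
    hits) at member ranks and falls by ``1/(N - Nh)`` elsewhere; the extrema
    over the whole list are reachable just after each hit (maximum candidates)
    and just before each hit (minimum candidates), so only hit positions are
    scanned.
    """
    pos = np.sort(positions, axis=1)
    m = pos.shape[1]
    w = np.abs(abs_metric_ranked[pos]) ** p
    w_cum = np.cumsum(w, axis=1)
    w_tot = w_cum[:, -1:]
    with np.errstate(invalid="ignore"):
        hit_frac = w_cum / w_tot
    miss_step = 1.0 / (n_genes - m)
    j = np.arange(m)
    misses_before = pos - j  # misses strictly before the j-th hit
    after_hit = hit_frac - misses_before * miss_step
    before_hit = np.concatenate(
        [np.zeros((pos.shape[0], 1)), hit_frac[:, :-1]], axis=1
    ) - misses_before * miss_step
    # the running sum ends at 0, so max(after_hit) >= 0 and min(before_hit) <= 0
    max_es = after_hit.max(axis=1)
    min_es = before_hit.min(axis=1)
    return np.where(max_es >= -min_es, max_es, min_es)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    n_perm: int
    seed: int


def enrichment_score(
    ranked_genes: pd.Series | pd.Index | list[str],
    metric: np.ndarray | pd.Series,
    members: set[str] | list[str],
    p: float = 1.0,
    return_profile: bool = True,
) -> tuple[float, np.ndarray] | float:
    """Weighted KS enrichment score of a gene set against a ranked list.

    ``ranked_genes`` must already be ordered by decreasing metric. Increments
    at member genes are ``|metric|**p`` normalized by their sum; decrements at
    non-members are ``1/(N - Nh)``. The ES is the extremum of the running sum
    (largest magnitude). Raises if the set misses the list entirely or covers
    it completely.
    """
    genes = pd.Index(ranked_genes)
    metric = np.asarray(metric, dtype=float)
    hit = np.asarray(genes.isin(set(members)))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the entire ranked list (empty complement)")
    weights = np.abs(metric) ** p
    w_hit = np.where(hit, weights, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        # all member metrics are exactly zero: fall back to equal weights
        w_hit = hit.astype(float)
        denom = w_hit.sum()
    steps = w_hit / denom - (~hit) / (len(genes) - n_hit)
    profile = np.cumsum(steps)
    hi, lo = float(profile.max()), float(profile.min())
    es = hi if hi >= -lo else lo
    return (es, profile) if return_profile else es


def gsea_genewise(
    matrix: pd.DataFrame,
    groups: pd.Series,
    sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """GSEA with a gene-wise permutation null.

    Genes are ranked by the signal-to-noise metric; for each set the null ES
    distribution comes from ``n_perm`` random re-draws of which genes belong to
    the set (same size), against the fixed ranked list. NES divides the ES by
    the mean |null ES| of the same sign; the permutation p is the same-sign
    exceedance fraction; FDR q follows the enrichment-tool convention of
    comparing tail fractions of the pooled null NES and the observed NES,
    separately per sign.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not sets:
        raise ValueError("need at least one gene set")
    rng = np.random.default_rng(seed)
    metric = signal_to_noise(matrix, groups)
    order = np.argsort(-metric.to_numpy(), kind="stable")
    ranked = metric.index.to_numpy()[order]
    ranked_metric = metric.to_numpy()[order]
    gene_pos = {g: i for i, g in enumerate(ranked)}
    n_genes = len(ranked)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in sets.items():
        pos = np.array([gene_pos[g] for g in members if g in gene_pos])
        if pos.size == 0:
            raise ValueError(f"gene set {name!r} does not intersect the matrix")
        if pos.size == n_genes:
            raise ValueError(f"gene set {name!r} covers all genes")
        es = _es_from_positions(pos[None, :], ranked_metric, n_genes, weight_p)[0]
        perm_pos = np.array(
            [rng.choice(n_genes, size=pos.size, replace=False) for _ in range(n_perm)]
        )
        null_es = _es_from_positions(perm_pos, ranked_metric, n_genes, weight_p)

        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = max(int(same_sign.sum()), 1)
        if es >= 0:
            p_perm = float((null_es[same_sign] >= es).sum()) / n_same
            mean_same = null_es[same_sign].mean() if same_sign.any() else np.nan
        else:
            p_perm = float((null_es[same_sign] <= es).sum()) / n_same
            mean_same = null_es[same_sign].mean() if same_sign.any() else np.nan
        nes = float(es / abs(mean_same)) if np.isfinite(mean_same) and mean_same != 0 else np.nan

        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        null_nes = np.concatenate(
            [
                pos_null / pos_null.mean() if pos_null.size else pos_null,
                -(neg_null / neg_null.mean()) if neg_null.size else neg_null,
            ]
        )
        null_nes_pool.append(null_nes)
        rows.append({"name": name, "es": es, "nes": nes, "p_perm": p_perm})

    result = pd.DataFrame(rows).set_index("name")
    pooled = np.concatenate(null_nes_pool)
    obs = result["nes"].to_numpy()
    q = np.empty(len(result))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = np.nan
            continue
        if nes >= 0:
            null_tail = np.mean(pooled[pooled >= 0] >= nes) if np.any(pooled >= 0) else 0.0
            obs_tail = np.mean(obs[np.isfinite(obs) & (obs >= 0)] >= nes)
        else:
            null_tail = np.mean(pooled[pooled < 0] <= nes) if np.any(pooled < 0) else 0.0
            obs_tail = np.mean(obs[np.isfinite(obs) & (obs < 0)] <= nes)
        q[i] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else np.nan
    result["fdr_q"] = q
    result["n_perm"] = n_perm
    result["seed"] = seed
    return result


def enrichment_records(result: pd.DataFrame) -> list[EnrichmentResult]:
    """Rows of a :func:`gsea_genewise` result as typed records."""
    return [
        EnrichmentResult(
            name=name,
            es=float(row["es"]),
            nes=float(row["nes"]),
            p_perm=float(row["p_perm"]),
            fdr_q=float(row["fdr_q"]),
            n_perm=int(row["n_perm"]),
            seed=int(row["seed"]),
        )
        for name, row in result.iterrows()
    ]
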