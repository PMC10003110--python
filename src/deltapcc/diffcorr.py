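"""Single-sample differential correlation (ΔPCC) of miRNA-RNA pairs.

The perturbation statistic: for a gene pair (X, Y) with Pearson correlation
PCC_n computed over the n normal samples, appending one tumor sample and
recomputing gives PCC_{n+1}; the difference

    ΔPCC(X, Y) = PCC_{n+1}(X, Y) - PCC_n(X, Y)

measures how much that single tumor sample perturbs the normal-tissue
co-expression of the pair. ΔPCC is computed per (pair, tumor sample) and is
the feature underlying both the metastasis classifiers and the prognostic
screening.

Pair selection happens in three steps:

1. class correlation filter — pairs must be strongly correlated
   (|PCC| >= 0.4 by default) in exactly one of the positive / negative
   tumor-sample sets (pairs strong in both are uninformative and removed);
2. ΔPCC table construction over all task tumor samples;
3. a two-sided Wilcoxon rank-sum screen of ΔPCC values, positives versus
   negatives, keeping pairs with p < 0.01.

The incremental ΔPCC implementation updates the baseline correlation sums
in O(1) per tumor sample and is contract-bound to agree with direct
recomputation to 1e-10.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import RNA_BIOTYPES

logger = logging.getLogger(__name__)

__all__ = [
    "pearson",
    "build_pair_universe",
    "class_correlations",
    "class_correlation_filter",
    "delta_pcc",
    "build_delta_table",
    "wilcoxon_screen",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, clamped to [-1, 1]; NaN for constant input.

    Degenerate (zero-variance) vectors yield NaN rather than an exception so
    that pair-level screening can skip and log them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def build_pair_universe(
    annotation: pd.Series,
    gene_ids,
    whitelist: pd.DataFrame | None = None,
) -> pd.MultiIndex:
    """All (miRNA, target RNA) pairs among ``gene_ids``.

    Targets are genes with biotype mRNA, lncRNA or pseudogene; genes with
    biotype "other" never enter pairs. An optional whitelist (columns mirna,
    rna) restricts the universe to listed interactions.
    """
    ann = annotation.reindex(gene_ids)
    if ann.isna().any():
        missing = ann.index[ann.isna()].tolist()[:5]
        raise ValueError(f"genes without biotype annotation, e.g. {missing}")
    mirnas = ann.index[ann == "miRNA"]
    rnas = ann.index[ann.isin(RNA_BIOTYPES)]
    if len(mirnas) == 0 or len(rnas) == 0:
        raise ValueError("pair universe is empty: need miRNAs and target RNAs")
    universe = pd.MultiIndex.from_product([mirnas, rnas], names=["mirna", "rna"])
    if whitelist is not None:
        wanted = pd.MultiIndex.from_frame(whitelist[["mirna", "rna"]])
        universe = universe.intersection(wanted, sort=False)
    return universe


def _pairwise_corr(values: pd.DataFrame, universe: pd.MultiIndex) -> np.ndarray:
    """Correlation across columns of ``values`` for each (mirna, rna) pair."""
    x = values.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=1))
    loc = {g: i for i, g in enumerate(values.index)}
    ia = np.fromiter((loc[m] for m, _ in universe), dtype=int, count=len(universe))
    ib = np.fromiter((loc[r] for _, r in universe), dtype=int, count=len(universe))
    num = (x[ia] * x[ib]).sum(axis=1)
    denom = norms[ia] * norms[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def class_correlations(
    cpm_values: pd.DataFrame, labels: pd.Series, universe: pd.MultiIndex
) -> pd.DataFrame:
    """Per-pair PCC within positive and within negative tumor samples."""
    pos = labels.index[labels == "positive"]
    neg = labels.index[labels == "negative"]
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("need at least 3 samples per class for class correlations")
    return pd.DataFrame(
        {
            "pcc_pos": _pairwise_corr(cpm_values[pos], universe),
            "pcc_neg": _pairwise_corr(cpm_values[neg], universe),
        },
        index=universe,
    )


def class_correlation_filter(
    cpm_values: pd.DataFrame,
    labels: pd.Series,
    universe: pd.MultiIndex,
    cutoff: float = 0.4,
) -> pd.MultiIndex:
    """Keep pairs strongly correlated in exactly one class.

    With P = pairs at |PCC| >= cutoff among positives and N = the same among
    negatives, the surviving set is the symmetric difference (P u N) \\
    (P n N): pairs below the cutoff everywhere carry no class signal, pairs
    above it in both classes carry none either.
    """
    corr = class_correlations(cpm_values, labels, universe)
    in_pos = corr["pcc_pos"].abs() >= cutoff
    in_neg = corr["pcc_neg"].abs() >= cutoff
    keep = in_pos ^ in_neg
    kept = universe[keep.to_numpy()]
    if len(kept) == 0:
        raise ValueError(
            f"no pair passed the class correlation filter at cutoff {cutoff}; "
            "consider lowering the cutoff"
        )
    return kept


def delta_pcc(
    normal_x: np.ndarray, normal_y: np.ndarray, tumor_x: float, tumor_y: float
) -> float:
    """ΔPCC of one tumor sample against the normal baseline, by direct
    recomputation (the reference path for the incremental table builder)."""
    base = pearson(normal_x, normal_y)
    if np.isnan(base):
        return float("nan")
    aug_x = np.append(np.asarray(normal_x, dtype=float), tumor_x)
    aug_y = np.append(np.asarray(normal_y, dtype=float), tumor_y)
    return pearson(aug_x, aug_y) - base


def build_delta_table(
    cpm_values: pd.DataFrame,
    labels: pd.Series,
    universe: pd.MultiIndex,
    normal_samples,
    task: str | None = None,
) -> pd.DataFrame:
    """ΔPCC table: rows = pairs, columns = task tumor samples.

    The baseline PCC_n uses the normal samples only. For each tumor sample
    the augmented correlation PCC_{n+1} is obtained by O(1) updates of the
    baseline sums (sum x, sum x^2, sum xy), which is algebraically identical
    to recomputing the correlation over the n+1 points. Entries where either
    gene is constant across the augmented vector are NaN and counted in a
    log line.

    The result carries ``attrs['n_normals']`` and ``attrs['task']``.
    """
    if len(universe) == 0:
        raise ValueError("empty pair universe")
    normal_samples = list(normal_samples)
    n = len(normal_samples)
    if n < 3:
        raise ValueError("need at least 3 normal samples for the baseline")
    tumor_samples = [s for s in labels.index if labels[s] in ("positive", "negative")]

    genes = cpm_values.index
    loc = {g: i for i, g in enumerate(genes)}
    ia = np.fromiter((loc[m] for m, _ in universe), dtype=int, count=len(universe))
    ib = np.fromiter((loc[r] for _, r in universe), dtype=int, count=len(universe))

    normal = cpm_values[normal_samples].to_numpy(dtype=float)
    tumor = cpm_values[tumor_samples].to_numpy(dtype=float)

    # baseline sufficient statistics per gene / per pair over the n normals
    s1 = normal.sum(axis=1)
    s2 = (normal**2).sum(axis=1)
    sxy = (normal[ia] * normal[ib]).sum(axis=1)

    def corr_from_sums(sx, sy, sxx, syy, sxy_, m):
        cov = m * sxy_ - sx * sy
        vx = m * sxx - sx**2
        vy = m * syy - sy**2
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(vx * vy)
        r = np.where((vx <= 0) | (vy <= 0), np.nan, r)
        return np.clip(r, -1.0, 1.0)

    base = corr_from_sums(s1[ia], s1[ib], s2[ia], s2[ib], sxy, n)

    xt = tumor[ia]  # (pairs, tumors) miRNA CPM of each pair in each tumor
    yt = tumor[ib]
    sx = s1[ia][:, None] + xt
    sy = s1[ib][:, None] + yt
    sxx = s2[ia][:, None] + xt**2
    syy = s2[ib][:, None] + yt**2
    sxy1 = sxy[:, None] + xt * yt
    aug = corr_from_sums(sx, sy, sxx, syy, sxy1, n + 1)

    delta = aug - base[:, None]
    n_missing = int(np.isnan(delta).sum())
    if n_missing:
        logger.warning("ΔPCC undefined for %d (pair, sample) entries", n_missing)
    table = pd.DataFrame(delta, index=universe, columns=tumor_samples)
    table.attrs["n_normals"] = n
    table.attrs["task"] = task
    return table


def wilcoxon_screen(
    table: pd.DataFrame, labels: pd.Series, alpha: float = 0.01
) -> pd.DataFrame:
    """Two-sided rank-sum screen of ΔPCC, positives vs negatives, per pair.

    Returns a frame indexed by pair with columns statistic, p_value, kept
    (kept iff p < alpha). Missing ΔPCC values are removed pairwise; pairs
    with fewer than 2 usable values in either class are dropped with a
    warning. Exact p-values for small tie-free samples, tie-corrected
    normal approximation otherwise (scipy's Mann-Whitney U).
    """
    pos_cols = [s for s in table.columns if labels.get(s) == "positive"]
    neg_cols = [s for s in table.columns if labels.get(s) == "negative"]
    if not pos_cols or not neg_cols:
        raise ValueError("screen needs tumor samples of both classes")
    pos = table[pos_cols].to_numpy(dtype=float)
    neg = table[neg_cols].to_numpy(dtype=float)

    rows = []
    n_dropped = 0
    for i in range(len(table.index)):
        p_vals = pos[i][~np.isnan(pos[i])]
        n_vals = neg[i][~np.isnan(neg[i])]
        if p_vals.size < 2 or n_vals.size < 2:
            n_dropped += 1
            continue
        res = stats.mannwhitneyu(p_vals, n_vals, alternative="two-sided")
        rows.append((table.index[i], float(res.statistic), float(res.pvalue)))
    if n_dropped:
        logger.warning("%d pairs dropped from the Wilcoxon screen (too many missing)", n_dropped)
    keys = [r[0] for r in rows]
    if keys and all(isinstance(k, tuple) and len(k) == 2 for k in keys):
        idx = pd.MultiIndex.from_tuples(keys, names=["mirna", "rna"])
    else:  # generic feature axis (e.g. already-named pair columns)
        idx = pd.Index(keys)
    out = pd.DataFrame(
        {
            "statistic": [r[1] for r in rows],
            "p_value": [r[2] for r in rows],
        },
        index=idx,
    )
    out["kept"] = out["p_value"] < alpha
    return out
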