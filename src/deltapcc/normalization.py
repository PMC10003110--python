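"""Low-expression filtering and TMM-scaled counts-per-million normalization.

Between-sample normalization follows the trimmed mean of M-values (TMM)
scheme of Robinson & Oshlack: a reference sample is chosen by upper-quartile
count fraction, per-sample log2 fold changes against the reference (M-values)
are doubly trimmed by M and by average log intensity (A), and the scaling
factor is two to the inverse-asymptotic-variance-weighted mean of the
surviving M-values. Factors are rescaled to geometric mean one so that they
only redistribute, never inflate, effective library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["CpmMatrix", "filter_low_expression", "tmm_factors", "cpm"]


@dataclass
class CpmMatrix:
    """Counts-per-million matrix (genes x samples) with its TMM factors.

    ``values`` is indexed like the raw count matrix; ``tmm_factors`` is one
    positive scaling factor per sample with geometric mean 1.
    """

    values: pd.DataFrame
    tmm_factors: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("CPM values must be finite")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("CPM values must be non-negative")
        log_gm = float(np.mean(np.log(self.tmm_factors.to_numpy())))
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")


def filter_low_expression(counts: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Drop genes whose mean raw count across all samples is below ``threshold``.

    Applied to raw counts over the full data set (tumor and normal samples
    alike) before any normalization. Gene order is preserved.
    """
    if counts.empty:
        raise ValueError("count matrix is empty")
    keep = counts.mean(axis=1) >= threshold
    if not keep.any():
        raise ValueError(
            f"low-expression filter at threshold {threshold} removed every gene"
        )
    return counts.loc[keep]


def _upper_quartile_fraction(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0)
    return np.quantile(counts, 0.75, axis=0) / lib


def _pair_tmm(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        # asymptotic (delta-method) variance of M
        w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    ok = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[ok], a[ok], w[ok]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction. For each sample, genes with
    a zero count in either the sample or the reference are excluded; the
    factor is 2**(weighted trimmed mean of M-values). A sample that shares
    no expressed gene with the reference gets factor 1 (before the global
    geometric-mean rescaling) with a warning.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    uq = _upper_quartile_fraction(x)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[:, ref_idx]

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            factors[j] = _pair_tmm(x[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
            continue
        shared = (x[:, j] > 0) & (ref > 0)
        if not shared.any():
            import warnings

            warnings.warn(
                f"sample {counts.columns[j]!r} shares no expressed gene with the "
                "TMM reference; factor set to 1",
                stacklevel=2,
            )
            factors[j] = 1.0
            continue
        factors[j] = _pair_tmm(x[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> CpmMatrix:
    """Counts per million on TMM-corrected library sizes.

    value(g, s) = count(g, s) / (lib_size(s) * factor(s)) * 1e6. With unit
    factors every column sums to one million.
    """
    if factors is None:
        factors = tmm_factors(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("need one positive TMM factor per sample")
    lib = counts.sum(axis=0)
    eff = lib * factors
    if (eff <= 0).any():
        bad = counts.columns[eff <= 0].tolist()
        raise ValueError(f"zero effective library size for samples: {bad}")
    values = counts / eff * 1e6
    return CpmMatrix(values=values, tmm_factors=factors)
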