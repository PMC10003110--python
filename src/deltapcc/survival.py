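"""Pair-level prognostic screening: univariate Cox, C-index, optimal cutpoints.

Each candidate miRNA-RNA pair is scored on overall survival using the
patient-wise |ΔPCC| as the predictor:

* a univariate Cox proportional-hazards fit (Efron tie handling) gives the
  coefficient beta, the hazard ratio exp(beta) and per-patient partial
  hazards exp(beta * x);
* the concordance index is computed literally as

      C = sum_{i != j} 1[T_i > T_j] * 1[eta_i < eta_j] * d_j
          -----------------------------------------------
          sum_{i != j} 1[T_i > T_j] * d_j

  with eta the partial hazard and d the event indicator — note that score
  ties contribute 0 to the numerator under this definition (a 0.5 tie
  convention is available via ``tie_value``);
* patients are split into high/low groups at the cutpoint maximizing the
  two-group log-rank statistic over all admissible midpoints of adjacent
  predictor values; the reported p-value accounts for having scanned the
  cuts via the Contal-O'Quigley approximation (the supremum of the
  partial-sum process of log-rank scores converges to a Brownian bridge,
  so the corrected p is the Kolmogorov tail of max|S|/sqrt(sum U_i^2)).
  The nominal chi-square p at the chosen cut — grossly optimistic under
  selection — is available with ``correct_selection=False``;
* log-rank p-values are Benjamini-Hochberg adjusted across all tested
  pairs, and pairs with adjusted p below ``alpha_adj`` survive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData",
    "PairSurvivalResult",
    "cox_univariate",
    "c_index",
    "logrank_test",
    "optimal_cutpoint",
    "selection_corrected_p",
    "bh_adjust",
    "screen_pairs",
    "kaplan_meier_table",
]

# standardized-effect bound |beta| * sd(x) flagged as monotone-likelihood
# divergence (a hazard ratio of e^10 per predictor SD is not a finite MLE)
BETA_STD_CAP = 10.0


@dataclass
class SurvivalData:
    """Aligned survival triples: time (days), event (1 = death observed),
    and a continuous predictor per patient."""

    time: np.ndarray
    event: np.ndarray
    predictor: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.predictor = np.asarray(self.predictor, dtype=float)
        if not (self.time.shape == self.event.shape == self.predictor.shape):
            raise ValueError("time, event and predictor must be aligned")
        if not np.all(np.isfinite(self.time)) or (self.time < 0).any():
            raise ValueError("survival times must be finite and non-negative")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class CoxResult:
    beta: float
    hr: float
    wald_p: float
    partial_hazards: np.ndarray
    converged: bool = True


def cox_univariate(data: SurvivalData) -> CoxResult:
    """Univariate Cox PH fit of survival on the predictor (Efron ties).

    Returns beta, HR = exp(beta), the Wald p-value and per-patient partial
    hazards exp(beta * x). Perfect separation (monotone likelihood) is
    caught: the standardized effect |beta| * sd(x) is capped at
    ``BETA_STD_CAP`` and the result flagged as not converged.
    """
    if data.event.sum() < 1:
        raise ValueError("Cox regression needs at least one observed event")
    if np.ptp(data.predictor) == 0:
        raise ValueError("predictor is constant; Cox coefficient undefined")
    sd_x = float(np.std(data.predictor))
    beta_cap = BETA_STD_CAP / sd_x
    df = pd.DataFrame({"time": data.time, "event": data.event, "x": data.predictor})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["x"])
        wald_p = float(cph.summary.loc["x", "p"])
        converged = True
    except Exception as exc:  # lifelines ConvergenceError and kin
        logger.warning("Cox fit diverged (%s); capping |beta|*sd(x) at %.0f",
                       exc, BETA_STD_CAP)
        slope = np.corrcoef(data.predictor, data.time)[0, 1]
        beta = -np.sign(slope) * beta_cap if np.isfinite(slope) else beta_cap
        wald_p = float("nan")
        converged = False
    if abs(beta) > beta_cap:
        logger.warning("Cox standardized effect %.2f exceeds cap; flagging divergence",
                       abs(beta) * sd_x)
        beta = float(np.clip(beta, -beta_cap, beta_cap))
        converged = False
    hazards = np.exp(beta * data.predictor)
    return CoxResult(beta=beta, hr=float(np.exp(beta)), wald_p=wald_p,
                     partial_hazards=hazards, converged=converged)


def c_index(data: SurvivalData, tie_value: float = 0.0) -> float:
    """Concordance index, literal ordered-pair form.

    Over ordered pairs (i, j), i != j: the denominator counts pairs with
    T_i > T_j and d_j = 1; the numerator additionally requires
    eta_i < eta_j (longer survivor has the lower score). Ties in eta score
    ``tie_value`` (0 by default; 0.5 restores the common convention).
    Returns NaN when no pair is comparable.
    """
    t = data.time
    eta = data.predictor
    d = data.event
    t_gt = t[:, None] > t[None, :]
    comparable = t_gt & (d[None, :] == 1)
    denom = comparable.sum()
    if denom == 0:
        return float("nan")
    eta_lt = eta[:, None] < eta[None, :]
    eta_eq = eta[:, None] == eta[None, :]
    np.fill_diagonal(eta_eq, False)
    num = (comparable & eta_lt).sum() + tie_value * (comparable & eta_eq).sum()
    return float(num / denom)


def logrank_test(
    time_a, event_a, time_b, event_b
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if int(np.sum(event_a)) + int(np.sum(event_b)) == 0:
        return float("nan"), float("nan")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def _logrank_scan(
    time: np.ndarray, event: np.ndarray, predictor: np.ndarray, cuts: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square at every candidate cut, vectorized over cuts.

    Group 1 at cut c is {predictor > c}. Uses the tie-aware hypergeometric
    variance; cuts with zero variance (all events in one risk pattern)
    return 0.
    """
    event_times = np.unique(time[event == 1])
    at_risk = (time[None, :] >= event_times[:, None]).astype(float)
    died = ((time[None, :] == event_times[:, None]) & (event[None, :] == 1)).astype(float)
    grp = (predictor[:, None] > cuts[None, :]).astype(float)  # n x K
    n1 = at_risk @ grp  # events-times x K
    d1 = died @ grp
    n_t = at_risk.sum(axis=1)[:, None]
    d_t = died.sum(axis=1)[:, None]
    o_minus_e = (d1 - n1 * d_t / n_t).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    var_t = np.where(n_t > 1, var_t, 0.0)
    v = var_t.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(v > 0, o_minus_e**2 / v, 0.0)
    return stat


def _logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank (martingale) scores U_i = d_i - NelsonAalen(T_i)."""
    event_times = np.unique(time[event == 1])
    n_at_risk = (time[None, :] >= event_times[:, None]).sum(axis=1)
    d = ((time[None, :] == event_times[:, None]) & (event[None, :] == 1)).sum(axis=1)
    increments = d / n_at_risk
    cum_haz = np.concatenate([[0.0], np.cumsum(increments)])
    idx = np.searchsorted(event_times, time, side="right")
    return event - cum_haz[idx]


def selection_corrected_p(
    time: np.ndarray, event: np.ndarray, predictor: np.ndarray, cuts: np.ndarray
) -> float:
    """Contal-O'Quigley p-value for a maximally selected log-rank cut.

    The partial-sum process S(c) = sum_{x_i > c} U_i of the log-rank scores
    behaves asymptotically like a Brownian bridge in the group fraction, so
    the p-value of sup_c |S(c)| / sqrt(sum U_i^2) is the Kolmogorov tail
    2 * sum_k (-1)^{k+1} exp(-2 k^2 q^2). Restricting the scan to the
    admissible cuts makes this slightly conservative, which is the intended
    direction for a screening statistic.
    """
    from scipy.special import kolmogorov

    u = _logrank_scores(time, event)
    denom = np.sqrt((u**2).sum())
    if denom == 0:
        return 1.0
    grp = (predictor[:, None] > cuts[None, :]).astype(float)
    s = u @ grp
    q = np.max(np.abs(s)) / denom
    return float(min(1.0, kolmogorov(q)))


def optimal_cutpoint(
    data: SurvivalData,
    min_group_fraction: float = 0.1,
    correct_selection: bool = True,
) -> tuple[float, float, float]:
    """Maximally selected log-rank cutpoint on a continuous predictor.

    Candidates are midpoints of adjacent sorted unique predictor values
    whose induced split leaves both groups at least ``min_group_fraction``
    of the cohort. Returns (cutpoint, log-rank statistic, p); the statistic
    is the largest two-group log-rank chi-square over the candidates, and
    the p-value is by default corrected for the scan (Contal-O'Quigley
    Brownian-bridge supremum). ``correct_selection=False`` reports the
    nominal chi-square(1) tail at the selected cut instead, which is
    optimistic and suitable only for descriptive output.
    """
    uniq = np.unique(data.predictor)
    if uniq.size < 2:
        raise ValueError("predictor needs at least 2 distinct values")
    mids = (uniq[:-1] + uniq[1:]) / 2
    n = len(data)
    min_n = max(1, int(np.ceil(min_group_fraction * n)))
    high_n = (data.predictor[:, None] > mids[None, :]).sum(axis=0)
    ok = (high_n >= min_n) & (n - high_n >= min_n)
    if not ok.any():
        raise ValueError(
            f"no admissible cut leaves both groups >= {min_n} samples"
        )
    cuts = mids[ok]
    stats_ = _logrank_scan(data.time, data.event, data.predictor, cuts)
    best = int(np.argmax(stats_))
    stat = float(stats_[best])
    if correct_selection:
        p = selection_corrected_p(data.time, data.event, data.predictor, cuts)
    else:
        p = float(chi2.sf(stat, df=1))
    return float(cuts[best]), stat, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PairSurvivalResult:
    """Survival statistics of one miRNA-RNA pair on |ΔPCC|."""

    mirna: str
    rna: str
    beta: float
    hr: float
    wald_p: float
    c_index: float
    cutpoint: float
    logrank_stat: float
    logrank_p: float
    logrank_p_adj: float = field(default=float("nan"))
    kept: bool = False


def screen_pairs(
    delta_table: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha_adj: float = 0.01,
    min_group_fraction: float = 0.1,
    max_missing_fraction: float = 0.5,
) -> list[PairSurvivalResult]:
    """Prognostic screening of every pair in a ΔPCC table.

    The per-patient predictor is |ΔPCC|. For each pair: univariate Cox
    (beta, HR, partial hazards), C-index on the partial hazards, optimal
    cutpoint and log-rank test between high/low groups. Log-rank p-values
    are BH-adjusted across all tested pairs; pairs with adjusted p <
    ``alpha_adj`` are flagged ``kept``. Results come back sorted by raw
    log-rank p ascending. Pairs whose predictor is missing for more than
    ``max_missing_fraction`` of patients are dropped with a warning.
    """
    patients = [s for s in delta_table.columns if s in clinical.index]
    surv = clinical.loc[patients]
    usable = surv["os_time"].notna()
    patients = list(np.array(patients)[usable.to_numpy()])
    time = surv.loc[patients, "os_time"].to_numpy(dtype=float)
    event = surv.loc[patients, "os_event"].to_numpy(dtype=int)

    results: list[PairSurvivalResult] = []
    values = delta_table[patients].to_numpy(dtype=float)
    for i, (mirna, rna) in enumerate(delta_table.index):
        x = np.abs(values[i])
        ok = ~np.isnan(x)
        if ok.mean() < 1 - max_missing_fraction:
            logger.warning("pair (%s, %s) dropped: >%d%% missing |ΔPCC|",
                           mirna, rna, int(100 * max_missing_fraction))
            continue
        d = SurvivalData(time[ok], event[ok], x[ok])
        if np.ptp(d.predictor) == 0 or d.event.sum() == 0:
            continue
        try:
            cox = cox_univariate(d)
            cut, stat, p = optimal_cutpoint(d, min_group_fraction)
        except ValueError:
            continue
        ci = c_index(SurvivalData(d.time, d.event, cox.partial_hazards))
        results.append(
            PairSurvivalResult(
                mirna=mirna, rna=rna, beta=cox.beta, hr=cox.hr,
                wald_p=cox.wald_p, c_index=ci, cutpoint=cut,
                logrank_stat=stat, logrank_p=p,
            )
        )
    if not results:
        return results
    adj = bh_adjust([r.logrank_p for r in results])
    for r, a in zip(results, adj):
        r.logrank_p_adj = float(a)
        r.kept = bool(a < alpha_adj)
    results.sort(key=lambda r: r.logrank_p)
    return results


def pair_results_frame(results: list[PairSurvivalResult]) -> pd.DataFrame:
    """Tabular form of screen_pairs output (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna, "rna": r.rna, "beta": r.beta, "hr": r.hr,
                "wald_p": r.wald_p, "c_index": r.c_index, "cutpoint": r.cutpoint,
                "logrank_stat": r.logrank_stat, "logrank_p": r.logrank_p,
                "logrank_p_adj": r.logrank_p_adj, "kept": r.kept,
            }
            for r in results
        ]
    )


def kaplan_meier_table(
    time, event, group: np.ndarray
) -> pd.DataFrame:
    """Kaplan-Meier curves per group as a tidy table.

    Columns: group, time, at_risk, survival — one row per distinct event or
    censoring time, mirroring the risk tables under published KM plots.
    """
    from lifelines import KaplanMeierFitter

    frames = []
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    for g in np.unique(group):
        sel = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        tab = kmf.event_table
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": tab.index.to_numpy(),
                    "at_risk": tab["at_risk"].to_numpy(),
                    "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
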