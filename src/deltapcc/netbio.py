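"""Star-network biomarkers: assembly, Cox-weighted risk scores, selection.

Significant prognostic pairs sharing a center miRNA are combined (smallest
log-rank p first, at most 15 members) into star-shaped networks. Patient i
is scored by

    risk(i) = sum_j |ΔPCC|_{j,i} * beta_j

over member pairs j, with beta_j the pair's univariate Cox coefficient
(taken as fitted at the pair level, never refit jointly). The score defines
high/low risk groups at the maximally selected log-rank cutpoint; networks
with C-index > 0.6 and BH-adjusted log-rank p < 0.01 are selected as
biomarkers. The network-level BH family is the set of evaluated networks,
separate from the pair-level family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .survival import (
    PairSurvivalResult,
    SurvivalData,
    bh_adjust,
    c_index,
    cox_univariate,
    optimal_cutpoint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StarNetwork",
    "build_networks",
    "risk_score",
    "risk_scores",
    "evaluate_network",
    "select_biomarkers",
    "networks_to_graphml",
]


@dataclass
class StarNetwork:
    """A miRNA-centered star of prognostic pairs with its survival stats."""

    center_mirna: str
    members: list[PairSurvivalResult]
    risk: pd.Series | None = None  # per-patient risk scores
    hr: float = float("nan")
    c_index: float = float("nan")
    cutpoint: float = float("nan")
    logrank_stat: float = float("nan")
    logrank_p: float = float("nan")
    logrank_p_adj: float = field(default=float("nan"))
    selected: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 15:
            raise ValueError("a star network has between 1 and 15 member pairs")
        if any(m.mirna != self.center_mirna for m in self.members):
            raise ValueError("all member pairs must share the center miRNA")

    @property
    def member_pairs(self) -> list[tuple[str, str]]:
        return [(m.mirna, m.rna) for m in self.members]


def build_networks(
    significant_pairs: list[PairSurvivalResult], max_members: int = 15
) -> list[StarNetwork]:
    """Group significant pairs by center miRNA into star networks.

    Within each center the ``max_members`` smallest raw log-rank p pairs are
    kept; every significant pair belongs to exactly one network (its
    miRNA's). Networks come back ordered by their best member p.
    """
    by_mirna: dict[str, list[PairSurvivalResult]] = {}
    for pair in sorted(significant_pairs, key=lambda r: r.logrank_p):
        by_mirna.setdefault(pair.mirna, []).append(pair)
    networks = [
        StarNetwork(center_mirna=mirna, members=pairs[:max_members])
        for mirna, pairs in by_mirna.items()
    ]
    networks.sort(key=lambda n: n.members[0].logrank_p)
    return networks


def risk_score(network: StarNetwork, abs_delta: dict | pd.Series) -> float:
    """Cox-weighted risk score of one patient: sum_j |ΔPCC|_j * beta_j.

    ``abs_delta`` maps (mirna, rna) to the patient's |ΔPCC|. Member pairs
    with a missing value are skipped with a warning; if every member is
    missing the score is NaN.
    """
    total, used = 0.0, 0
    for m in network.members:
        v = abs_delta.get((m.mirna, m.rna))
        if v is None or (isinstance(v, float) and np.isnan(v)):
            logger.warning("missing |ΔPCC| for pair (%s, %s); skipped", m.mirna, m.rna)
            continue
        total += float(v) * m.beta
        used += 1
    return total if used else float("nan")


def risk_scores(network: StarNetwork, delta_table: pd.DataFrame) -> pd.Series:
    """Per-patient risk scores of a network from a ΔPCC table (vectorized)."""
    idx = pd.MultiIndex.from_tuples(network.member_pairs, names=["mirna", "rna"])
    sub = delta_table.loc[idx].abs()
    betas = np.array([m.beta for m in network.members])
    weighted = sub.mul(betas, axis=0)
    score = weighted.sum(axis=0, skipna=True)
    score[sub.isna().all(axis=0)] = np.nan
    score.name = f"risk_{network.center_mirna}"
    return score


def evaluate_network(
    network: StarNetwork,
    delta_table: pd.DataFrame,
    clinical: pd.DataFrame,
    min_group_fraction: float = 0.1,
    min_score_fraction: float = 0.8,
    eta: str = "risk",
) -> StarNetwork | None:
    """Fill a network's survival statistics from patient risk scores.

    eta='risk' uses the raw risk score as the concordance score; eta='cox'
    refits a univariate Cox on the score and uses its partial hazards. HR
    always comes from the Cox refit on the score. Networks with a constant
    score, or scores defined for fewer than ``min_score_fraction`` of
    patients, are dropped (returns None).
    """
    scores = risk_scores(network, delta_table)
    patients = [s for s in scores.index if s in clinical.index]
    surv = clinical.loc[patients]
    ok = surv["os_time"].notna() & scores.loc[patients].notna()
    if ok.mean() < min_score_fraction:
        logger.warning("network %s: risk score defined for <%d%% of patients; dropped",
                       network.center_mirna, int(100 * min_score_fraction))
        return None
    patients = list(np.array(patients)[ok.to_numpy()])
    data = SurvivalData(
        surv.loc[patients, "os_time"].to_numpy(dtype=float),
        surv.loc[patients, "os_event"].to_numpy(dtype=int),
        scores.loc[patients].to_numpy(dtype=float),
    )
    if np.ptp(data.predictor) == 0:
        logger.warning("network %s has a constant risk score; dropped",
                       network.center_mirna)
        return None
    cox = cox_univariate(data)
    if eta == "cox":
        eta_scores = cox.partial_hazards
    else:
        eta_scores = data.predictor
    network.risk = scores
    network.hr = cox.hr
    network.c_index = c_index(SurvivalData(data.time, data.event, eta_scores))
    try:
        cut, stat, p = optimal_cutpoint(data, min_group_fraction)
    except ValueError:
        logger.warning("network %s: no admissible risk-score cut; dropped",
                       network.center_mirna)
        return None
    network.cutpoint, network.logrank_stat, network.logrank_p = cut, stat, p
    return network


def select_biomarkers(
    networks: list[StarNetwork], c_min: float = 0.6, alpha_adj: float = 0.01
) -> list[StarNetwork]:
    """BH-adjust network log-rank p across networks and apply both gates.

    A network is a biomarker when C-index > c_min AND adjusted p <
    alpha_adj. All input networks get ``logrank_p_adj`` and ``selected``
    filled; the selected subset is returned sorted by raw p.
    """
    evaluated = [n for n in networks if np.isfinite(n.logrank_p)]
    if not evaluated:
        return []
    adj = bh_adjust([n.logrank_p for n in evaluated])
    for n, a in zip(evaluated, adj):
        n.logrank_p_adj = float(a)
        n.selected = bool((n.c_index > c_min) and (a < alpha_adj))
    return sorted((n for n in evaluated if n.selected), key=lambda n: n.logrank_p)


def networks_to_graphml(
    networks: list[StarNetwork], annotation: pd.Series | None = None
) -> nx.Graph:
    """Export networks as one graph: nodes carry biotype, edges beta and p.

    RNA nodes shared between stars appear once (node identity dedup happens
    here, not in the star objects).
    """
    g = nx.Graph()
    for net in networks:
        g.add_node(net.center_mirna, biotype="miRNA", center="true")
        for m in net.members:
            biotype = ""
            if annotation is not None and m.rna in annotation.index:
                biotype = str(annotation[m.rna])
            if m.rna not in g:
                g.add_node(m.rna, biotype=biotype)
            g.add_edge(net.center_mirna, m.rna, beta=m.beta, logrank_p=m.logrank_p)
    return g


def networks_summary(networks: list[StarNetwork]) -> pd.DataFrame:
    """Biomarker summary table: network, #edges, HR, p, adjusted p, C-index."""
    return pd.DataFrame(
        [
            {
                "network": f"Network_{n.center_mirna}",
                "n_edges": len(n.members),
                "hr": n.hr,
                "logrank_p": n.logrank_p,
                "logrank_p_adj": n.logrank_p_adj,
                "c_index": n.c_index,
                "cutpoint": n.cutpoint,
                "selected": n.selected,
            }
            for n in networks
        ]
    )
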