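"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the structure of a TCGA-style RNA-seq cohort: one
set of normal samples plus four tumor classes (nonM, LNM_only, DM_only,
LNM_DM) with TNM fields consistent with each class, negative-binomial read
counts over miRNA / mRNA / lncRNA / pseudogene genes, 4-fold library-size
variation (so TMM is exercised non-trivially), planted class-specific
miRNA-RNA correlations, and overall survival driven by the latent
correlation-deviation signal of a prognostic hub miRNA.

Correlation planting: each planted pair (miRNA a, RNA b) with class
correlation rho draws the RNA's latent residual as
``e_b = rho' * e_a + sqrt(1 - rho'^2) * eps`` — a per-pair 2x2 latent
covariance embedded in an otherwise independent latent field. Because the
construction is a factor model on the shared miRNA residual it stays
positive definite even when several planted pairs share a center miRNA
(the hub); an RNA may be planted in at most one pair. Pearson correlations
downstream are computed on CPM (exponential) scale, which attenuates a
latent Gaussian correlation; the generator therefore plants the latent
rho' whose lognormal-scale correlation equals the configured target, so
targets are controlled on the scale the pipeline actually measures (up to
the small residual attenuation from count noise). Strong negative targets
are infeasible on the exponential scale and are rejected.

Survival: for tumor sample i the hub pair j contributes the deviation
signal u_ij = e_a,i * e_b,i - rho_normal_j (the per-sample quantity the
ΔPCC statistic estimates); the log hazard is the configured linear
combination of |u_ij| (centered), survival times are exponential, and a
configured fraction of samples is censored uniformly on (0, T). Hazard is
driven by the latent signal — not by ΔPCC itself — so recovering the hub
from ΔPCC is a genuine inference test rather than a circular one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlantedPair",
    "PrognosticHub",
    "SimConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "default_config",
    "null_config",
    "generate_cohort",
    "write_cohort",
    "score_recovery",
]

# one representative TNM assignment per class
_TNM = {
    "nonM": ("T2", "N0", "M0"),
    "LNM_only": ("T3", "N1", "M0"),
    "DM_only": ("T2", "N0", "M1"),
    "LNM_DM": ("T3", "N2", "M1"),
}


@dataclass(frozen=True)
class PlantedPair:
    """A miRNA-RNA pair with class-specific target correlations.

    rho_normal applies to normal samples, rho_neg to nonM tumors and
    rho_pos to the metastatic tumor classes.
    """

    mirna: str
    rna: str
    rho_normal: float
    rho_pos: float
    rho_neg: float

    def rho_for(self, sample_class: str) -> float:
        if sample_class == "normal":
            return self.rho_normal
        if sample_class == "nonM":
            return self.rho_neg
        return self.rho_pos


@dataclass(frozen=True)
class PrognosticHub:
    """Hub miRNA whose planted pairs carry true survival coefficients."""

    mirna: str
    rnas: tuple
    gammas: tuple  # true log-hazard coefficients on |u|, aligned with rnas


@dataclass
class SimConfig:
    seed: int
    n_normal: int = 30
    n_nonM: int = 200
    n_lnm_only: int = 200
    n_dm_only: int = 30
    n_lnm_dm: int = 30
    n_mirna: int = 10
    n_mrna: int = 14
    n_lncrna: int = 10
    n_pseudogene: int = 6
    n_other: int = 150  # background genes (biotype "other", never paired)
    n_low_expression: int = 5  # near-silent genes, removed by the count filter
    planted_pairs: list = field(default_factory=list)
    hub: PrognosticHub | None = None
    latent_sd: float = 0.5
    dispersion: float = 0.01
    library_size_range: tuple = (2e5, 8e5)  # 4-fold spread, uniform in log
    censoring_fraction: float = 0.3
    baseline_hazard: float = np.log(2) / 1100  # median survival ~3 years
    background_log_mean: float = np.log(100.0)
    background_log_sd: float = 1.0
    planted_log_mean: float = np.log(800.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        for p in self.planted_pairs:
            for rho in (p.rho_normal, p.rho_pos, p.rho_neg):
                if not -1 < rho < 1:
                    raise ValueError(
                        f"infeasible correlation {rho} in planted pair "
                        f"({p.mirna}, {p.rna}): latent 2x2 block not positive definite"
                    )
                _latent_rho(rho, self.latent_sd, pair=(p.mirna, p.rna))
        rnas = [p.rna for p in self.planted_pairs]
        if len(rnas) != len(set(rnas)):
            raise ValueError("an RNA may be planted in at most one pair")
        if self.hub is not None:
            planted = {(p.mirna, p.rna) for p in self.planted_pairs}
            for rna in self.hub.rnas:
                if (self.hub.mirna, rna) not in planted:
                    raise ValueError(
                        f"hub pair ({self.hub.mirna}, {rna}) is not planted"
                    )


def _latent_rho(target: float, latent_sd: float, pair=None) -> float:
    """Latent Gaussian correlation whose lognormal-scale correlation equals
    ``target``: rho' = log(1 + r (e^{s^2} - 1)) / s^2."""
    s2 = latent_sd**2
    arg = 1.0 + target * np.expm1(s2)
    rho = np.log(arg) / s2 if arg > 0 else -np.inf
    if not -1 < rho < 1:
        where = f" for pair {pair}" if pair else ""
        raise ValueError(
            f"target correlation {target} is infeasible on the count scale at "
            f"latent sd {latent_sd}{where}: latent block not positive definite"
        )
    return float(rho)


def _gene_names(config: SimConfig) -> dict[str, list[str]]:
    return {
        "miRNA": [f"MIR{i + 1:02d}" for i in range(config.n_mirna)],
        "mRNA": [f"MRNA{i + 1:02d}" for i in range(config.n_mrna)],
        "lncRNA": [f"LNC{i + 1:02d}" for i in range(config.n_lncrna)],
        "pseudogene": [f"PSG{i + 1:02d}" for i in range(config.n_pseudogene)],
        "other": [f"OTH{i + 1:03d}" for i in range(config.n_other)],
    }


def default_config(seed: int) -> SimConfig:
    """The standard planted-signal cohort.

    Ten differential pairs with a 0.7 correlation gap between metastatic
    and non-metastatic tumors (rho_pos = 0.8 vs rho_neg = 0.1, baseline
    rho_normal = 0.2); five of them share the hub miRNA MIR01, which
    carries the survival signal with coefficients >= 1.
    """
    hub_rnas = ("MRNA01", "MRNA02", "LNC01", "LNC02", "PSG01")
    planted = [
        PlantedPair("MIR01", rna, 0.2, 0.8, 0.1) for rna in hub_rnas
    ] + [
        PlantedPair("MIR02", "MRNA03", 0.2, 0.8, 0.1),
        PlantedPair("MIR03", "MRNA04", 0.2, 0.8, 0.1),
        PlantedPair("MIR04", "LNC03", 0.2, 0.8, 0.1),
        PlantedPair("MIR05", "LNC04", 0.2, 0.8, 0.1),
        PlantedPair("MIR06", "PSG02", 0.2, 0.8, 0.1),
    ]
    hub = PrognosticHub("MIR01", hub_rnas, (1.5, 1.25, 1.0, 1.0, 1.0))
    return SimConfig(seed=seed, planted_pairs=planted, hub=hub)


def null_config(seed: int, n_per_class: int = 100) -> SimConfig:
    """A no-signal cohort: no planted pairs, no hub, survival independent
    of expression. Two tumor classes of ``n_per_class`` each."""
    return SimConfig(
        seed=seed,
        n_nonM=n_per_class,
        n_lnm_only=n_per_class,
        n_dm_only=0,
        n_lnm_dm=0,
        planted_pairs=[],
        hub=None,
    )


@dataclass
class SyntheticTruth:
    planted_pairs: list
    hub: PrognosticHub | None
    sample_classes: dict  # sample_id -> class
    censoring_fraction: float
    seed: int

    def planted_set(self) -> set:
        return {(p.mirna, p.rna) for p in self.planted_pairs}

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "censoring_fraction": self.censoring_fraction,
            "planted_pairs": [asdict(p) for p in self.planted_pairs],
            "hub": None if self.hub is None else {
                "mirna": self.hub.mirna,
                "rnas": list(self.hub.rnas),
                "gammas": list(self.hub.gammas),
            },
            "sample_classes": self.sample_classes,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticCohort:
    counts: pd.DataFrame
    annotation: pd.Series
    clinical: pd.DataFrame
    truth: SyntheticTruth


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one cohort. Same config (incl. seed) -> identical output."""
    rng = np.random.default_rng(config.seed)
    names = _gene_names(config)
    genes = [g for group in names.values() for g in group]
    annotation = pd.Series(
        {g: bt for bt, group in names.items() for g in group}, name="biotype"
    )
    annotation.index.name = "gene_id"
    annotation = annotation.reindex(genes)

    class_sizes = {
        "normal": config.n_normal,
        "nonM": config.n_nonM,
        "LNM_only": config.n_lnm_only,
        "DM_only": config.n_dm_only,
        "LNM_DM": config.n_lnm_dm,
    }
    sample_ids, sample_class = [], []
    prefixes = {"normal": "N", "nonM": "T0", "LNM_only": "TL", "DM_only": "TD",
                "LNM_DM": "TB"}
    for cls, n in class_sizes.items():
        for i in range(n):
            sample_ids.append(f"{prefixes[cls]}{i + 1:04d}")
            sample_class.append(cls)
    n_samples = len(sample_ids)
    gene_idx = {g: i for i, g in enumerate(genes)}

    planted_genes = {p.mirna for p in config.planted_pairs} | {
        p.rna for p in config.planted_pairs
    }
    mu = np.where(
        [g in planted_genes for g in genes],
        config.planted_log_mean,
        config.background_log_mean
        + config.background_log_sd * rng.standard_normal(len(genes)),
    )
    # a handful of near-silent genes exercise the low-expression filter
    other_names = names["other"]
    for g in other_names[: min(config.n_low_expression, len(other_names))]:
        mu[gene_idx[g]] = np.log(0.002)

    # latent residual field: independent, then planted-pair RNAs replaced
    # by the factor construction on their miRNA's residual
    e = rng.standard_normal((len(genes), n_samples))
    eps = rng.standard_normal((len(config.planted_pairs), n_samples))
    class_arr = np.array(sample_class)
    for k, pair in enumerate(config.planted_pairs):
        a, b = gene_idx[pair.mirna], gene_idx[pair.rna]
        rho = np.array(
            [_latent_rho(pair.rho_for(c), config.latent_sd) for c in class_arr]
        )
        e[b] = rho * e[a] + np.sqrt(1 - rho**2) * eps[k]

    z = mu[:, None] + config.latent_sd * e
    rel = np.exp(z)
    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    mean = rel * (lib / np.exp(mu).sum())[None, :]
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mean * config.dispersion)
    counts = rng.poisson(lam).astype("int64")
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=sample_ids)

    clinical = _draw_clinical(config, rng, sample_ids, class_arr, e, gene_idx)
    truth = SyntheticTruth(
        planted_pairs=list(config.planted_pairs),
        hub=config.hub,
        sample_classes=dict(zip(sample_ids, sample_class)),
        censoring_fraction=config.censoring_fraction,
        seed=config.seed,
    )
    return SyntheticCohort(counts=counts_df, annotation=annotation,
                           clinical=clinical, truth=truth)


def _draw_clinical(config, rng, sample_ids, class_arr, e, gene_idx) -> pd.DataFrame:
    n = len(sample_ids)
    is_tumor = class_arr != "normal"
    log_hr = np.zeros(n)
    if config.hub is not None:
        a = gene_idx[config.hub.mirna]
        for rna, gamma in zip(config.hub.rnas, config.hub.gammas):
            b = gene_idx[rna]
            pair = next(p for p in config.planted_pairs
                        if p.mirna == config.hub.mirna and p.rna == rna)
            u = np.abs(e[a] * e[b] - _latent_rho(pair.rho_normal, config.latent_sd))
            log_hr += gamma * (u - u[is_tumor].mean())
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_true = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censoring_fraction
    os_time = np.where(censored, rng.random(n) * t_true, t_true)
    os_event = (~censored).astype(int)

    rows = []
    for i, (sid, cls) in enumerate(zip(sample_ids, class_arr)):
        if cls == "normal":
            rows.append((sid, "", "", "", True, "", ""))
        else:
            t, nst, m = _TNM[cls]
            rows.append((sid, t, nst, m, False,
                         round(float(os_time[i]), 2), int(os_event[i])))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "t_stage", "n_stage", "m_stage", "is_normal",
                 "os_time", "os_event"],
    ).set_index("sample_id")


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write counts/annotation/clinical TSVs and the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    cohort.counts.to_csv(paths["counts"], sep="\t")
    cohort.annotation.to_frame().to_csv(paths["annotation"], sep="\t")
    cohort.clinical.to_csv(paths["clinical"], sep="\t")
    paths["truth"].write_text(cohort.truth.to_json() + "\n")
    return paths


@dataclass
class RecoveryReport:
    sensitivity: float
    false_discovery_proportion: float
    hub_recovered: bool
    n_kept: int


def score_recovery(
    truth: SyntheticTruth,
    screen_result: pd.DataFrame | None = None,
    selected_networks=None,
) -> RecoveryReport:
    """Score a pipeline run against the planted ground truth.

    ``screen_result`` is the Wilcoxon screen frame (or any frame indexed by
    (mirna, rna) with a boolean ``kept`` column); ``selected_networks`` is
    the output of select_biomarkers. Sensitivity and false-discovery
    proportion refer to planted pairs; hub recovery means a selected
    network centered at the true hub miRNA.
    """
    planted = truth.planted_set()
    sens, fdp, n_kept = float("nan"), float("nan"), 0
    if screen_result is not None:
        kept = set(screen_result.index[screen_result["kept"]])
        known = {(m, r) for m, r in kept}
        universe_ok = all(isinstance(m, str) and isinstance(r, str) for m, r in known)
        if not universe_ok:
            raise ValueError("screen result index must be (mirna, rna) string pairs")
        n_kept = len(known)
        if planted:
            sens = len(known & planted) / len(planted)
        fdp = (len(known - planted) / n_kept) if n_kept else 0.0
    hub_recovered = False
    if selected_networks is not None and truth.hub is not None:
        hub_recovered = any(
            n.center_mirna == truth.hub.mirna for n in selected_networks
        )
    return RecoveryReport(
        sensitivity=sens,
        false_discovery_proportion=fdp,
        hub_recovered=hub_recovered,
        n_kept=n_kept,
    )
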