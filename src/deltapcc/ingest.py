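"""Reading expression, annotation and clinical tables; TNM-based sample classes.

The cohort model distinguishes five sample classes: ``normal`` tissue and
four tumor classes defined by TNM staging — no metastasis (``nonM``: T1-4,
N0, M0), lymph-node metastasis only (``LNM_only``: T1-4, N1-3, M0), distant
metastasis only (``DM_only``: T1-4, N0, M1), and both (``LNM_DM``: T1-4,
N1-3, M1). Two binary tasks are derived from the classes:

* LNM task — positives: LNM_only + LNM_DM; negatives: nonM; DM_only and
  normals are excluded.
* DM task — positives: DM_only + LNM_DM; negatives: nonM + LNM_only;
  normals are excluded.

Clinical TNM strings such as "T2b", "N1mi" or "MX" are reduced to their
leading digit; an "X" or missing stage makes a tumor sample unclassifiable
and it is dropped from classification (but normals are always retained for
the correlation baseline).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleClass",
    "read_counts",
    "write_counts",
    "read_annotation",
    "read_clinical",
    "classify_sample",
    "classify_cohort",
    "assign_labels",
    "check_cohort_eligibility",
]

BIOTYPES = frozenset({"miRNA", "lncRNA", "mRNA", "pseudogene", "other"})
RNA_BIOTYPES = ("mRNA", "lncRNA", "pseudogene")


class SampleClass(str, enum.Enum):
    normal = "normal"
    nonM = "nonM"
    LNM_only = "LNM_only"
    DM_only = "DM_only"
    LNM_DM = "LNM_DM"
    unclassifiable = "unclassifiable"


def read_counts(path) -> pd.DataFrame:
    """Read a raw read-count matrix (genes x samples) from TSV.

    First column holds gene ids, header row holds sample ids. Counts must be
    non-negative integers; duplicate gene or sample ids, negative or
    non-integer entries, and ragged rows are rejected with messages naming
    the offender.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValueError(f"malformed count TSV {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        g, s = _first_bad_cell(bad)
        raise ValueError(f"non-numeric count at gene {g!r}, sample {s!r}")
    neg = numeric < 0
    if neg.any().any():
        g, s = _first_bad_cell(neg)
        raise ValueError(
            f"negative count {numeric.loc[g, s]} at gene {g!r}, sample {s!r}"
        )
    frac = (numeric % 1) != 0
    if frac.any().any():
        g, s = _first_bad_cell(frac)
        raise ValueError(
            f"non-integer count {numeric.loc[g, s]} at gene {g!r}, sample {s!r}"
        )
    out = numeric.astype("int64")
    out.index.name = "gene_id"
    return out


def _first_bad_cell(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return str(gene), str(sample)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_annotation(path) -> pd.Series:
    """Read gene_id -> biotype mapping from a 2-column TSV or a GTF/GFF file.

    GTF records are recognized by a ``gene_biotype``/``gene_type`` attribute
    plus ``gene_id``; biotypes outside the four used downstream collapse to
    "other" (such genes are dropped before pairing).
    """
    path = str(path)
    if path.endswith((".gtf", ".gff", ".gff3")):
        return _annotation_from_gtf(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "biotype" not in cols:
        raise ValueError("annotation TSV needs columns gene_id and biotype")
    ann = df.set_index(cols["gene_id"])[cols["biotype"]]
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dups}")
    unknown = set(ann.unique()) - BIOTYPES
    if unknown:
        raise ValueError(f"unknown biotypes in annotation: {sorted(unknown)}")
    ann.name = "biotype"
    ann.index.name = "gene_id"
    return ann


_GTF_ID = re.compile(r'gene_id "([^"]+)"')
_GTF_BIOTYPE = re.compile(r'gene_(?:bio)?type "([^"]+)"')
# Ensembl biotype vocabulary -> the four-way split used downstream
_BIOTYPE_MAP = {
    "miRNA": "miRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
}


def _annotation_from_gtf(path: str) -> pd.Series:
    records: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            gid = _GTF_ID.search(fields[8])
            bt = _GTF_BIOTYPE.search(fields[8])
            if gid is None or bt is None:
                continue
            raw = bt.group(1)
            if raw in _BIOTYPE_MAP:
                biotype = _BIOTYPE_MAP[raw]
            elif "pseudogene" in raw:
                biotype = "pseudogene"
            else:
                biotype = "other"
            records[gid.group(1)] = biotype
    if not records:
        raise ValueError(f"no gene records with biotype attributes in {path}")
    ann = pd.Series(records, name="biotype")
    ann.index.name = "gene_id"
    return ann


def read_clinical(path) -> pd.DataFrame:
    """Read the per-sample clinical table.

    Expected columns: sample_id, t_stage, n_stage, m_stage, is_normal,
    os_time (days), os_event. Stages may be TNM strings ("T2b", "N1mi",
    "MX") or bare digits; normals need no TNM.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "t_stage", "n_stage", "m_stage", "is_normal", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in clinical table: {dups}")
    out = df.set_index("sample_id")
    out["is_normal"] = out["is_normal"].str.lower().isin({"true", "1", "yes"})
    out["os_time"] = pd.to_numeric(out["os_time"], errors="coerce")
    out["os_event"] = pd.to_numeric(out["os_event"], errors="coerce").fillna(0).astype(bool)
    if (out["os_time"].dropna() < 0).any():
        raise ValueError("negative os_time in clinical table")
    return out


_STAGE_DIGIT = re.compile(r"^[TNMtnm]?\s*(\d)")


def parse_stage(value) -> int | None:
    """Leading digit of a TNM stage string; None for missing/'X' stages."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"nan", "x", "tx", "nx", "mx", "na"}:
        return None
    m = _STAGE_DIGIT.match(s)
    return int(m.group(1)) if m else None


def classify_sample(
    t_stage, n_stage, m_stage, is_normal: bool = False
) -> SampleClass:
    """Map one sample's TNM staging to its five-way class."""
    if is_normal:
        return SampleClass.normal
    t, n, m = parse_stage(t_stage), parse_stage(n_stage), parse_stage(m_stage)
    if t is None or n is None or m is None:
        return SampleClass.unclassifiable
    if not (1 <= t <= 4) or not (0 <= n <= 3) or m not in (0, 1):
        return SampleClass.unclassifiable
    if n == 0 and m == 0:
        return SampleClass.nonM
    if n >= 1 and m == 0:
        return SampleClass.LNM_only
    if n == 0 and m == 1:
        return SampleClass.DM_only
    return SampleClass.LNM_DM


def classify_cohort(clinical: pd.DataFrame) -> pd.Series:
    """Classify every sample; unclassifiable tumor samples are logged."""
    classes = pd.Series(
        [
            classify_sample(r.t_stage, r.n_stage, r.m_stage, bool(r.is_normal))
            for r in clinical.itertuples()
        ],
        index=clinical.index,
        name="sample_class",
    )
    n_bad = int((classes == SampleClass.unclassifiable).sum())
    if n_bad:
        logger.warning("%d tumor samples unclassifiable (missing/X TNM stage)", n_bad)
    return classes


@dataclass
class EligibilityReport:
    eligible: bool
    reasons: list[str]
    class_counts: dict[str, int]


def check_cohort_eligibility(
    classes: pd.Series, min_lnm: int = 50, min_normal: int = 10
) -> EligibilityReport:
    """Advisory cohort-selection rule: >= 50 LNM tumors and >= 10 normals."""
    counts = classes.value_counts()
    n_lnm = int(counts.get(SampleClass.LNM_only, 0) + counts.get(SampleClass.LNM_DM, 0))
    n_normal = int(counts.get(SampleClass.normal, 0))
    reasons = []
    if n_lnm < min_lnm:
        reasons.append(f"LNM < {min_lnm}")
    if n_normal < min_normal:
        reasons.append(f"normals < {min_normal}")
    return EligibilityReport(
        eligible=not reasons,
        reasons=reasons,
        class_counts={k.value: int(v) for k, v in counts.items()},
    )


def assign_labels(classes: pd.Series, task: str) -> pd.Series:
    """Per-sample task labels: 'positive', 'negative' or 'excluded'.

    ``task`` is "LNM" or "DM". Unclassifiable samples are excluded. Raises
    if either the positive or the negative set comes out empty.
    """
    task = task.upper()
    if task == "LNM":
        pos = {SampleClass.LNM_only, SampleClass.LNM_DM}
        neg = {SampleClass.nonM}
    elif task == "DM":
        pos = {SampleClass.DM_only, SampleClass.LNM_DM}
        neg = {SampleClass.nonM, SampleClass.LNM_only}
    else:
        raise ValueError(f"unknown task {task!r}; expected 'LNM' or 'DM'")
    labels = pd.Series("excluded", index=classes.index, name=f"label_{task}")
    labels[classes.isin(pos)] = "positive"
    labels[classes.isin(neg)] = "negative"
    n_pos = int((labels == "positive").sum())
    n_neg = int((labels == "negative").sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"task {task} infeasible for this cohort: "
            f"{n_pos} positive and {n_neg} negative samples"
        )
    return labels
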