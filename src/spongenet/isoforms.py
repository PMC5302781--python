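"""Isoform-level titration analysis.

Given paired per-patient FPKM tables of a gene's transcript isoforms in
normal and cancer tissue, this module implements the downstream analysis
of how the isoform mix shifts between conditions:

* a paired Student's t-test filter for isoforms with significant
  fold-changes;
* each isoform's share of the gene's total abundance per condition;
* the variation matrix (per-patient cancer-minus-normal differences,
  observations = isoforms, variables = patients) and its covariance PCA
  (scores and factors in the classical sense);
* the ratio of an isoform's abundance to a reference miRNA's abundance,
  the quantity whose collapse in cancer signals a broken titration
  balance (a sponge isoform overwhelmed by its miRNA);
* a per-exon usage comparison on normalized read counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import EmptyResultError
from .seeds import MiRNASeed, count_sites

logger = logging.getLogger(__name__)


@dataclass
class IsoformTable:
    """Paired isoform FPKM tables: rows = isoforms, columns = patients."""

    normal: pd.DataFrame
    cancer: pd.DataFrame
    site_annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.normal.index) != list(self.cancer.index):
            raise ValueError("conditions must list the same isoforms")
        if set(self.normal.columns) != set(self.cancer.columns):
            unpaired = set(self.normal.columns) ^ set(self.cancer.columns)
            raise ValueError(f"unpaired patients: {sorted(unpaired)}")
        self.cancer = self.cancer[self.normal.columns]
        if (self.normal.to_numpy() < 0).any() or (self.cancer.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.normal.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.normal.columns)

    def condition(self, condition: str) -> pd.DataFrame:
        if condition not in ("normal", "cancer"):
            raise ValueError(f"unknown condition {condition!r}")
        return self.normal if condition == "normal" else self.cancer

    def subset(self, isoform_ids: Sequence[str]) -> "IsoformTable":
        ids = list(isoform_ids)
        return IsoformTable(
            self.normal.loc[ids], self.cancer.loc[ids],
            {i: set(s) for i, s in self.site_annotations.items() if i in ids},
        )


@dataclass
class PairedProfile:
    """One entity's per-patient profile in both conditions."""

    normal: pd.Series
    cancer: pd.Series


def read_isoform_table(
    normal_path: str | Path,
    cancer_path: str | Path,
    site_annotations: Mapping[str, set[str]] | None = None,
) -> IsoformTable:
    """Read per-condition isoform FPKM TSVs (rows isoforms, columns patients)."""
    normal = pd.read_csv(normal_path, sep="\t", index_col=0)
    cancer = pd.read_csv(cancer_path, sep="\t", index_col=0)
    return IsoformTable(normal, cancer, dict(site_annotations or {}))


def write_isoform_table(table: IsoformTable, normal_path, cancer_path) -> None:
    table.normal.to_csv(normal_path, sep="\t", index_label="isoform_id")
    table.cancer.to_csv(cancer_path, sep="\t", index_label="isoform_id")


def annotate_sites(
    table: IsoformTable, sequences: Mapping[str, str], seeds: Sequence[MiRNASeed]
) -> IsoformTable:
    """Mark, per isoform, the miRNAs whose 6-mer match site its sequence carries."""
    for iso in table.isoform_ids:
        seq = sequences.get(iso)
        if seq is None:
            continue
        table.site_annotations[iso] = {
            s.mirna_id for s in seeds if count_sites(seq, s.match_site) > 0
        }
    return table


def paired_ttest(normal, cancer, paired: bool = True) -> float:
    """Two-sided Student's t-test p-value between the conditions.

    Paired by default (the design is matched samples); ``paired=False``
    switches to the unpaired (Welch) variant for sensitivity checks.
    All-zero differences carry no evidence against the null and return 1
    by convention; constant non-zero differences return 0 (the t statistic
    diverges).
    """
    normal = np.asarray(normal, dtype=float)
    cancer = np.asarray(cancer, dtype=float)
    if normal.shape != cancer.shape:
        raise ValueError("profiles must be paired (equal length)")
    if normal.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = cancer - normal
    if np.all(diffs == diffs[0]):
        return 1.0 if diffs[0] == 0 else 0.0
    if not paired:
        return float(sps.ttest_ind(cancer, normal, equal_var=False).pvalue)
    return float(sps.ttest_rel(cancer, normal).pvalue)


def filter_isoforms(
    table: IsoformTable, alpha: float = 0.05, paired: bool = True
) -> IsoformTable:
    """Retain isoforms whose t-test p-value is strictly below alpha."""
    pvals = {
        iso: paired_ttest(table.normal.loc[iso], table.cancer.loc[iso], paired)
        for iso in table.isoform_ids
    }
    kept = [iso for iso, p in pvals.items() if p < alpha]
    for iso, p in pvals.items():
        logger.info("t-test filter: %s p=%.4g %s", iso, p,
                    "kept" if iso in kept else "dropped")
    if not kept:
        raise EmptyResultError("no isoform passed the t-test filter")
    return table.subset(kept)


def abundance_shares(table: IsoformTable, condition: str) -> pd.Series:
    """Each isoform's percentage of the gene's total abundance in a condition.

    Mean FPKM per isoform over the condition's patients, normalised to sum
    to 100%.
    """
    means = table.condition(condition).mean(axis=1)
    total = means.sum()
    if total <= 0:
        raise ValueError(f"total abundance in {condition!r} is zero")
    return 100.0 * means / total


def variation_matrix(table: IsoformTable) -> pd.DataFrame:
    """Per-patient expression variation: cancer minus normal.

    Rows = isoforms (observations), columns = patients (variables).
    """
    return table.cancer - table.normal


@dataclass
class PCAResult:
    """Covariance PCA of an observations x variables matrix.

    ``factors`` (variables x components) is the orthonormal change of
    basis; ``scores`` (observations x components) the representation of
    the column-mean-centered data in that basis, so
    ``centered data = scores @ factors.T``.
    """

    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    factors: pd.DataFrame


def pca(data: pd.DataFrame | np.ndarray) -> PCAResult:
    """Classical covariance PCA via SVD of the column-centered matrix.

    Components are ordered by decreasing eigenvalue; each factor column's
    sign is fixed so its largest-magnitude entry is positive.  Raises on
    data with no variation (explained fractions undefined).
    """
    frame = isinstance(data, pd.DataFrame)
    x = data.to_numpy(dtype=float) if frame else np.asarray(data, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total <= 0:
        raise ValueError("data has no variation; explained fractions undefined")
    # sign convention: largest-|.| entry of each factor positive
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = centered @ vt.T
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    obs_index = data.index if frame else pd.RangeIndex(n)
    var_index = data.columns if frame else pd.RangeIndex(p)
    return PCAResult(
        eigenvalues=eig,
        explained_variance_ratio=eig / total,
        scores=pd.DataFrame(scores, index=obs_index, columns=comp_names),
        factors=pd.DataFrame(vt.T, index=var_index, columns=comp_names),
    )


@dataclass
class RatioResult:
    """An isoform's abundance relative to a reference miRNA in one condition."""

    condition: str
    ratio: float
    per_patient: pd.Series
    p_vs_other_condition: float


def ratio_to_mirna(
    table: IsoformTable,
    isoform_id: str,
    mirna: PairedProfile,
    condition: str,
) -> RatioResult:
    """Isoform-to-miRNA mean abundance ratio in one condition.

    Also returns the per-patient ratio distribution and the paired t-test
    p-value comparing the per-patient ratios between the two conditions.
    """
    iso = table.condition(condition).loc[isoform_id]
    mir = getattr(mirna, condition).loc[table.patient_ids]
    if mir.mean() <= 0:
        raise ValueError(f"miRNA mean abundance in {condition!r} is not positive")
    other = "cancer" if condition == "normal" else "normal"
    iso_o = table.condition(other).loc[isoform_id]
    mir_o = getattr(mirna, other).loc[table.patient_ids]
    with np.errstate(divide="ignore", invalid="ignore"):
        per_patient = iso / mir
        per_patient_o = iso_o / mir_o
    finite = np.isfinite(per_patient) & np.isfinite(per_patient_o)
    p = paired_ttest(per_patient_o[finite], per_patient[finite])
    return RatioResult(
        condition=condition,
        ratio=float(iso.mean() / mir.mean()),
        per_patient=per_patient,
        p_vs_other_condition=p,
    )


def titration_report(
    table: IsoformTable,
    mirna: PairedProfile | None = None,
    reference_mirna: str = "",
) -> pd.DataFrame:
    """Per-isoform summary: means, shares, fold change, t-test p, ratios."""
    shares_n = abundance_shares(table, "normal")
    shares_c = abundance_shares(table, "cancer")
    rows = []
    for iso in table.isoform_ids:
        mean_n = float(table.normal.loc[iso].mean())
        mean_c = float(table.cancer.loc[iso].mean())
        row = {
            "isoform_id": iso,
            "mean_normal": mean_n,
            "mean_cancer": mean_c,
            "share_normal_pct": float(shares_n[iso]),
            "share_cancer_pct": float(shares_c[iso]),
            "fold_change": mean_c / mean_n if mean_n > 0 else float("nan"),
            "ttest_p": paired_ttest(table.normal.loc[iso], table.cancer.loc[iso]),
            "site_mirnas": ";".join(sorted(table.site_annotations.get(iso, set()))),
        }
        if mirna is not None:
            for cond in ("normal", "cancer"):
                res = ratio_to_mirna(table, iso, mirna, cond)
                row[f"ratio_to_{reference_mirna or 'mirna'}_{cond}"] = res.ratio
        rows.append(row)
    return pd.DataFrame(rows).set_index("isoform_id")


def write_titration_report(report: pd.DataFrame, tsv_path, json_path=None) -> None:
    report.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(json.loads(report.to_json(orient="index")), fh, indent=2)


def exon_usage_comparison(
    exon_counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-exon fold change and paired t-test between conditions.

    ``exon_counts``: normalized counts, rows = exons, columns = samples.
    ``samples``: sample annotation (index sample_id, columns patient_id and
    condition).  Exons with mean-cancer/mean-normal fold > 1 and p < alpha
    are flagged; exons with zero normal mean get an undefined fold and are
    flagged separately.
    """
    meta = samples.loc[list(exon_counts.columns)]
    normal_cols = meta.index[meta["condition"] == "normal"]
    cancer_cols = meta.index[meta["condition"] == "cancer"]
    order = meta.loc[normal_cols, "patient_id"]
    cancer_by_patient = {
        meta.loc[s, "patient_id"]: s for s in cancer_cols
    }
    try:
        paired_cancer = [cancer_by_patient[p] for p in order]
    except KeyError as exc:
        raise ValueError(f"unpaired patient {exc.args[0]!r}") from None
    rows = []
    for exon in exon_counts.index:
        n_vals = exon_counts.loc[exon, normal_cols].to_numpy(float)
        c_vals = exon_counts.loc[exon, paired_cancer].to_numpy(float)
        mean_n, mean_c = n_vals.mean(), c_vals.mean()
        fold = mean_c / mean_n if mean_n > 0 else float("nan")
        p = paired_ttest(n_vals, c_vals)
        rows.append(
            {
                "exon": exon,
                "mean_normal": mean_n,
                "mean_cancer": mean_c,
                "fold": fold,
                "p": p,
                "upregulated": bool(np.isfinite(fold) and fold > 1 and p < alpha),
                "fold_undefined": not np.isfinite(fold),
            }
        )
    return pd.DataFrame(rows).set_index("exon")
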