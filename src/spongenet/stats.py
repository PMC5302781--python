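"""Correlation statistics and enrichment test defining sponge candidate triplets.

For a candidate triplet (mRNA X, lncRNA Y, miRNA Z) the mediation of the
X-Y co-expression by Z is scored with the sensitivity correlation

    S = rho_XY - rho_XY|Z,

where rho_XY|Z is the first-order partial correlation

    rho_XY|Z = (rho_XY - rho_XZ * rho_ZY) / sqrt((1 - rho_XZ^2)(1 - rho_ZY^2)).

A large S means conditioning on the miRNA removes much of the X-Y
correlation, the signature of miRNA-mediated (sponge) co-expression.
Candidates must additionally be enriched in the shared miRNA's 6-mer
match sites (one-sided hypergeometric test over 6-mer windows).

Correlations are computed on FPKM values as provided (no log transform by
default) on pairwise-complete observations; undefined quantities (zero
variance, too few joint observations, |rho|=1 in the conditioning set)
are reported as NaN, never silently coerced to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix
from .seeds import SeedMatchIndex

logger = logging.getLogger(__name__)

_MIN_JOINT_OBS = 3
_VAR_EPS = 1e-300


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation on pairwise-complete observations.

    Returns NaN when either profile has zero variance or fewer than three
    complete pairs remain (undefined, as distinct from uncorrelated).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < _MIN_JOINT_OBS:
        return float("nan")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def partial_correlation(rho_xy: float, rho_xz: float, rho_zy: float) -> float:
    """First-order partial correlation of X and Y given Z.

    NaN when either conditioning correlation has magnitude 1 (the partial
    correlation is undefined) or any input is NaN.
    """
    if any(np.isnan(v) for v in (rho_xy, rho_xz, rho_zy)):
        return float("nan")
    denom_sq = (1.0 - rho_xz**2) * (1.0 - rho_zy**2)
    if denom_sq <= 0:
        return float("nan")
    return (rho_xy - rho_xz * rho_zy) / np.sqrt(denom_sq)


def sensitivity(rho_xy: float, rho_xy_given_z: float) -> float:
    """Sensitivity correlation S: the drop in correlation when Z is removed."""
    return rho_xy - rho_xy_given_z


def _corr_rows_vs_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` against every row of ``b``.

    Pairwise-complete over missing values; undefined entries are NaN.
    Shapes: a (m, s), b (l, s) -> (m, l).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not np.isnan(a).any() and not np.isnan(b).any():
        az = a - a.mean(axis=1, keepdims=True)
        bz = b - b.mean(axis=1, keepdims=True)
        sa = np.sqrt((az**2).sum(axis=1))
        sb = np.sqrt((bz**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (az @ bz.T) / np.outer(sa, sb)
        r[sa <= _VAR_EPS, :] = np.nan
        r[:, sb <= _VAR_EPS] = np.nan
        return np.clip(r, -1.0, 1.0)
    out = np.empty((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        out[i] = _corr_profile_vs_matrix(a[i], b)
    return out


def _corr_profile_vs_matrix(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Pearson of one profile against each row of a matrix, pairwise-complete."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    xm = np.broadcast_to(x, m.shape)
    mask = ~(np.isnan(xm) | np.isnan(m))
    n = mask.sum(axis=1)
    xs = np.where(mask, xm, 0.0)
    ms = np.where(mask, m, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = xs.sum(axis=1) / n
        mean_m = ms.sum(axis=1) / n
        cov = (xs * ms).sum(axis=1) / n - mean_x * mean_m
        var_x = (xs**2).sum(axis=1) / n - mean_x**2
        var_m = (ms**2).sum(axis=1) / n - mean_m**2
        r = cov / np.sqrt(var_x * var_m)
    r[(n < _MIN_JOINT_OBS) | (var_x <= 1e-14) | (var_m <= 1e-14)] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlation_matrix(
    mrna_expr: ExpressionMatrix, lnc_expr: ExpressionMatrix
) -> pd.DataFrame:
    """All mRNA x lncRNA Pearson correlations (rows mRNA, columns lncRNA)."""
    if list(mrna_expr.sample_ids) != list(lnc_expr.sample_ids):
        raise ValueError("matrices must share sample ordering")
    r = _corr_rows_vs_rows(
        mrna_expr.values.to_numpy(float), lnc_expr.values.to_numpy(float)
    )
    return pd.DataFrame(r, index=mrna_expr.entity_ids, columns=lnc_expr.entity_ids)


def select_top_pairs(
    mrna_expr: ExpressionMatrix,
    lnc_expr: ExpressionMatrix,
    percentile: float = 99.0,
) -> list[tuple[str, str, float]]:
    """Select mRNA/lncRNA pairs above the given percentile of all correlations.

    The threshold is the empirical ``percentile`` of the full correlation
    distribution; pairs strictly above it are returned sorted by
    descending correlation.
    """
    corr = correlation_matrix(mrna_expr, lnc_expr)
    flat = corr.to_numpy().ravel()
    flat = flat[~np.isnan(flat)]
    if flat.size == 0:
        return []
    if flat.size < 100 and percentile >= 99:
        logger.warning(
            "only %d defined correlations; percentile %g is coarse",
            flat.size, percentile,
        )
    threshold = float(np.percentile(flat, percentile))
    stacked = corr.stack()
    selected = stacked[stacked > threshold].sort_values(ascending=False)
    logger.info(
        "top-pair selection: threshold rho > %.4f keeps %d of %d pairs",
        threshold, len(selected), flat.size,
    )
    return [(x, y, float(r)) for (x, y), r in selected.items()]


@dataclass
class SpongeTriplet:
    """One (mRNA X, lncRNA Y, miRNA Z) candidate with its statistics."""

    x_id: str
    y_id: str
    z_id: str
    rho_xy: float
    rho_xz: float
    rho_zy: float
    rho_xy_given_z: float
    sensitivity: float
    shared_site_counts: tuple[int, int] | None = None
    enrichment_p: float | None = None


def triplet_scan(
    pairs: Sequence[tuple[str, str, float]],
    mrna_expr: ExpressionMatrix,
    lnc_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    s_threshold: float = 0.3,
) -> tuple[pd.DataFrame, list[SpongeTriplet]]:
    """Score every (pair, miRNA) combination with the sensitivity correlation.

    Returns the full sensitivity matrix (rows = pairs labelled ``x|y``,
    columns = miRNAs; NaN where undefined) and the triplets with
    S strictly above ``s_threshold``.
    """
    if not (
        list(mrna_expr.sample_ids) == list(lnc_expr.sample_ids) == list(mirna_expr.sample_ids)
    ):
        raise ValueError("matrices must share sample ordering")
    z_mat = mirna_expr.values.to_numpy(float)
    z_ids = mirna_expr.entity_ids
    rows = []
    triplets: list[SpongeTriplet] = []
    labels = []
    for x_id, y_id, rho_xy in pairs:
        x = mrna_expr.values.loc[x_id].to_numpy(float)
        y = lnc_expr.values.loc[y_id].to_numpy(float)
        rho_xz = _corr_profile_vs_matrix(x, z_mat)
        rho_zy = _corr_profile_vs_matrix(y, z_mat)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt((1.0 - rho_xz**2) * (1.0 - rho_zy**2))
            partial = (rho_xy - rho_xz * rho_zy) / denom
        partial[denom <= 0] = np.nan
        s_row = rho_xy - partial
        rows.append(s_row)
        labels.append(f"{x_id}|{y_id}")
        for j, z_id in enumerate(z_ids):
            if np.isnan(s_row[j]):
                continue
            if s_row[j] > s_threshold:
                triplets.append(
                    SpongeTriplet(
                        x_id, y_id, z_id,
                        rho_xy=float(rho_xy),
                        rho_xz=float(rho_xz[j]),
                        rho_zy=float(rho_zy[j]),
                        rho_xy_given_z=float(partial[j]),
                        sensitivity=float(s_row[j]),
                    )
                )
    matrix = pd.DataFrame(np.array(rows).reshape(len(labels), len(z_ids)),
                          index=labels, columns=z_ids)
    logger.info(
        "triplet scan: %d pairs x %d miRNAs -> %d triplets with S > %g",
        len(pairs), len(z_ids), len(triplets), s_threshold,
    )
    return matrix, triplets


def enrichment_test(
    x_id: str, y_id: str, z_id: str, index: SeedMatchIndex
) -> float:
    """One-sided hypergeometric enrichment of z's sites in the pair's sequences.

    Population: all 6-mer windows over the indexed transcripts (N), of
    which the occurrences of z's match site anywhere are the successes (K).
    Sample: the windows of X's 3'UTR plus Y's transcript (n), with their
    combined site count as the observation (k).  Returns P(X >= k).
    """
    n_pop = index.total_windows()
    k_pop = index.total_count(z_id)
    n_draw = index.windows[x_id] + index.windows[y_id]
    k_obs = index.count(x_id, z_id) + index.count(y_id, z_id)
    if k_pop > n_pop or k_obs > n_draw:
        raise ValueError(
            f"inconsistent index for ({x_id}, {y_id}, {z_id}): "
            f"K={k_pop}, N={n_pop}, k={k_obs}, n={n_draw}"
        )
    return float(sps.hypergeom.sf(k_obs - 1, n_pop, k_pop, n_draw))


def add_enrichment(
    triplets: Sequence[SpongeTriplet], index: SeedMatchIndex
) -> list[SpongeTriplet]:
    """Fill each triplet's shared-site counts and enrichment p-value in place."""
    for t in triplets:
        t.shared_site_counts = (
            index.count(t.x_id, t.z_id),
            index.count(t.y_id, t.z_id),
        )
        t.enrichment_p = enrichment_test(t.x_id, t.y_id, t.z_id, index)
    return list(triplets)


def triplets_to_frame(triplets: Sequence[SpongeTriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_id": t.x_id,
            "y_id": t.y_id,
            "z_id": t.z_id,
            "rho_xy": t.rho_xy,
            "rho_xz": t.rho_xz,
            "rho_zy": t.rho_zy,
            "rho_xy_given_z": t.rho_xy_given_z,
            "sensitivity": t.sensitivity,
            "sites_x": None if t.shared_site_counts is None else t.shared_site_counts[0],
            "sites_y": None if t.shared_site_counts is None else t.shared_site_counts[1],
            "enrichment_p": t.enrichment_p,
        }
        for t in triplets
    )
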