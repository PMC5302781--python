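"""Synthetic data with the statistical structure the sponge analysis assumes.

The expression model is log-normal throughout (FPKM is strictly positive
and right-skewed) with miRNA repression acting multiplicatively, i.e.
linearly in log space.  For each planted sponge triplet, with G the
standardized log-abundance of the miRNA Z:

    log Z = mu_Z + s * G
    log X = mu_X - gamma * G + sigma * N1
    log Y = mu_Y - gamma * G + sigma * N2

so the mRNA X and the lncRNA Y are co-expressed *only* through the shared
miRNA; conditioning on Z removes the correlation, giving a large
sensitivity correlation.  Confounded pairs replace G by a latent factor
the miRNAs know nothing about: they are just as correlated but show
S ~ 0, mirroring co-expression from a shared transcriptional program
rather than a sponge interaction.  All three pairwise Pearson
correlations of a planted triplet have closed forms under this model
(moments of the bivariate log-normal), exposed by
:func:`expected_triplet_correlations` for calibration checks.

Sequences are uniform-random DNA with the mediating miRNA's 6-mer match
site planted into both members of each sponge pair; confounded pairs get
no planted sites.

The defaults encode the study conditions the analysis is meant for:
72 matched patients, miRNAs up-regulated 4- to 8-fold in cancer, the
sponge gene's total abundance roughly doubling, and miRNA-mediation
switched off in the cancer condition (the sponge program breaks down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    TranscriptSequence,
    write_expression,
    write_fasta,
    write_sample_table,
)
from .isoforms import IsoformTable, PairedProfile
from .seeds import MiRNASeed, SEED_LENGTH

_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))


@dataclass
class SynthParams:
    """Parameters of the synthetic generators (a pure function of the seed)."""

    n_patients: int = 72
    n_sponge_triplets: int = 50
    n_confounded_pairs: int = 50
    n_background_entities: int = 50  # per RNA class (mRNA and lncRNA)
    n_background_mirnas: int = 10
    repression_strength: float = 0.3   # gamma: log-scale repression slope
    noise_dispersion: float = 0.15     # sigma: log-scale residual sd
    mirna_dispersion: float = 0.15     # s: sd of log miRNA abundance
    latent_strength: float = 0.3       # confounded pairs' shared-factor slope
    n_hub_targets: int = 0  # >0 plants a super-sponge lncRNA with this many mRNA partners
    mirna_fold_range: tuple[float, float] = (4.0, 8.0)
    gene_fold: float = 2.0
    utr_length_range: tuple[int, int] = (600, 1500)
    lnc_length_range: tuple[int, int] = (800, 2000)
    planted_site_count: int = 3
    # isoform titration generator
    n_isoforms: int = 9
    dominant_share: float = 0.50
    site_share: float = 0.15
    site_fold: float = 1.3
    isoform_noise: float = 0.25
    mirna_mean_fpkm: float = 15.0
    total_fpkm: float = 100.0
    # exon-usage generator
    n_exons: int = 10
    exon_breakpoint: int = 5
    exon_fold: float = 2.0
    exon_nb_size: float = 10.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_patients, self.n_sponge_triplets, self.n_confounded_pairs,
            self.n_background_entities, self.n_background_mirnas,
            self.planted_site_count, self.n_isoforms, self.n_exons,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.mirna_fold_range[0] < 1 or self.gene_fold < 1:
            raise ValueError("fold ranges must be >= 1")
        if self.repression_strength < 0:
            raise ValueError("repression_strength must be >= 0")
        if self.exon_breakpoint >= self.n_exons:
            raise ValueError("exon breakpoint must fall before the last exon")


def expected_triplet_correlations(params: SynthParams) -> tuple[float, float, float]:
    """Population Pearson correlations (rho_XY, rho_XZ, rho_ZY) of a planted
    triplet in the normal condition, from bivariate log-normal moments:
    corr(e^U, e^V) = (e^cov(U,V) - 1) / sqrt((e^var(U) - 1)(e^var(V) - 1)).
    """
    g = params.repression_strength
    s = params.mirna_dispersion
    sig = params.noise_dispersion
    var_x = g**2 + sig**2
    ex = np.expm1(var_x)
    ez = np.expm1(s**2)
    rho_xy = np.expm1(g**2) / ex
    rho_xz = np.expm1(-g * s) / np.sqrt(ex * ez)
    return float(rho_xy), float(rho_xz), float(rho_xz)


# ---------------------------------------------------------------------------
# sponge (network) dataset
# ---------------------------------------------------------------------------

@dataclass
class SpongeDataset:
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    utr_sequences: list[TranscriptSequence]
    lnc_sequences: list[TranscriptSequence]
    mirna_seeds: list[MiRNASeed]
    utr_lengths: dict[str, int]
    truth: dict


def _sample_table(n_patients: int) -> pd.DataFrame:
    # all normal samples first, then all cancer: expression rows are stored
    # as the concatenation [normal block, cancer block]
    rows = [
        {"sample_id": f"P{i:03d}-N", "patient_id": f"P{i:03d}", "condition": "normal"}
        for i in range(n_patients)
    ] + [
        {"sample_id": f"P{i:03d}-C", "patient_id": f"P{i:03d}", "condition": "cancer"}
        for i in range(n_patients)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def _plant_sites(
    rng: np.random.Generator, sequence: str, site: str, count: int
) -> str:
    """Overwrite ``count`` non-overlapping 6-mer windows with the match site."""
    if count * SEED_LENGTH > len(sequence):
        raise ValueError(
            f"cannot plant {count} sites of {SEED_LENGTH} nt "
            f"in a sequence of {len(sequence)} nt"
        )
    seq = list(sequence)
    taken: list[int] = []
    while len(taken) < count:
        pos = int(rng.integers(0, len(sequence) - SEED_LENGTH + 1))
        if all(abs(pos - t) >= SEED_LENGTH for t in taken):
            taken.append(pos)
            seq[pos : pos + SEED_LENGTH] = site
    return "".join(seq)


def _random_mature_mirna(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(_RNA, size=length))


def simulate_sponge_dataset(params: SynthParams) -> SpongeDataset:
    """Paired normal/cancer expression matrices, sequences and ground truth.

    Normal condition: each planted triplet's X and Y are repressed by its
    miRNA (strength ``repression_strength``).  Cancer condition: the
    repression coupling is switched off and every miRNA is up-regulated by
    a factor drawn from ``mirna_fold_range`` — co-expression mediated by
    miRNAs exists only in normal tissue.  Confounded pairs are driven by a
    shared latent factor in both conditions.
    """
    root = np.random.SeedSequence(params.random_seed)
    rng_expr, rng_seq, rng_mir = [np.random.default_rng(s) for s in root.spawn(3)]

    n = params.n_patients
    samples = _sample_table(n)
    g, s, sig = params.repression_strength, params.mirna_dispersion, params.noise_dispersion

    mrna_rows: dict[str, np.ndarray] = {}
    lnc_rows: dict[str, np.ndarray] = {}
    mir_rows: dict[str, np.ndarray] = {}
    truth_triplets = []
    truth_confounded = []

    def lognormal_profile(mu: float, loading: float, factor_n, factor_c, rng):
        noise_n = rng.normal(size=n) * sig
        noise_c = rng.normal(size=n) * sig
        log_n = mu + loading * factor_n + noise_n
        log_c = mu + 0.0 * factor_c + noise_c  # coupling lost in cancer
        return np.concatenate([np.exp(log_n), np.exp(log_c)])

    # planted sponge triplets
    mirna_folds = {}
    for i in range(params.n_sponge_triplets):
        x_id, y_id, z_id = f"mRNA-sp{i:03d}", f"lnc-sp{i:03d}", f"miR-sp{i:03d}"
        g_norm = rng_expr.normal(size=n)
        g_canc = rng_expr.normal(size=n)
        mu_z = rng_expr.uniform(np.log(5), np.log(50))
        fold = rng_expr.uniform(*params.mirna_fold_range)
        mirna_folds[z_id] = fold
        z_n = np.exp(mu_z + s * g_norm)
        z_c = fold * np.exp(mu_z + s * g_canc)
        mir_rows[z_id] = np.concatenate([z_n, z_c])
        mu_x = rng_expr.uniform(np.log(2), np.log(100))
        mu_y = rng_expr.uniform(np.log(2), np.log(100))
        mrna_rows[x_id] = lognormal_profile(mu_x, -g, g_norm, g_canc, rng_expr)
        lnc_rows[y_id] = lognormal_profile(mu_y, -g, g_norm, g_canc, rng_expr)
        truth_triplets.append((x_id, y_id, z_id))

    # optional super-sponge hub: one lncRNA sequesters one miRNA shared
    # with many mRNAs, so every (target, hub) pair is mediated by it
    truth_hub: dict = {}
    if params.n_hub_targets > 0:
        hub_y, hub_z = "lnc-hub", "miR-hub"
        g_norm = rng_expr.normal(size=n)
        g_canc = rng_expr.normal(size=n)
        mu_z = rng_expr.uniform(np.log(5), np.log(50))
        fold = rng_expr.uniform(*params.mirna_fold_range)
        mirna_folds[hub_z] = fold
        mir_rows[hub_z] = np.concatenate(
            [np.exp(mu_z + s * g_norm), fold * np.exp(mu_z + s * g_canc)]
        )
        lnc_rows[hub_y] = lognormal_profile(
            rng_expr.uniform(np.log(2), np.log(100)), -g, g_norm, g_canc, rng_expr
        )
        hub_targets = []
        for i in range(params.n_hub_targets):
            x_id = f"mRNA-hub{i:03d}"
            mrna_rows[x_id] = lognormal_profile(
                rng_expr.uniform(np.log(2), np.log(100)), -g, g_norm, g_canc, rng_expr
            )
            truth_triplets.append((x_id, hub_y, hub_z))
            hub_targets.append(x_id)
        truth_hub = {"lncrna": hub_y, "mirna": hub_z, "targets": hub_targets}

    # confounded pairs: correlated in both conditions, no miRNA involved
    lam = params.latent_strength
    for i in range(params.n_confounded_pairs):
        x_id, y_id = f"mRNA-cf{i:03d}", f"lnc-cf{i:03d}"
        l_norm = rng_expr.normal(size=n)
        l_canc = rng_expr.normal(size=n)
        for rows, eid in ((mrna_rows, x_id), (lnc_rows, y_id)):
            mu = rng_expr.uniform(np.log(2), np.log(100))
            log_n = mu + lam * l_norm + rng_expr.normal(size=n) * sig
            log_c = mu + lam * l_canc + rng_expr.normal(size=n) * sig
            rows[eid] = np.concatenate([np.exp(log_n), np.exp(log_c)])
        truth_confounded.append((x_id, y_id))

    # independent background entities, dispersion matched to planted ones
    tau = np.sqrt(g**2 + sig**2)
    for i in range(params.n_background_entities):
        for rows, eid in (
            (mrna_rows, f"mRNA-bg{i:03d}"),
            (lnc_rows, f"lnc-bg{i:03d}"),
        ):
            mu = rng_expr.uniform(np.log(2), np.log(100))
            rows[eid] = np.exp(mu + rng_expr.normal(size=2 * n) * tau)
    for i in range(params.n_background_mirnas):
        mu = rng_expr.uniform(np.log(5), np.log(50))
        mir_rows[f"miR-bg{i:03d}"] = np.exp(mu + rng_expr.normal(size=2 * n) * s)

    cols = list(samples.index)

    def matrix(rows: dict[str, np.ndarray], role: str) -> ExpressionMatrix:
        values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        return ExpressionMatrix(values, role, samples)

    # sequences with planted sites
    seeds = [
        MiRNASeed(z_id, _random_mature_mirna(rng_mir)) for z_id in mir_rows
    ]
    site_of = {sd.mirna_id: sd.match_site for sd in seeds}
    utr_sequences, lnc_sequences = [], []
    planted_for: dict[str, str] = {}
    for x_id, y_id, z_id in truth_triplets:
        planted_for[x_id] = z_id
        planted_for[y_id] = z_id
    for eid in mrna_rows:
        length = int(rng_seq.integers(*params.utr_length_range))
        seq = _random_dna(rng_seq, length)
        if eid in planted_for:
            seq = _plant_sites(
                rng_seq, seq, site_of[planted_for[eid]], params.planted_site_count
            )
        utr_sequences.append(TranscriptSequence(eid, seq, role="mRNA-3'UTR"))
    for eid in lnc_rows:
        length = int(rng_seq.integers(*params.lnc_length_range))
        seq = _random_dna(rng_seq, length)
        if eid in planted_for:
            seq = _plant_sites(
                rng_seq, seq, site_of[planted_for[eid]], params.planted_site_count
            )
        lnc_sequences.append(TranscriptSequence(eid, seq, role="lncRNA-cDNA"))

    truth = {
        "triplets": truth_triplets,
        "confounded_pairs": truth_confounded,
        "mirna_folds": mirna_folds,
        "hub": truth_hub,
    }
    return SpongeDataset(
        mrna=matrix(mrna_rows, "mRNA"),
        lncrna=matrix(lnc_rows, "lncRNA"),
        mirna=matrix(mir_rows, "miRNA"),
        utr_sequences=utr_sequences,
        lnc_sequences=lnc_sequences,
        mirna_seeds=seeds,
        utr_lengths={t.id: t.length for t in utr_sequences},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# isoform titration dataset
# ---------------------------------------------------------------------------

@dataclass
class TitrationDataset:
    table: IsoformTable
    mirna: PairedProfile
    mirna_id: str
    truth: dict


def simulate_isoform_titration(params: SynthParams) -> TitrationDataset:
    """Paired isoform FPKM tables emulating a broken titration balance.

    One dominant isoform without the miRNA site (~``dominant_share`` of the
    gene's abundance) is up-regulated so the gene's total abundance rises
    by ``gene_fold``; one site-bearing isoform (~``site_share``) changes
    modestly (``site_fold``); the remaining isoforms are low-abundance
    with null changes.  The paired miRNA profile is up-regulated by a
    factor drawn from ``mirna_fold_range`` — so the site isoform's
    isoform/miRNA abundance ratio collapses in cancer while the gene as a
    whole goes up.
    """
    if params.n_isoforms < 3:
        raise ValueError("need at least 3 isoforms (dominant, site, background)")
    rng = np.random.default_rng(np.random.SeedSequence(params.random_seed).spawn(1)[0])
    n = params.n_patients
    patients = [f"P{i:03d}" for i in range(n)]

    total = params.total_fpkm
    mean_dom = params.dominant_share * total
    mean_site = params.site_share * total
    n_bg = params.n_isoforms - 2
    mean_bg = (1.0 - params.dominant_share - params.site_share) * total / n_bg

    # the dominant isoform absorbs whatever fold keeps the gene total at
    # gene_fold x while the site isoform moves by site_fold and background
    # isoforms stay put
    dom_cancer = params.gene_fold * total - params.site_fold * mean_site - n_bg * mean_bg
    if dom_cancer <= 0:
        raise ValueError("gene_fold too small for the planted share structure")

    iso_ids = ["iso-dom", "iso-site"] + [f"iso-bg{i:02d}" for i in range(n_bg)]
    means_n = [mean_dom, mean_site] + [mean_bg] * n_bg
    means_c = [dom_cancer, params.site_fold * mean_site] + [mean_bg] * n_bg

    sig = params.isoform_noise
    correction = np.exp(-(sig**2) / 2.0)  # keep E[FPKM] at the planted mean

    def draw(mean: float) -> np.ndarray:
        return mean * correction * np.exp(sig * rng.normal(size=n))

    normal = pd.DataFrame(
        [draw(m) for m in means_n], index=iso_ids, columns=patients
    )
    cancer = pd.DataFrame(
        [draw(m) for m in means_c], index=iso_ids, columns=patients
    )
    mir_fold = float(rng.uniform(*params.mirna_fold_range))
    mir_id = "miR-ref"
    mir_normal = pd.Series(draw(params.mirna_mean_fpkm), index=patients)
    mir_cancer = pd.Series(draw(mir_fold * params.mirna_mean_fpkm), index=patients)

    table = IsoformTable(
        normal, cancer, site_annotations={"iso-site": {mir_id}}
    )
    truth = {
        "site_isoform": "iso-site",
        "dominant_isoform": "iso-dom",
        "mirna_id": mir_id,
        "mirna_fold": mir_fold,
        "dominant_fold": dom_cancer / mean_dom,
        "site_fold": params.site_fold,
    }
    return TitrationDataset(table, PairedProfile(mir_normal, mir_cancer), mir_id, truth)


# ---------------------------------------------------------------------------
# exon-usage dataset
# ---------------------------------------------------------------------------

@dataclass
class ExonDataset:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: dict


def simulate_exon_counts(params: SynthParams) -> ExonDataset:
    """Negative-binomial-like exon counts, doubled past the breakpoint in cancer.

    Exons are numbered from 1; exons strictly after ``exon_breakpoint``
    have their cancer means multiplied by ``exon_fold`` (the skipped-exon
    up-regulation pattern).  Counts are gamma-Poisson draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.random_seed).spawn(2)[1])
    n = params.n_patients
    samples = _sample_table(n)
    r = params.exon_nb_size
    exon_ids = [f"exon{i + 1}" for i in range(params.n_exons)]
    base = rng.uniform(100, 400, size=params.n_exons)
    rows = []
    upregulated = []
    for i, exon in enumerate(exon_ids):
        mean_n = base[i]
        up = (i + 1) > params.exon_breakpoint and params.exon_fold > 1
        mean_c = mean_n * (params.exon_fold if (i + 1) > params.exon_breakpoint else 1.0)
        if up:
            upregulated.append(exon)
        lam_n = rng.gamma(shape=r, scale=mean_n / r, size=n)
        lam_c = rng.gamma(shape=r, scale=mean_c / r, size=n)
        rows.append(np.concatenate([rng.poisson(lam_n), rng.poisson(lam_c)]).astype(float))
    counts = pd.DataFrame(rows, index=exon_ids, columns=list(samples.index))
    return ExonDataset(counts, samples, {"upregulated_exons": upregulated})


# ---------------------------------------------------------------------------
# on-disk dataset in the formats the readers consume
# ---------------------------------------------------------------------------

def write_sponge_dataset(dataset: SpongeDataset, outdir: str | Path) -> dict:
    """Write TSV matrices, FASTA sequences, sample table and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.mrna, outdir / "mrna_fpkm.tsv")
    write_expression(dataset.lncrna, outdir / "lncrna_fpkm.tsv")
    write_expression(dataset.mirna, outdir / "mirna_fpkm.tsv")
    write_sample_table(dataset.mrna.samples, outdir / "samples.tsv")
    write_fasta(dataset.utr_sequences, outdir / "mrna_3utr.fa")
    write_fasta(dataset.lnc_sequences, outdir / "lncrna_cdna.fa")
    with open(outdir / "mature_mirnas.tsv", "w") as fh:
        for sd in dataset.mirna_seeds:
            fh.write(f"{sd.mirna_id}\t{sd.mature_sequence}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2)
    manifest = {
        "files": sorted(p.name for p in outdir.iterdir()),
        "n_mrna": len(dataset.mrna.entity_ids),
        "n_lncrna": len(dataset.lncrna.entity_ids),
        "n_mirna": len(dataset.mirna.entity_ids),
    }
    return manifest
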