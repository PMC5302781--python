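"""Readers, writers and preprocessing filters for expression and sequence data.

Expression profiles arrive as tab-separated matrices (rows = entities,
columns = samples) of FPKM values, accompanied by a sample table mapping
each sample to a patient and a condition (``normal`` or ``cancer``).
Transcript sequences arrive as FASTA; transcript models as GTF.

Two preprocessing filters are applied before any correlation analysis:
entities with more than 10% missing values are dropped, and mRNAs whose
3'UTR is shorter than 500 nt are dropped (6-mer site scanning on very
short UTRs is statistically uninformative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ROLES = ("mRNA", "lncRNA", "miRNA", "isoform")
VALID_CONDITIONS = ("normal", "cancer")

#: Drop an entity when its fraction of missing values exceeds this.
MISSING_MAX = 0.10
#: Minimum 3'UTR length (nt) for an mRNA to be retained.
UTR_MIN = 500


class SpongenetError(Exception):
    """Base class for package errors."""


class EmptyResultError(SpongenetError):
    """A filter or pipeline stage produced an empty result."""


@dataclass
class ExpressionMatrix:
    """FPKM expression profiles for one class of entities.

    ``values`` is a DataFrame indexed by entity id with one column per
    sample; missing measurements are ``NaN`` (never imputed).  ``samples``
    is a DataFrame indexed by sample id with columns ``patient_id`` and
    ``condition``.
    """

    values: pd.DataFrame
    role: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown entity role {self.role!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate entity ids: {dups}")
        missing_meta = [s for s in self.values.columns if s not in self.samples.index]
        if missing_meta:
            raise ValueError(f"samples without condition annotation: {missing_meta}")
        bad = self.samples.loc[
            ~self.samples["condition"].isin(VALID_CONDITIONS), "condition"
        ]
        if len(bad):
            raise ValueError(f"invalid condition labels: {sorted(set(bad))}")
        present = self.values.to_numpy(dtype=float)
        if np.nanmin(present, initial=0.0) < 0:
            raise ValueError("FPKM values must be non-negative")
        # a patient may appear at most once per condition (matched design)
        meta = self.samples.loc[list(self.values.columns)]
        if meta.duplicated(subset=["patient_id", "condition"]).any():
            raise ValueError("a patient appears more than once in a condition")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_samples(self, condition: str) -> list[str]:
        meta = self.samples.loc[list(self.values.columns)]
        return list(meta.index[meta["condition"] == condition])

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        cols = self.condition_samples(condition)
        return ExpressionMatrix(self.values[cols], self.role, self.samples.loc[cols])


@dataclass
class TranscriptSequence:
    """A DNA-alphabet transcript sequence (RNA input is normalised U->T)."""

    id: str
    sequence: str
    role: str = "lncRNA-cDNA"

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """A transcript model from a GTF: exons in 0-based half-open coordinates."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    site_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(end - start for start, end in self.exons)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert the RNA alphabet to DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation TSV (sample_id, patient_id, condition)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "condition"}
    if not required.issubset(table.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    return table.set_index("sample_id")


def read_expression(
    path: str | Path,
    samples: pd.DataFrame | Mapping[str, tuple[str, str]],
    role: str,
) -> ExpressionMatrix:
    """Read a tab-separated FPKM matrix (first column entity id, header samples).

    ``samples`` maps each sample id to its patient and condition, either as
    the DataFrame produced by :func:`read_sample_table` or as a plain
    mapping ``sample_id -> (patient_id, condition)``.  Empty cells are kept
    as missing (NaN).  Duplicate entity ids and samples absent from the
    annotation are errors.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns = values.columns.astype(str)
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame.from_dict(
            {s: {"patient_id": p, "condition": c} for s, (p, c) in samples.items()},
            orient="index",
        ).rename_axis("sample_id")
    return ExpressionMatrix(values, role, samples)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the FPKM matrix as TSV; missing values become empty cells."""
    matrix.values.to_csv(path, sep="\t", index_label="entity_id")


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def preprocess(
    matrix: ExpressionMatrix,
    utr_lengths: Mapping[str, int] | None = None,
    missing_max: float = MISSING_MAX,
    utr_min: int = UTR_MIN,
) -> ExpressionMatrix:
    """Apply the entity-level filters and return the reduced matrix.

    Entities whose fraction of missing values (over all samples, both
    conditions jointly) exceeds ``missing_max`` are dropped.  When the
    matrix holds mRNAs, entities whose annotated 3'UTR is shorter than
    ``utr_min`` nt (or not annotated at all) are additionally dropped.
    Entity order is preserved.  Raises :class:`EmptyResultError` when
    nothing survives.
    """
    values = matrix.values
    n_before = len(values)
    frac_missing = values.isna().mean(axis=1)
    keep = frac_missing <= missing_max
    values = values[keep]
    logger.info(
        "filter missing>%d%%: %d -> %d entities",
        round(missing_max * 100), n_before, len(values),
    )
    if matrix.role == "mRNA":
        if utr_lengths is None:
            raise ValueError("utr_lengths is required for mRNA matrices")
        n_mid = len(values)
        keep_utr = [utr_lengths.get(e, 0) >= utr_min for e in values.index]
        values = values[keep_utr]
        logger.info("filter 3'UTR<%dnt: %d -> %d entities", utr_min, n_mid, len(values))
    if values.empty:
        raise EmptyResultError("preprocessing removed every entity")
    return ExpressionMatrix(values, matrix.role, matrix.samples)


def read_fasta(path: str | Path, role: str = "lncRNA-cDNA") -> list[TranscriptSequence]:
    """Read FASTA records as DNA-normalised transcript sequences."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        records.append(TranscriptSequence(rec.id, str(rec.seq), role=role))
    return records


def write_fasta(sequences: Iterable[TranscriptSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.sequence), 70):
                fh.write(seq.sequence[i : i + 70] + "\n")


def _validate_gtf_exons(path: str | Path) -> None:
    # gffutils reports attribute problems without a line number, so check
    # the one attribute the model requires up front.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            if fields[2] == "exon" and "transcript_id" not in fields[8]:
                raise ValueError(
                    f"exon without transcript_id attribute at line {lineno}"
                )


def read_gtf_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    One model per distinct ``transcript_id``, in order of first appearance.
    GTF exon coordinates (1-based, inclusive) are converted to 0-based
    half-open intervals, so interval length is simply ``end - start``.
    """
    _validate_gtf_exons(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: dict[str, TranscriptModel] = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = exon.attributes["transcript_id"][0]
        gid = exon.attributes.get("gene_id", [""])[0]
        model = models.get(tid)
        if model is None:
            model = models[tid] = TranscriptModel(tid, gid, exon.strand)
        # GTF start is 1-based inclusive -> 0-based half-open
        model.exons.append((exon.start - 1, exon.end))
    for model in models.values():
        model.exons.sort()
    logger.info("read %d transcript models from %s", len(models), path)
    return list(models.values())
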