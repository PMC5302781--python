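"""miRNA seed extraction and 6-mer seed-match scanning.

The minimal pairing requirement used throughout is a perfect match to the
6-mer seed: nucleotides 2-7 from the 5' end of the mature miRNA.  A target
transcript carries a site wherever the reverse complement of the seed
occurs in its (DNA-alphabet) sequence.  Occurrences are counted at every
position, sliding one nucleotide at a time, so overlapping occurrences all
count; a transcript of length L has max(L - 5, 0) scannable 6-mer windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import TranscriptSequence, normalize_sequence, read_fasta

SEED_LENGTH = 6

_RNA_ALPHABET = set("ACGU")


def extract_seed(mature_sequence: str) -> str:
    """Return the 6-mer seed: positions 2..7 (1-based) of the mature miRNA."""
    seq = mature_sequence.upper()
    if len(seq) < 7:
        raise ValueError(
            f"mature sequence of length {len(seq)} is too short for a 2-7 seed"
        )
    return seq[1:7]


def seed_to_site(seed: str) -> str:
    """Reverse-complement an RNA 6-mer seed into its DNA match site."""
    seed = seed.upper()
    bad = set(seed) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid seed characters: {sorted(bad)}")
    return str(Seq(seed.replace("U", "T")).reverse_complement())


@dataclass
class MiRNASeed:
    """A mature miRNA with its derived seed and DNA match site."""

    mirna_id: str
    mature_sequence: str
    seed: str = field(init=False)
    match_site: str = field(init=False)

    def __post_init__(self) -> None:
        # mature miRNAs are RNA; tolerate DNA-alphabet input
        self.mature_sequence = self.mature_sequence.upper().replace("T", "U")
        self.seed = extract_seed(self.mature_sequence)
        self.match_site = seed_to_site(self.seed)


def count_sites(sequence: str | TranscriptSequence, site: str) -> int:
    """Count exact, possibly overlapping occurrences of ``site``.

    Ambiguity codes never match (only exact A/C/G/T characters count).
    """
    seq = sequence.sequence if isinstance(sequence, TranscriptSequence) else sequence
    if len(site) != SEED_LENGTH:
        raise ValueError(f"site must be {SEED_LENGTH} nt, got {len(site)}")
    count = 0
    start = seq.find(site)
    while start != -1:
        count += 1
        start = seq.find(site, start + 1)
    return count


def n_windows(length: int) -> int:
    """Number of 6-mer windows in a sequence of the given length."""
    return max(length - (SEED_LENGTH - 1), 0)


@dataclass
class SeedMatchIndex:
    """Per (transcript, miRNA) 6-mer site counts plus window totals.

    ``counts[(transcript_id, mirna_id)]`` is the number of occurrences of
    the miRNA's match site in that transcript; ``windows[transcript_id]``
    the number of 6-mer windows.  miRNAs with identical seeds are kept as
    distinct entries (network edges are per-miRNA).
    """

    counts: dict[tuple[str, str], int]
    windows: dict[str, int]
    mirna_ids: list[str]

    def total_windows(self) -> int:
        return sum(self.windows.values())

    def total_count(self, mirna_id: str) -> int:
        if mirna_id not in self.mirna_ids:
            raise KeyError(f"miRNA {mirna_id!r} not in index")
        return sum(
            c for (tid, mid), c in self.counts.items() if mid == mirna_id
        )

    def count(self, transcript_id: str, mirna_id: str) -> int:
        if transcript_id not in self.windows:
            raise KeyError(f"transcript {transcript_id!r} not in index")
        if mirna_id not in self.mirna_ids:
            raise KeyError(f"miRNA {mirna_id!r} not in index")
        return self.counts.get((transcript_id, mirna_id), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": tid,
                "mirna_id": mid,
                "count": self.count(tid, mid),
                "windows": self.windows[tid],
            }
            for tid in self.windows
            for mid in self.mirna_ids
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_index(
    sequences: Sequence[TranscriptSequence], seeds: Sequence[MiRNASeed]
) -> SeedMatchIndex:
    """Scan every transcript for every miRNA's match site."""
    if not sequences or not seeds:
        raise ValueError("build_index requires non-empty sequences and seeds")
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids: {dups}")
    counts: dict[tuple[str, str], int] = {}
    windows: dict[str, int] = {}
    for seq in sequences:
        windows[seq.id] = n_windows(seq.length)
        for seed in seeds:
            c = count_sites(seq, seed.match_site)
            if c:
                counts[(seq.id, seed.mirna_id)] = c
    return SeedMatchIndex(counts, windows, [s.mirna_id for s in seeds])


def read_mirnas(path: str | Path) -> list[MiRNASeed]:
    """Read mature miRNAs from FASTA or a two-column TSV (id, sequence)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return [MiRNASeed(rec.id, rec.sequence) for rec in read_fasta(path)]
    table = pd.read_csv(path, sep="\t", header=None, names=["id", "sequence"])
    return [MiRNASeed(str(r.id), str(r.sequence)) for r in table.itertuples()]
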