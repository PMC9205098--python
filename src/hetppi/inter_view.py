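"""Inter-view (sequence) feature: reduced-alphabet 3-mer frequency vectors.

The 20 standard amino acids are collapsed into four side-chain-polarity
groups (the conjoint-triad grouping of Shen et al.), the sequence is scanned
with a width-3 window at step 1, and each window increments one of the
4x4x4 = 64 triplet bins.  The counts are normalised to frequencies, giving
a 64-dimensional descriptor per protein that is independent of sequence
length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Side-chain-polarity grouping of the 20 standard residues.
SHEN_GROUPS: tuple[str, ...] = ("AVLIMFWP", "GSTCNQY", "RKH", "DE")

#: residue letter -> group index in {0, 1, 2, 3}
REDUCED_ALPHABET: dict[str, int] = {
    aa: g for g, members in enumerate(SHEN_GROUPS) for aa in members
}

#: Sentinel emitted for non-standard residues (X, U, B, Z, *, ...).
UNKNOWN = "?"

N_GROUPS = len(SHEN_GROUPS)
KMER_DIM = N_GROUPS**3  # 64


@dataclass(frozen=True)
class SequenceRecord:
    """A protein id with its upper-case amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: sequence must be non-empty")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            object.__setattr__(
                self, "sequence", "".join(c for c in self.sequence.upper() if c.isalpha())
            )
            if not self.sequence:
                raise ValueError(f"{self.protein_id}: sequence has no letters")


def reduce_alphabet(seq: str) -> str:
    """Map a sequence onto group-index characters '0123'; non-standard
    residues become the '?' sentinel.  Output length equals input length."""
    return "".join(str(REDUCED_ALPHABET[c]) if c in REDUCED_ALPHABET else UNKNOWN
                   for c in seq.upper())


def kmer_index(g1: int, g2: int, g3: int) -> int:
    """Position of the triplet (g1, g2, g3) in the 64-vector.

    Base-4 with the leftmost group most significant: 16*g1 + 4*g2 + g3.
    """
    for g in (g1, g2, g3):
        if not 0 <= g < N_GROUPS:
            raise ValueError(f"group index {g} out of range [0, {N_GROUPS})")
    return (g1 * N_GROUPS + g2) * N_GROUPS + g3


def kmer_vector(rec: SequenceRecord | str) -> np.ndarray:
    """64-dim triplet frequency vector of one protein sequence.

    Windows containing a non-standard residue are skipped; the counts are
    divided by the number of counted windows, so entries sum to 1 whenever
    at least one window was valid.  Sequences shorter than 3 residues (or
    with no valid window) yield the all-zero vector.
    """
    seq = rec.sequence if isinstance(rec, SequenceRecord) else rec
    reduced = reduce_alphabet(seq)
    counts = np.zeros(KMER_DIM, dtype=float)
    n_windows = 0
    for i in range(len(reduced) - 2):
        window = reduced[i : i + 3]
        if UNKNOWN in window:
            continue
        counts[kmer_index(int(window[0]), int(window[1]), int(window[2]))] += 1
        n_windows += 1
    if n_windows == 0:
        name = rec.protein_id if isinstance(rec, SequenceRecord) else "<sequence>"
        logger.warning("%s: no valid 3-mer window; all-zero inter-view vector", name)
        return counts
    return counts / n_windows


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein sequences; one record per header, sequences upper-cased
    and joined across wrapped lines.  Empty-sequence records are skipped with
    a warning; text before the first header is an error."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                break
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("%s: record %r has an empty sequence; skipped", path, rec.id)
            continue
        records.append(SequenceRecord(rec.id, seq))
    return records


def inter_view_table(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Feature matrix as a DataFrame: protein_id index, 64 triplet columns."""
    records = list(records)
    data = np.vstack([kmer_vector(r) for r in records]) if records else np.empty((0, KMER_DIM))
    columns = [f"k{idx:02d}" for idx in range(KMER_DIM)]
    return pd.DataFrame(data, index=[r.protein_id for r in records], columns=columns)


def write_inter_view_table(records: Iterable[SequenceRecord], path: str | Path) -> Path:
    path = Path(path)
    inter_view_table(records).to_csv(path, sep="\t", index_label="protein_id")
    return path
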