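"""Species-labelled ortholog alignments and multi-FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hky import MISSING, encode_sequences, site_patterns

ALPHABET = set("ACGTacgtNn-")


@dataclass
class OrthologAlignment:
    """One regulatory element aligned across primate species.

    Sequences are equal length over {A,C,G,T,-,N}; headers are species names.
    """

    id: str
    sequences: dict[str, str]
    _codes: dict[str, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(f"{self.id}: alignment needs >=2 species")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.id}: unequal sequence lengths {lengths}")
        for sp, s in self.sequences.items():
            bad = set(s) - ALPHABET
            if bad:
                raise ValueError(f"{self.id}/{sp}: illegal characters {bad}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def codes(self) -> dict[str, np.ndarray]:
        if self._codes is None:
            self._codes = encode_sequences(self.sequences)
        return self._codes

    def patterns(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        order = self.species
        pat, cnt = site_patterns(self.codes(), order)
        return pat, cnt, order

    def n_informative_columns(self) -> int:
        """Columns with at least one non-missing base."""
        mat = np.stack(list(self.codes().values()))
        return int(np.any(mat != MISSING, axis=0).sum())

    def ungapped(self, species: str) -> str:
        return self.sequences[species].replace("-", "")

    def column_of_position(self, species: str) -> np.ndarray:
        """Alignment column index of each non-gap position of ``species``."""
        arr = np.frombuffer(self.sequences[species].encode(), dtype=np.uint8)
        return np.flatnonzero(arr != ord("-"))

    def slice_columns(self, start: int, stop: int, new_id: str | None = None) -> "OrthologAlignment":
        return OrthologAlignment(
            new_id or f"{self.id}[{start}:{stop}]",
            {sp: s[start:stop] for sp, s in self.sequences.items()},
        )

    def subset(self, species: list[str]) -> "OrthologAlignment":
        return OrthologAlignment(self.id, {s: self.sequences[s] for s in species})


def read_alignment_fasta(path: str | Path, element_id: str | None = None) -> OrthologAlignment:
    """Read one element's alignment from multi-FASTA (headers = species)."""
    path = Path(path)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return OrthologAlignment(element_id or path.stem, seqs)


def write_alignment_fasta(aln: OrthologAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sp, description="") for sp, s in aln.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
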