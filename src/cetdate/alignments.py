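"""In-frame coding alignments and their FASTA / relaxed-PHYLIP I/O."""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .substitution import STATE_CODE

__all__ = ["GeneAlignment", "read_fasta_alignment", "write_fasta_alignment",
           "write_relaxed_phylip"]

_DECODE = np.frombuffer(b"ACGT-N", dtype=np.uint8)
_ENCODE = np.full(256, 5, dtype=np.uint8)
for ch, code in STATE_CODE.items():
    _ENCODE[ord(ch)] = code
    _ENCODE[ord(ch.lower())] = code
_ENCODE[ord("?")] = 5
_ENCODE[ord(".")] = 4


def codon_position_labels(n_sites: int, frame_offset: int = 0) -> np.ndarray:
    """Per-site codon-position labels in {1,2,3}, cycling from the frame."""
    return ((np.arange(n_sites) + frame_offset) % 3 + 1).astype(np.int8)


@dataclass
class GeneAlignment:
    """A per-gene nucleotide matrix with codon-position labels.

    ``matrix`` holds byte codes 0..5 over {A,C,G,T,-,N}; rows follow
    ``taxa`` order.  ``frame_offset`` is the codon phase of the first
    column (0 means column 0 is a first codon position).
    """

    gene_id: str
    taxa: list[str]
    matrix: np.ndarray
    frame_offset: int = 0
    codon_pos: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix must be taxa x sites")
        if self.matrix.shape[1] < 1:
            raise ValueError("alignment needs at least one site")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0..2")
        if self.codon_pos is None:
            self.codon_pos = codon_position_labels(self.n_sites,
                                                   self.frame_offset)
        self.codon_pos = np.asarray(self.codon_pos, dtype=np.int8)
        if self.codon_pos.shape != (self.n_sites,):
            raise ValueError("codon_pos length mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def sequence_str(self, taxon: str) -> str:
        return _DECODE[self.row(taxon)].tobytes().decode()

    def subset_sites(self, mask: np.ndarray, gene_id: str | None = None
                     ) -> "GeneAlignment":
        return GeneAlignment(gene_id or self.gene_id, list(self.taxa),
                             self.matrix[:, mask], frame_offset=0,
                             codon_pos=self.codon_pos[mask])

    def copy(self) -> "GeneAlignment":
        return GeneAlignment(self.gene_id, list(self.taxa),
                             self.matrix.copy(), self.frame_offset,
                             self.codon_pos.copy())

    @classmethod
    def from_strings(cls, gene_id: str, seqs: Mapping[str, str],
                     frame_offset: int = 0) -> "GeneAlignment":
        taxa = list(seqs)
        rows = [np.frombuffer(seqs[t].encode(), dtype=np.uint8) for t in taxa]
        if len({len(r) for r in rows}) != 1:
            raise ValueError("sequences differ in length")
        mat = _ENCODE[np.vstack(rows)]
        return cls(gene_id, taxa, mat, frame_offset=frame_offset)


def read_fasta_alignment(path: str | Path, gene_id: str | None = None,
                         frame_offset: int = 0) -> GeneAlignment:
    path = Path(path)
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GeneAlignment.from_strings(gene_id or path.stem, seqs,
                                      frame_offset=frame_offset)


def write_fasta_alignment(aln: GeneAlignment, path: str | Path,
                          header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f";{header}\n")
        for i, t in enumerate(aln.taxa):
            fh.write(f">{t}\n")
            fh.write(_DECODE[aln.matrix[i]].tobytes().decode() + "\n")


def write_relaxed_phylip(alignments: Sequence[GeneAlignment],
                         path: str | Path) -> None:
    """Concatenated relaxed-PHYLIP with one block per alignment."""
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
            for i, t in enumerate(aln.taxa):
                seq = _DECODE[aln.matrix[i]].tobytes().decode()
                fh.write(f"{t}  {seq}\n")
            fh.write("\n")
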