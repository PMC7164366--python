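"""Dataset-assembly filters for coding alignments.

Pseudogene screening (internal stop codons, frameshift gap runs),
taxon-missingness exclusion, representative-individual selection and
exon-to-gene concatenation with reading-frame checks.  The default policy
drops a whole gene from dating when any sequence carries pseudogene
evidence; per-sequence dropping is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import GeneAlignment

__all__ = ["QcReport", "PresenceMatrix", "screen_premature_stops",
           "detect_frameshift_indels", "qc_gene", "filter_genes",
           "filter_taxa_by_missingness", "select_representatives",
           "concatenate_exons"]

_STOP_SET = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA in ACGT codes


@dataclass
class QcFlag:
    taxon: str
    kind: str              # "premature_stop" | "frameshift"
    position: int          # codon index for stops, site index for gaps
    length: int = 3


@dataclass
class QcReport:
    """Per-gene QC outcome: flags, decision and rationale."""

    gene_id: str
    flags: list[QcFlag] = field(default_factory=list)
    decision: str = "keep"     # keep | drop_gene | drop_sequence
    rationale: str = ""

    @property
    def flagged_taxa(self) -> set[str]:
        return {f.taxon for f in self.flags}


def screen_premature_stops(aln: GeneAlignment) -> list[QcFlag]:
    """Flag in-frame internal stop codons.

    A stop is internal when it sits strictly before the final codon of the
    sequence's own ungapped CDS (a terminal stop is legitimate).  Codons
    containing gaps or N are skipped -- ambiguity never produces a flag.
    """
    if aln.n_sites < 3:
        raise ValueError("alignment shorter than one codon")
    start = (3 - aln.frame_offset) % 3
    usable = (aln.n_sites - start) // 3
    flags: list[QcFlag] = []
    for i, taxon in enumerate(aln.taxa):
        row = aln.matrix[i]
        clean_codons = []   # (codon_index, triple)
        for c in range(usable):
            s = start + 3 * c
            triple = tuple(int(x) for x in row[s:s + 3])
            if any(x > 3 for x in triple):
                continue
            clean_codons.append((c, triple))
        if not clean_codons:
            continue
        last_c = clean_codons[-1][0]
        for c, triple in clean_codons:
            if triple in _STOP_SET and c < last_c:
                flags.append(QcFlag(taxon, "premature_stop", c))
    return flags


def detect_frameshift_indels(aln: GeneAlignment) -> list[QcFlag]:
    """Flag maximal gap runs whose length is not a multiple of three."""
    flags: list[QcFlag] = []
    gap = aln.matrix == 4
    for i, taxon in enumerate(aln.taxa):
        g = gap[i]
        if not g.any():
            continue
        d = np.diff(np.concatenate([[0], g.astype(np.int8), [0]]))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            ln = int(e - s)
            if ln % 3 != 0:
                flags.append(QcFlag(taxon, "frameshift", int(s), ln))
    return flags


def qc_gene(aln: GeneAlignment, policy: str = "gene") -> QcReport:
    """Screen one gene; ``policy`` is "gene" (any flag drops the gene,
    the default) or "sequence" (only flagged sequences are dropped)."""
    flags = screen_premature_stops(aln) + detect_frameshift_indels(aln)
    rep = QcReport(aln.gene_id, flags)
    if flags:
        if policy == "gene":
            rep.decision = "drop_gene"
            rep.rationale = (f"{len(flags)} pseudogene flag(s) in "
                             f"{len(rep.flagged_taxa)} taxa")
        else:
            rep.decision = "drop_sequence"
            rep.rationale = "flags confined to listed sequences"
    return rep


def filter_genes(alignments: Sequence[GeneAlignment], policy: str = "gene"
                 ) -> tuple[list[GeneAlignment], list[QcReport]]:
    """Apply pseudogene screening across a gene set."""
    kept, reports = [], []
    for aln in alignments:
        rep = qc_gene(aln, policy=policy)
        reports.append(rep)
        if rep.decision == "keep":
            kept.append(aln)
        elif rep.decision == "drop_sequence":
            keep_idx = [i for i, t in enumerate(aln.taxa)
                        if t not in rep.flagged_taxa]
            if keep_idx:
                kept.append(GeneAlignment(
                    aln.gene_id, [aln.taxa[i] for i in keep_idx],
                    aln.matrix[keep_idx], aln.frame_offset, aln.codon_pos))
    return kept, reports


# ----------------------------------------------------------------------
# Missingness over exons
# ----------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Boolean taxa x exons presence with per-taxon missing fractions."""

    taxa: list[str]
    exons: list[str]
    present: np.ndarray

    def __post_init__(self):
        self.present = np.asarray(self.present, bool)
        if self.present.shape != (len(self.taxa), len(self.exons)):
            raise ValueError("presence matrix shape mismatch")

    @property
    def missing_fraction(self) -> np.ndarray:
        return 1.0 - self.present.mean(axis=1)

    @classmethod
    def from_alignments(cls, alignments: Sequence[GeneAlignment],
                        taxa: Sequence[str] | None = None
                        ) -> "PresenceMatrix":
        """A taxon is present in an exon if it has a row that is not
        entirely gap/N."""
        if taxa is None:
            seen: dict[str, None] = {}
            for a in alignments:
                for t in a.taxa:
                    seen.setdefault(t)
            taxa = list(seen)
        pm = np.zeros((len(taxa), len(alignments)), bool)
        tidx = {t: i for i, t in enumerate(taxa)}
        for j, a in enumerate(alignments):
            informative = a.matrix < 4
            for i, t in enumerate(a.taxa):
                if t in tidx and informative[i].any():
                    pm[tidx[t], j] = True
        return cls(list(taxa), [a.gene_id for a in alignments], pm)


def filter_taxa_by_missingness(pm: PresenceMatrix,
                               threshold: float = 0.5) -> list[str]:
    """Keep taxa missing at most ``threshold`` of their exons
    (strictly-greater missingness is excluded)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if pm.present.size == 0:
        raise ValueError("empty presence matrix")
    mf = pm.missing_fraction
    return [t for t, m in zip(pm.taxa, mf) if m <= threshold]


def select_representatives(individuals: Mapping[str, Sequence[tuple[str, float]]],
                           keep_list: Sequence[str] = ()) -> set[str]:
    """One individual per species: highest completeness, ties broken by
    lexicographic id; every ``keep_list`` id is retained additionally."""
    all_ids = {i for per in individuals.values() for i, _ in per}
    for k in keep_list:
        if k not in all_ids:
            raise KeyError(f"keep_list id {k!r} unknown")
    chosen: set[str] = set()
    for sp, per in individuals.items():
        if not per:
            continue
        best = min(per, key=lambda ic: (-ic[1], ic[0]))
        chosen.add(best[0])
    chosen.update(keep_list)
    return chosen


# ----------------------------------------------------------------------
# Exon -> gene concatenation
# ----------------------------------------------------------------------

def concatenate_exons(exons: Sequence[GeneAlignment], gene_id: str,
                      taxa: Sequence[str] | None = None
                      ) -> tuple[GeneAlignment, list[tuple[int, int]]]:
    """Concatenate exon alignments (in given order) into a gene alignment.

    Taxa absent from an exon are padded with N over that span.  Returns the
    gene and the recorded (start, end) site boundaries of each exon, which
    allow exact re-splitting.  Frame continuity follows from cumulative
    length: exon k+1 starts at phase (sum of previous lengths) mod 3.
    """
    if not exons:
        raise ValueError("no exons to concatenate")
    if taxa is None:
        seen: dict[str, None] = {}
        for e in exons:
            for t in e.taxa:
                seen.setdefault(t)
        taxa = list(seen)
    for e in exons:
        if len(set(e.taxa)) != len(e.taxa):
            raise ValueError(f"duplicate taxon rows in exon {e.gene_id}")
    total = sum(e.n_sites for e in exons)
    mat = np.full((len(taxa), total), 5, dtype=np.uint8)  # N padding
    boundaries = []
    pos = 0
    for e in exons:
        for i, t in enumerate(e.taxa):
            if t in taxa:
                mat[list(taxa).index(t), pos:pos + e.n_sites] = e.matrix[i]
        boundaries.append((pos, pos + e.n_sites))
        pos += e.n_sites
    return GeneAlignment(gene_id, list(taxa), mat, frame_offset=0), boundaries


def split_concatenation(gene: GeneAlignment,
                        boundaries: Sequence[tuple[int, int]]
                        ) -> list[GeneAlignment]:
    """Inverse of :func:`concatenate_exons` (up to N-padding of absentees)."""
    out = []
    for k, (s, e) in enumerate(boundaries):
        out.append(GeneAlignment(f"{gene.gene_id}.exon{k+1}",
                                 list(gene.taxa), gene.matrix[:, s:e],
                                 frame_offset=s % 3,
                                 codon_pos=gene.codon_pos[s:e]))
    return out


def reports_to_tsv(reports: Iterable[QcReport], path) -> None:
    rows = []
    for r in reports:
        if not r.flags:
            rows.append({"gene_id": r.gene_id, "taxon": "", "kind": "",
                         "position": -1, "length": 0,
                         "decision": r.decision})
        for f in r.flags:
            rows.append({"gene_id": r.gene_id, "taxon": f.taxon,
                         "kind": f.kind, "position": f.position,
                         "length": f.length, "decision": r.decision})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
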