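"""Virus redundancy collapsing by global-alignment percent identity.

Closely related viruses would otherwise dominate repertoire averages, so
pairwise Needleman–Wunsch identities are computed between viruses and any
virus with greater than a threshold identity (default 95%) to an already
retained virus is collapsed onto it.

Identity follows the EMBOSS Needle convention: identical aligned positions
divided by alignment length including gaps, with BLOSUM62, gap open 10 /
extend 0.5 and free end gaps by default. Per-virus sequences are the
concatenation of the virus's protein records in id-sorted order, which
makes the result independent of record order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import ProteomeSet

DEFAULT_COLLAPSE_THRESHOLD = 95.0


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap global alignment scoring (EMBOSS Needle protein defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True


@dataclass
class IdentityMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric percent identities, diagonal 100

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("identity matrix shape does not match id count")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, vid in enumerate(self.ids):
                row = "\t".join(f"{x:.4f}" for x in self.matrix[i])
                fh.write(f"{vid}\t{row}\n")


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Biopython convention: a gap of length L costs open + (L-1) * extend.
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.end_gaps_free:
        for attr in (
            "open_end_insertion_score",
            "extend_end_insertion_score",
            "open_end_deletion_score",
            "extend_end_deletion_score",
        ):
            setattr(aligner, attr, 0.0)
    return aligner


def global_align_identity(
    seq_a: str, seq_b: str, params: AlignParams = AlignParams()
) -> float:
    """Percent identity of the optimal affine-gap global alignment.

    Identity = 100 x identical aligned positions / alignment length
    (including gap columns). Among co-optimal alignments the aligner's
    first traceback is used, deterministically.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(params)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def _concat_sorted(virus: ProteomeSet) -> str:
    return "".join(r.residues for r in sorted(virus.records, key=lambda r: r.id))


def virus_identity(
    virus_a: ProteomeSet, virus_b: ProteomeSet, params: AlignParams = AlignParams()
) -> float:
    """Identity between two viruses on their id-sorted concatenated proteomes."""
    return global_align_identity(_concat_sorted(virus_a), _concat_sorted(virus_b), params)


def identity_matrix(
    viruses: Sequence[ProteomeSet], params: AlignParams = AlignParams()
) -> IdentityMatrix:
    n = len(viruses)
    mat = np.full((n, n), 100.0)
    seqs = [_concat_sorted(v) for v in viruses]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = global_align_identity(seqs[i], seqs[j], params)
    return IdentityMatrix(ids=[v.source_id for v in viruses], matrix=mat)


def collapse(
    viruses: Sequence[ProteomeSet],
    threshold: float = DEFAULT_COLLAPSE_THRESHOLD,
    params: AlignParams = AlignParams(),
    precomputed: IdentityMatrix | None = None,
) -> tuple[list[ProteomeSet], dict[str, str]]:
    """Greedy collapse in input order at a strict identity threshold.

    A virus is retained iff its identity to every already retained virus is
    <= threshold ("greater than 95% identity" collapses, exactly 95.0 is
    kept). Returns the retained viruses and a map from every virus id to
    its representative (retained viruses map to themselves; a collapsed
    virus maps to the first retained virus that excluded it).
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"collapse threshold {threshold} outside (0, 100]")
    retained: list[ProteomeSet] = []
    seqs: list[str] = []
    cluster_map: dict[str, str] = {}
    for virus in viruses:
        seq = _concat_sorted(virus)
        rep = None
        for kept, kept_seq in zip(retained, seqs):
            if precomputed is not None:
                ident = precomputed.get(virus.source_id, kept.source_id)
            else:
                ident = global_align_identity(seq, kept_seq, params)
            if ident > threshold:
                rep = kept.source_id
                break
        if rep is None:
            retained.append(virus)
            seqs.append(seq)
            cluster_map[virus.source_id] = virus.source_id
        else:
            cluster_map[virus.source_id] = rep
    return retained, cluster_map


def write_cluster_map(cluster_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\trepresentative_id\n")
        for member, rep in cluster_map.items():
            fh.write(f"{member}\t{rep}\n")
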