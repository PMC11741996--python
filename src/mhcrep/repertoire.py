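"""Per-(allele, virus) binder repertoires.

A repertoire entry is the set of unique viral digestion products whose
self-calibrated percentile rank for that allele is at or below the binder
threshold. These sets are the substrate of both the Jaccard functional
distances and the epitope densities, so the per-virus total digestion
product counts are carried along.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .binding import DEFAULT_RANK_THRESHOLD, BindingModel, RankReference, percentile_ranks
from .digestion import VIRAL_LENGTHS, DigestResult, decode_code, digest_proteome
from .io import AllelePanel, ProteomeSet


@dataclass
class BinderRepertoire:
    """Sets of unique binder peptides per (allele, virus)."""

    alleles: list[str]
    viruses: list[str]
    binders: dict[tuple[str, str], frozenset[str]]
    threshold: float
    total_products: dict[str, int]
    backend: str = "unknown"

    def binder_set(self, allele: str, virus: str) -> frozenset[str]:
        return self.binders[(allele, virus)]

    def n_binders(self, allele: str, virus: str) -> int:
        return len(self.binders[(allele, virus)])

    def to_tsv(self, path: str | Path) -> None:
        """Dump as TSV (allele, virus, peptide), sorted for reproducibility."""
        with open(path, "w") as fh:
            fh.write("allele\tvirus\tpeptide\n")
            for allele in self.alleles:
                for virus in self.viruses:
                    for pep in sorted(self.binders[(allele, virus)]):
                        fh.write(f"{allele}\t{virus}\t{pep}\n")


def build_repertoire(
    panel: AllelePanel,
    viruses: Sequence[ProteomeSet],
    references: Mapping[str, RankReference],
    lengths: Sequence[int] = VIRAL_LENGTHS,
    threshold: float = DEFAULT_RANK_THRESHOLD,
    digests: Mapping[str, DigestResult] | None = None,
) -> BinderRepertoire:
    """Digest every virus and call binders for every allele.

    Every allele must have a :class:`RankReference`; a peptide appearing in
    two viruses contributes independently to each virus's set. Precomputed
    ``digests`` (keyed by virus id) are reused when given.
    """
    missing = [e.allele for e in panel if e.allele not in references]
    if missing:
        raise ValueError(f"missing rank reference for allele(s): {missing}")

    virus_ids = [v.source_id for v in viruses]
    binders: dict[tuple[str, str], frozenset[str]] = {}
    totals: dict[str, int] = {}
    for virus in viruses:
        dig = digests[virus.source_id] if digests else digest_proteome(virus, lengths)
        totals[virus.source_id] = dig.total_products
        for entry in panel:
            model: BindingModel = entry.model  # type: ignore[assignment]
            ref = references[entry.allele]
            hits: list[str] = []
            for k, codes in dig.codes_by_length.items():
                if codes.size == 0:
                    continue
                ranks = percentile_ranks(model.score_codes(codes, k), ref)
                for code in codes[ranks <= threshold]:
                    hits.append(decode_code(int(code)))
            binders[(entry.allele, virus.source_id)] = frozenset(hits)
    return BinderRepertoire(
        alleles=list(panel.alleles),
        viruses=virus_ids,
        binders=binders,
        threshold=threshold,
        total_products=totals,
        backend=type(panel.entries[0].model).__name__ if len(panel) else "unknown",
    )
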