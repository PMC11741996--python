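"""In-silico digestion: all overlapping peptide windows of configured lengths.

Each protein is cut into every window ("digestion product") of each length
in the configured range — lengths 8–11 for viral and self proteins, 8–12
for the rank-calibration reference. Windows overlapping a masked
(nonstandard) position are excluded.

Peptides are held internally as packed integer codes: each residue maps to
a 5-bit digit (index into the alphabet plus one), so any peptide of length
up to 12 fits a single ``uint64``. The leading digit is always nonzero,
which makes codes unique across lengths as well. This keeps digestion,
uniqueness and scoring vectorized; helpers convert back to strings at the
edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import STANDARD_AA, ProteinRecord, ProteomeSet

#: Viral / self-proteome digestion lengths.
VIRAL_LENGTHS: tuple[int, ...] = (8, 9, 10, 11)
#: Rank-reference digestion lengths.
REFERENCE_LENGTHS: tuple[int, ...] = (8, 9, 10, 11, 12)

#: Longest peptide representable in one packed uint64 code (12 * 5 = 60 bits).
MAX_CODE_LENGTH = 12

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _aa in enumerate(STANDARD_AA):
    _LUT[ord(_aa)] = _i
    _LUT[ord(_aa.lower())] = _i


def encode_residues(residues: str, mask: np.ndarray | None = None) -> np.ndarray:
    """Map residues to alphabet indices (0–19); invalid/masked positions → 255."""
    idx = _LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)].copy()
    if mask is not None:
        if len(mask) != len(idx):
            raise ValueError("mask length does not match sequence length")
        idx[np.asarray(mask, dtype=bool)] = 255
    return idx


def window_codes(idx: np.ndarray, k: int) -> np.ndarray:
    """Packed codes for every valid window of length ``k`` (with multiplicity)."""
    if k < 1:
        raise ValueError("window length must be >= 1")
    if k > MAX_CODE_LENGTH:
        raise ValueError(f"window length {k} exceeds packed-code limit {MAX_CODE_LENGTH}")
    if len(idx) < k:
        return np.empty(0, dtype=np.uint64)
    sw = sliding_window_view(idx, k)
    valid = (sw < 20).all(axis=1)
    sw = sw[valid]
    codes = np.zeros(len(sw), dtype=np.uint64)
    for i in range(k):
        codes |= (sw[:, i].astype(np.uint64) + np.uint64(1)) << np.uint64(5 * i)
    return codes


def encode_peptide(peptide: str) -> int:
    """Pack one peptide string into its integer code."""
    idx = _LUT[np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)]
    if (idx >= 20).any():
        bad = peptide[int(np.argmax(idx >= 20))]
        raise ValueError(f"nonstandard residue {bad!r} in peptide {peptide!r}")
    if len(peptide) > MAX_CODE_LENGTH:
        raise ValueError(f"peptide longer than {MAX_CODE_LENGTH} residues")
    code = 0
    for i, d in enumerate(idx):
        code |= (int(d) + 1) << (5 * i)
    return code


def decode_code(code: int) -> str:
    """Inverse of :func:`encode_peptide`."""
    code = int(code)
    out = []
    while code:
        out.append(STANDARD_AA[(code & 31) - 1])
        code >>= 5
    return "".join(out)


def code_length(code: int) -> int:
    code = int(code)
    n = 0
    while code:
        n += 1
        code >>= 5
    return n


@dataclass
class DigestResult:
    """Digestion products of one source, pooled across its proteins.

    ``total_products`` counts windows with multiplicity (the denominator of
    epitope densities); the per-length unique code arrays deduplicate
    sequences (the substrate of binder repertoires).
    """

    source_id: str
    total_products: int
    codes_by_length: dict[int, np.ndarray]  # sorted unique packed codes
    counts_by_length: dict[int, np.ndarray]  # occurrence count per unique code

    @property
    def n_unique(self) -> int:
        return sum(len(c) for c in self.codes_by_length.values())

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.codes_by_length))

    @property
    def unique_products(self) -> frozenset[str]:
        """Distinct peptide sequences as strings (materialized on demand)."""
        return frozenset(self.iter_peptides())

    def iter_peptides(self) -> Iterator[str]:
        for k in sorted(self.codes_by_length):
            for code in self.codes_by_length[k]:
                yield decode_code(int(code))


def _digest_indices(
    encoded: list[np.ndarray], source_id: str, lengths: Sequence[int]
) -> DigestResult:
    lengths = sorted(set(int(k) for k in lengths))
    if not lengths:
        raise ValueError("lengths must be non-empty")
    if any(k < 1 for k in lengths):
        raise ValueError("all lengths must be >= 1")
    total = 0
    codes_by_length: dict[int, np.ndarray] = {}
    counts_by_length: dict[int, np.ndarray] = {}
    for k in lengths:
        chunks = [window_codes(idx, k) for idx in encoded]
        all_codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
        total += int(all_codes.size)
        uniq, counts = np.unique(all_codes, return_counts=True)
        codes_by_length[k] = uniq
        counts_by_length[k] = counts
    return DigestResult(
        source_id=source_id,
        total_products=total,
        codes_by_length=codes_by_length,
        counts_by_length=counts_by_length,
    )


def digest(
    record: ProteinRecord,
    lengths: Sequence[int] = VIRAL_LENGTHS,
    mask: np.ndarray | None = None,
) -> DigestResult:
    """Digest one protein. A protein shorter than every length yields zero
    products; windows overlapping masked positions are skipped."""
    idx = encode_residues(record.residues, mask)
    return _digest_indices([idx], record.id, lengths)


def digest_proteome(
    proteome: ProteomeSet,
    lengths: Sequence[int] = VIRAL_LENGTHS,
    masks: dict[str, np.ndarray] | None = None,
) -> DigestResult:
    """Digest all proteins of a source and pool the products.

    Totals add across records; unique products are the union. ``masks``
    optionally maps record ids to nonstandard-position masks from
    :func:`mhcrep.io.sanitize_record`; unmapped records are digested with
    nonstandard letters auto-masked position-wise.
    """
    encoded = [
        encode_residues(rec.residues, masks.get(rec.id) if masks else None)
        for rec in proteome.records
    ]
    return _digest_indices(encoded, proteome.source_id, lengths)


def expected_window_count(protein_length: int, lengths: Iterable[int]) -> int:
    """Closed form: an unmasked protein of length L yields Σ_k max(L−k+1, 0)."""
    return sum(max(protein_length - k + 1, 0) for k in lengths)
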