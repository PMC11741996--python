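"""Binding-score backend and self-calibrated percentile ranks.

An external neural-network predictor is deliberately out of scope: binding
is abstracted behind a minimal contract (a deterministic ``score`` per
allele–peptide pair, higher = stronger), and a synthetic anchor-motif
model implements it so the whole pipeline is testable offline.

Percentile ranks are self-calibrated exactly as predictors without
built-in rank tables require: digest a reference proteome into peptides of
lengths 8–12, sample 25,000 unique products per length, score them, and
rank every query score against the pooled 125,000 reference scores. A
peptide is called a binder when its rank is at or below the threshold
(default: top 1%).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .digestion import (
    REFERENCE_LENGTHS,
    DigestResult,
    decode_code,
    digest_proteome,
    encode_peptide,
)
from .io import ProteomeSet

MIN_PEPTIDE_LENGTH = 8
MAX_PEPTIDE_LENGTH = 12

DEFAULT_PER_LENGTH_COUNT = 25_000
DEFAULT_RANK_THRESHOLD = 1.0


@runtime_checkable
class BindingModel(Protocol):
    """Contract for a binding-score backend.

    Scores must be deterministic in (allele, peptide): the same pair always
    yields the same value, regardless of call order.
    """

    name: str

    def score(self, peptide: str) -> float: ...

    def score_codes(self, codes: np.ndarray, length: int) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Deterministic per-(model, peptide) noise
# ---------------------------------------------------------------------------

_M1 = np.uint64(0x9E3779B97F4A7C15)
_M2 = np.uint64(0xBF58476D1CE4E5B9)
_M3 = np.uint64(0x94D049BB133111EB)


def _hash_unit(codes: np.ndarray, key: np.uint64) -> np.ndarray:
    """splitmix64-style mix of packed peptide codes into floats in [-1, 1).

    Hash-derived rather than RNG-stream-derived so that a given
    (model, peptide) pair scores identically no matter when it is scored.
    """
    with np.errstate(over="ignore"):
        z = (codes.astype(np.uint64) ^ key) * _M1
        z ^= z >> np.uint64(30)
        z *= _M2
        z ^= z >> np.uint64(27)
        z *= _M3
        z ^= z >> np.uint64(31)
    u = (z >> np.uint64(11)).astype(np.float64) * (1.0 / (1 << 53))
    return 2.0 * u - 1.0


@dataclass
class SyntheticAlleleModel:
    """Anchor-motif stand-in for a peptide–MHC binding predictor.

    The score of a peptide is the anchor weight of its P2 residue plus the
    anchor weight of its C-terminal residue plus the mean background weight
    over the remaining positions, perturbed by a deterministic
    hash-derived noise term of magnitude ``noise_scale``:

        score = w_P2[p_2] + w_C[p_k] + mean_i(w_bg[p_i]) + noise_scale * h

    with h in [-1, 1) a pure function of the weight tables, the seed and
    the peptide. Two models with identical tables and seed therefore score
    every peptide identically (they are the same binding function).
    """

    name: str
    supertype: str
    w_p2: np.ndarray
    w_cterm: np.ndarray
    w_background: np.ndarray
    noise_scale: float = 0.0
    seed: int = 0
    _key: np.uint64 = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.w_p2 = np.asarray(self.w_p2, dtype=np.float64)
        self.w_cterm = np.asarray(self.w_cterm, dtype=np.float64)
        self.w_background = np.asarray(self.w_background, dtype=np.float64)
        for nm, tab in (
            ("w_p2", self.w_p2),
            ("w_cterm", self.w_cterm),
            ("w_background", self.w_background),
        ):
            if tab.shape != (20,):
                raise ValueError(f"{nm} must cover all 20 residues, got shape {tab.shape}")
        # Content-derived noise key: the binding function is fully determined
        # by (tables, noise_scale, seed), never by the display name.
        h = hashlib.blake2b(digest_size=8)
        h.update(np.int64(self.seed).tobytes())
        h.update(np.float64(self.noise_scale).tobytes())
        for tab in (self.w_p2, self.w_cterm, self.w_background):
            h.update(np.round(tab, 12).tobytes())
        object.__setattr__(self, "_key", np.uint64(int.from_bytes(h.digest(), "little")))

    # -- scoring ------------------------------------------------------------

    def score_codes(self, codes: np.ndarray, length: int) -> np.ndarray:
        """Vectorized scores for packed peptide codes of one length."""
        if not (MIN_PEPTIDE_LENGTH <= length <= MAX_PEPTIDE_LENGTH):
            raise ValueError(
                f"unsupported peptide length {length} "
                f"(supported: {MIN_PEPTIDE_LENGTH}-{MAX_PEPTIDE_LENGTH})"
            )
        codes = np.asarray(codes, dtype=np.uint64)
        digits = [
            ((codes >> np.uint64(5 * i)) & np.uint64(31)).astype(np.intp) - 1
            for i in range(length)
        ]
        score = self.w_p2[digits[1]] + self.w_cterm[digits[length - 1]]
        interior = [0] + list(range(2, length - 1))
        bg = np.zeros(len(codes), dtype=np.float64)
        for i in interior:
            bg += self.w_background[digits[i]]
        score = score + bg / len(interior)
        if self.noise_scale:
            score = score + self.noise_scale * _hash_unit(codes, self._key)
        return score

    def score(self, peptide: str) -> float:
        code = np.array([encode_peptide(peptide)], dtype=np.uint64)
        return float(self.score_codes(code, len(peptide))[0])

    def max_score(self, length: int) -> float:
        """Analytic maximum for ``noise_scale == 0`` at a given length."""
        return float(self.w_p2.max() + self.w_cterm.max() + self.w_background.max())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "type": "synthetic",
            "name": self.name,
            "supertype": self.supertype,
            "w_p2": self.w_p2.tolist(),
            "w_cterm": self.w_cterm.tolist(),
            "w_background": self.w_background.tolist(),
            "noise_scale": self.noise_scale,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticAlleleModel":
        if d.get("type", "synthetic") != "synthetic":
            raise ValueError(f"not a synthetic model spec: {d.get('type')!r}")
        return cls(
            name=d["name"],
            supertype=d["supertype"],
            w_p2=np.asarray(d["w_p2"]),
            w_cterm=np.asarray(d["w_cterm"]),
            w_background=np.asarray(d["w_background"]),
            noise_scale=float(d["noise_scale"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# Rank reference
# ---------------------------------------------------------------------------


@dataclass
class RankReference:
    """An allele's pool of reference binding scores for percentile ranking."""

    allele: str
    scores: np.ndarray  # sorted ascending internally
    per_length_counts: dict[int, int]
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=np.float64))
        if self.scores.size == 0:
            raise ValueError("rank reference pool is empty")

    @property
    def size(self) -> int:
        return int(self.scores.size)

    @property
    def pool(self) -> np.ndarray:
        """Reference scores sorted descending (strongest first)."""
        return self.scores[::-1]

    # -- persistence (plain text: JSON header line + one score per line) ----

    def save(self, path: str | Path) -> None:
        header = {
            "allele": self.allele,
            "seed": self.seed,
            "per_length_counts": {str(k): v for k, v in self.per_length_counts.items()},
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for s in self.pool:
                fh.write(f"{float(s).hex()}\n")

    @classmethod
    def load(cls, path: str | Path) -> "RankReference":
        with open(path) as fh:
            header = json.loads(fh.readline())
            scores = np.array([float.fromhex(line.strip()) for line in fh if line.strip()])
        return cls(
            allele=header["allele"],
            scores=scores,
            per_length_counts={int(k): v for k, v in header["per_length_counts"].items()},
            seed=int(header["seed"]),
        )


def build_rank_reference(
    model: BindingModel,
    reference_proteome: ProteomeSet | None,
    lengths: Sequence[int] = REFERENCE_LENGTHS,
    per_length_count: int = DEFAULT_PER_LENGTH_COUNT,
    seed: int = 0,
    digest: "DigestResult | None" = None,
) -> RankReference:
    """Self-calibrate an allele: sample and score reference digestion products.

    For each length, ``per_length_count`` distinct digestion products of the
    reference proteome are drawn uniformly without replacement (seeded),
    scored, pooled and sorted. At the default settings (5 lengths x 25,000)
    the pool holds 125,000 scores. Pass a precomputed ``digest`` to reuse
    one digestion across a whole allele panel.
    """
    if digest is None:
        if reference_proteome is None:
            raise ValueError("need a reference proteome or a precomputed digest")
        digest = digest_proteome(reference_proteome, lengths=lengths)
    rng = np.random.default_rng(seed)
    pools: list[np.ndarray] = []
    per_length: dict[int, int] = {}
    for k in sorted(digest.codes_by_length):
        codes = digest.codes_by_length[k]
        if len(codes) < per_length_count:
            raise ValueError(
                f"reference proteome yields only {len(codes)} unique products of "
                f"length {k}; need {per_length_count} "
                f"(short by {per_length_count - len(codes)})"
            )
        sel = rng.choice(len(codes), size=per_length_count, replace=False)
        pools.append(model.score_codes(codes[sel], k))
        per_length[k] = per_length_count
    return RankReference(
        allele=getattr(model, "name", "allele"),
        scores=np.concatenate(pools),
        per_length_counts=per_length,
        seed=seed,
    )


def build_panel_references(
    panel,
    reference_proteome: ProteomeSet,
    lengths: Sequence[int] = REFERENCE_LENGTHS,
    per_length_count: int = DEFAULT_PER_LENGTH_COUNT,
    seed: int = 0,
) -> dict[str, RankReference]:
    """Rank references for every panel allele, sharing one digestion.

    Each allele gets its own sampling substream (seed + allele index)."""
    digest = digest_proteome(reference_proteome, lengths=lengths)
    return {
        entry.allele: build_rank_reference(
            entry.model,
            None,
            lengths=lengths,
            per_length_count=per_length_count,
            seed=seed + i,
            digest=digest,
        )
        for i, entry in enumerate(panel)
    }


def percentile_ranks(scores: np.ndarray, reference: RankReference) -> np.ndarray:
    """Vectorized percentile ranks in [0, 100].

    rank = 100 * |{r in pool : r > score}| / pool_size. Ties with pool
    members do not count against the query, so a score equal to the pool
    maximum ranks 0 and one below the pool minimum ranks 100.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = reference.size
    greater = n - np.searchsorted(reference.scores, scores, side="right")
    return 100.0 * greater / n


def percentile_rank(score: float, reference: RankReference) -> float:
    return float(percentile_ranks(np.array([score]), reference)[0])


def is_binder(rank: float, threshold: float = DEFAULT_RANK_THRESHOLD) -> bool:
    """Binder call at a percentile-rank threshold (inclusive boundary)."""
    if not 0.0 <= rank <= 100.0:
        raise ValueError(f"rank {rank} outside [0, 100]")
    return rank <= threshold


def sample_reference_like_peptides(
    background: np.ndarray | None,
    n: int,
    lengths: Sequence[int] = REFERENCE_LENGTHS,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Draw i.i.d. peptides exchangeable with a uniform-per-length reference
    pool: length uniform over ``lengths``, residues from ``background``
    (default uniform over 20). Returns packed codes grouped by length."""
    rng = np.random.default_rng(seed)
    lengths = sorted(set(int(k) for k in lengths))
    p = None if background is None else np.asarray(background, dtype=np.float64)
    ks = rng.choice(lengths, size=n, replace=True)
    out: dict[int, np.ndarray] = {}
    for k in lengths:
        m = int((ks == k).sum())
        if m == 0:
            out[k] = np.empty(0, dtype=np.uint64)
            continue
        draws = rng.choice(20, size=(m, k), replace=True, p=p).astype(np.uint64)
        codes = np.zeros(m, dtype=np.uint64)
        for i in range(k):
            codes |= (draws[:, i] + np.uint64(1)) << np.uint64(5 * i)
        out[k] = codes
    return out
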