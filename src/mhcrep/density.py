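"""Epitope densities, group statistics, permutation test, sweep screening.

The epitope density of a (virus, allele) pair is the observed number of
unique binder peptides divided by the number expected by chance at the
rank threshold; with a 1% threshold the expectation is 1% of the virus's
total digestion products. Under score exchangeability with the reference
pool the density is 1 in expectation, so densities below/above 1 flag
under-/over-presentation.

Group contrasts (e.g. A02-supertype HLA vs non-A02 HLA vs Patr vs Gogo)
use two-sided Mann–Whitney U tests with Bonferroni correction across all
unordered group pairs; a one-sided permutation test asks whether a focal
allele group presents a particular virus at lower density than the rest.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding import RankReference, percentile_ranks
from .digestion import VIRAL_LENGTHS, digest
from .io import ProteomeSet
from .repertoire import BinderRepertoire


@dataclass
class DensityTable:
    """Epitope densities indexed by (virus, allele) plus group labels."""

    values: pd.DataFrame  # index: virus ids, columns: allele names
    groups: dict[str, str]  # allele -> group label
    totals: dict[str, int]  # virus -> total digestion products
    threshold: float

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("densities must be non-negative")

    @property
    def viruses(self) -> list[str]:
        return list(self.values.index)

    @property
    def alleles(self) -> list[str]:
        return list(self.values.columns)

    def group_alleles(self, group: str) -> list[str]:
        return [a for a in self.alleles if self.groups.get(a) == group]

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("virus").to_csv(path, sep="\t", float_format="%.6f")


def epitope_density(
    repertoire: BinderRepertoire,
    virus: str,
    allele: str,
    threshold: float | None = None,
) -> float:
    """density = |binders(allele, virus)| / ((threshold/100) x total products)."""
    thr = repertoire.threshold if threshold is None else threshold
    total = repertoire.total_products[virus]
    if total == 0:
        raise ValueError(f"virus {virus!r} has zero digestion products")
    expected = thr / 100.0 * total
    return repertoire.n_binders(allele, virus) / expected


def density_table(
    repertoire: BinderRepertoire, groups: Mapping[str, str] | None = None
) -> DensityTable:
    groups = dict(groups) if groups else {a: "all" for a in repertoire.alleles}
    data = {
        allele: [epitope_density(repertoire, v, allele) for v in repertoire.viruses]
        for allele in repertoire.alleles
    }
    return DensityTable(
        values=pd.DataFrame(data, index=repertoire.viruses),
        groups=groups,
        totals=dict(repertoire.total_products),
        threshold=repertoire.threshold,
    )


def mean_density(
    table: DensityTable, allele: str, virus_subset: Sequence[str] | None = None
) -> float:
    subset = list(virus_subset) if virus_subset is not None else table.viruses
    if not subset:
        raise ValueError("virus subset is empty")
    return float(table.values.loc[subset, allele].mean())


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    p_adjusted: float
    n_a: int
    n_b: int


def group_compare(
    table: DensityTable, unit: str = "per_allele_virus"
) -> list[GroupComparison]:
    """Pairwise two-sided Mann–Whitney U across groups, Bonferroni-corrected.

    ``unit="per_allele_virus"`` pools every (allele, virus) density value
    within a group; ``unit="per_allele"`` first averages each allele over
    viruses. Small tie-free samples use the exact null distribution, larger
    or tied samples the tie-corrected normal approximation (SciPy's
    ``method="auto"``).
    """
    if unit not in ("per_allele_virus", "per_allele"):
        raise ValueError(f"unknown unit {unit!r}")
    labels = sorted(set(table.groups[a] for a in table.alleles))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples: dict[str, np.ndarray] = {}
    for g in labels:
        alleles = table.group_alleles(g)
        if not alleles:
            raise ValueError(f"group {g!r} has no alleles")
        if unit == "per_allele_virus":
            samples[g] = table.values[alleles].to_numpy().ravel()
        else:
            samples[g] = table.values[alleles].mean(axis=0).to_numpy()
    pairs = list(itertools.combinations(labels, 2))
    out: list[GroupComparison] = []
    for ga, gb in pairs:
        x, y = samples[ga], samples[gb]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        out.append(
            GroupComparison(
                group_a=ga,
                group_b=gb,
                u_statistic=float(res.statistic),
                p_value=float(res.pvalue),
                p_adjusted=min(1.0, float(res.pvalue) * len(pairs)),
                n_a=len(x),
                n_b=len(y),
            )
        )
    return out


def write_comparisons(comparisons: Sequence[GroupComparison], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_a\tgroup_b\tU\tn_a\tn_b\tp\tp_bonferroni\n")
        for c in comparisons:
            fh.write(
                f"{c.group_a}\t{c.group_b}\t{c.u_statistic:.1f}\t{c.n_a}\t{c.n_b}"
                f"\t{c.p_value:.6g}\t{c.p_adjusted:.6g}\n"
            )


def permutation_test(
    table: DensityTable,
    virus: str,
    focal_group: str,
    n_perm: int = 10_000,
    seed: int = 0,
    group_labels: Mapping[str, str] | None = None,
) -> float:
    """One-sided label-permutation p-value for "focal group presents this
    virus at lower density".

    Statistic: mean focal density minus mean density of the other alleles,
    for the given virus. When all label assignments can be enumerated
    within ``n_perm`` the p-value is exact (fraction of assignments with a
    statistic <= observed); otherwise ``n_perm`` random assignments are
    drawn and the +1 convention keeps p > 0.
    """
    groups = dict(group_labels) if group_labels is not None else table.groups
    values = table.values.loc[virus].to_numpy()
    alleles = table.alleles
    focal_idx = [i for i, a in enumerate(alleles) if groups.get(a) == focal_group]
    k, n = len(focal_idx), len(alleles)
    if k == 0 or k == n:
        raise ValueError("focal group must be a non-empty proper subset of alleles")

    def statistic(idx: Sequence[int]) -> float:
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        return float(values[sel].mean() - values[~sel].mean())

    observed = statistic(focal_idx)
    eps = 1e-12
    n_comb = math.comb(n, k)
    if n_comb <= n_perm:
        hits = sum(
            1 for idx in itertools.combinations(range(n), k)
            if statistic(idx) <= observed + eps
        )
        return hits / n_comb
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        if statistic(idx) <= observed + eps:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Sweep-candidate screening
# ---------------------------------------------------------------------------


def sweep_candidate_filter(
    table: DensityTable,
    focal_alleles: Sequence[str],
    other_alleles: Sequence[str],
    low: float = 1.0,
    high: float = 2.0,
    min_count: int = 10,
) -> list[str]:
    """Viruses under-presented by every focal allele yet well presented
    elsewhere.

    A virus passes iff its density is strictly below ``low`` for every
    focal allele AND strictly above ``high`` for at least ``min_count`` of
    the other alleles.
    """
    focal = list(focal_alleles)
    other = list(other_alleles)
    if not focal or not other:
        raise ValueError("focal and other allele sets must be non-empty")
    if set(focal) & set(other):
        raise ValueError("focal and other allele sets overlap")
    out: list[str] = []
    for virus in table.viruses:
        row = table.values.loc[virus]
        if (row[focal] < low).all() and int((row[other] > high).sum()) >= min_count:
            out.append(virus)
    return out


# ---------------------------------------------------------------------------
# Self-proteome presentation
# ---------------------------------------------------------------------------


def self_presentation(
    self_proteome: ProteomeSet,
    model,
    reference: RankReference,
    lengths: Sequence[int] = VIRAL_LENGTHS,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-protein expected vs observed binder counts on a host proteome.

    expected = (threshold/100) x the protein's digestion products;
    observed counts binder digestion products with multiplicity, so at a
    100% threshold the ratio is 1 by construction. The ratio column is NaN
    for proteins with no products of the configured lengths.
    """
    rows = []
    for rec in self_proteome.records:
        dig = digest(rec, lengths=lengths)
        expected = threshold / 100.0 * dig.total_products
        observed = 0
        for k, codes in dig.codes_by_length.items():
            if codes.size == 0:
                continue
            ranks = percentile_ranks(model.score_codes(codes, k), reference)
            observed += int(dig.counts_by_length[k][ranks <= threshold].sum())
        ratio = observed / expected if expected > 0 else float("nan")
        rows.append((rec.id, dig.total_products, expected, observed, ratio))
    return pd.DataFrame(
        rows, columns=["protein", "n_products", "expected", "observed", "ratio"]
    ).set_index("protein")
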