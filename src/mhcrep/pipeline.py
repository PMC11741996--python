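"""End-to-end orchestration of the repertoire analysis stages.

Stages (in dependency order): collapse → rankref → repertoire →
{cluster, density → filter}, plus selfpres. Every stage reads and writes
plain-text artifacts (FASTA/TSV/Newick) in a workspace directory so each
intermediate is inspectable and diffable, and a manifest records the
configuration, seeds and per-stage counts. Re-running with the same
config and seed reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import binding, clustering, density, redundancy, repertoire as repertoire_mod
from .io import AllelePanel, ProteomeSet, read_allele_panel, read_fasta, read_proteome

STAGES = ("collapse", "rankref", "repertoire", "cluster", "density", "filter", "selfpres")

_DEPENDENCIES = {
    "collapse": (),
    "rankref": (),
    "repertoire": ("collapse", "rankref"),
    "cluster": ("repertoire",),
    "density": ("repertoire",),
    "filter": ("density",),
    "selfpres": ("rankref",),
}


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (defaults are the native
    analysis settings: lengths 8–11 viral / 8–12 reference, 25,000
    reference products per length, 1% rank threshold, 95% collapse
    threshold, 1000 bootstrap replicates of 20% of the viruses, and the
    <1 / >2 / ≥10-allele sweep-candidate filter)."""

    workspace: Path
    output: Path
    viral_lengths: tuple[int, ...] = (8, 9, 10, 11)
    reference_lengths: tuple[int, ...] = (8, 9, 10, 11, 12)
    per_length_count: int = 25_000
    rank_threshold: float = 1.0
    collapse_threshold: float = 95.0
    bootstrap_reps: int = 1000
    bootstrap_fraction: float = 0.2
    filter_low: float = 1.0
    filter_high: float = 2.0
    filter_min_count: int = 10
    focal_group: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.workspace = Path(self.workspace)
        self.output = Path(self.output)
        if not 0 < self.rank_threshold <= 100:
            raise ValueError("rank_threshold must be in (0, 100]")
        if not 0 < self.collapse_threshold <= 100:
            raise ValueError("collapse_threshold must be in (0, 100]")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % (2**31)
        )


def _require(path: Path, stage: str, produced_by: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {path} (produced by stage {produced_by!r})"
        )


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages; returns the manifest dictionary.

    Dependency violations (e.g. cluster requested before a repertoire
    exists) are reported before any work is done.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    out = config.output
    out.mkdir(parents=True, exist_ok=True)
    _LAST_REPERTOIRE.pop(out, None)
    _LAST_TABLE.pop(out, None)

    # pre-flight dependency check: every dependency either runs first or
    # has already left its artifact in the output directory
    artifacts = {
        "collapse": out / "retained_viruses.txt",
        "rankref": out / "rankref",
        "repertoire": out / "repertoire.tsv",
        "density": out / "density.tsv",
    }
    for s in stages:
        for dep in _DEPENDENCIES[s]:
            if dep not in stages and dep in artifacts:
                _require(artifacts[dep], s, dep)

    manifest: dict = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    panel: AllelePanel | None = None

    def get_panel() -> AllelePanel:
        nonlocal panel
        if panel is None:
            panel = read_allele_panel(config.workspace / "panel.tsv")
        return panel

    def load_retained_viruses() -> list[ProteomeSet]:
        _require(artifacts["collapse"], "repertoire", "collapse")
        ids = [
            line.strip()
            for line in open(artifacts["collapse"])
            if line.strip()
        ]
        return [read_proteome(config.workspace / "viruses" / f"{vid}.fasta") for vid in ids]

    for stage in stages:
        if stage == "collapse":
            virus_files = sorted((config.workspace / "viruses").glob("*.fasta"))
            if not virus_files:
                raise FileNotFoundError(f"no virus FASTA files under {config.workspace / 'viruses'}")
            viruses = [read_proteome(p) for p in virus_files]
            retained, cmap = redundancy.collapse(viruses, threshold=config.collapse_threshold)
            with open(artifacts["collapse"], "w") as fh:
                for v in retained:
                    fh.write(v.source_id + "\n")
            redundancy.write_cluster_map(cmap, out / "cluster_map.tsv")
            manifest["stages"]["collapse"] = {
                "n_input": len(viruses),
                "n_retained": len(retained),
            }
        elif stage == "rankref":
            ref_proteome = read_proteome(config.workspace / "reference.fasta")
            (out / "rankref").mkdir(exist_ok=True)
            refs = binding.build_panel_references(
                get_panel(),
                ref_proteome,
                lengths=config.reference_lengths,
                per_length_count=config.per_length_count,
                seed=config.stage_seed("rankref"),
            )
            for allele, ref in refs.items():
                ref.save(out / "rankref" / f"{allele}.txt")
            manifest["stages"]["rankref"] = {
                "n_alleles": len(get_panel()),
                "pool_size": config.per_length_count * len(config.reference_lengths),
            }
        elif stage == "repertoire":
            viruses = load_retained_viruses()
            refs = {
                e.allele: binding.RankReference.load(out / "rankref" / f"{e.allele}.txt")
                for e in get_panel()
            }
            rep = repertoire_mod.build_repertoire(
                get_panel(),
                viruses,
                refs,
                lengths=config.viral_lengths,
                threshold=config.rank_threshold,
            )
            rep.to_tsv(out / "repertoire.tsv")
            with open(out / "virus_totals.tsv", "w") as fh:
                fh.write("virus\ttotal_products\n")
                for vid in rep.viruses:
                    fh.write(f"{vid}\t{rep.total_products[vid]}\n")
            manifest["stages"]["repertoire"] = {
                "n_viruses": len(rep.viruses),
                "n_alleles": len(rep.alleles),
                "n_binder_pairs": sum(len(s) for s in rep.binders.values()),
            }
            _LAST_REPERTOIRE[out] = rep
        elif stage == "cluster":
            rep = _load_repertoire(config, out)
            dm = clustering.distance_matrix(rep)
            dm.to_tsv(out / "distances.tsv")
            dm.to_phylip(out / "distances.phylip")
            tree = clustering.upgma(dm)
            trees, freqs = clustering.bootstrap_supports(
                rep,
                n_reps=config.bootstrap_reps,
                fraction=config.bootstrap_fraction,
                seed=config.stage_seed("cluster"),
            )
            clustering.annotate_supports(tree, freqs)
            clustering.write_newick(tree, out / "upgma.nwk")
            consensus = clustering.extended_majority_consensus(trees)
            clustering.write_newick(consensus, out / "consensus.nwk")
            manifest["stages"]["cluster"] = {
                "n_alleles": len(dm.names),
                "bootstrap_reps": config.bootstrap_reps,
            }
        elif stage == "density":
            rep = _load_repertoire(config, out)
            table = density.density_table(rep, groups=get_panel().groups)
            table.to_tsv(out / "density.tsv")
            comparisons = density.group_compare(table)
            density.write_comparisons(comparisons, out / "group_comparisons.tsv")
            manifest["stages"]["density"] = {
                "n_cells": int(table.values.size),
                "n_comparisons": len(comparisons),
            }
            _LAST_TABLE[out] = table
        elif stage == "filter":
            table = _load_table(config, out)
            groups = get_panel().groups
            focal_group = config.focal_group or sorted(set(groups.values()))[0]
            focal = [a for a in table.alleles if groups[a] == focal_group]
            other = [a for a in table.alleles if groups[a] != focal_group]
            hits = density.sweep_candidate_filter(
                table,
                focal,
                other,
                low=config.filter_low,
                high=config.filter_high,
                min_count=config.filter_min_count,
            )
            with open(out / "sweep_candidates.txt", "w") as fh:
                for vid in hits:
                    fh.write(vid + "\n")
            manifest["stages"]["filter"] = {
                "focal_group": focal_group,
                "n_candidates": len(hits),
            }
        elif stage == "selfpres":
            selfp = read_proteome(config.workspace / "self.fasta")
            entry = get_panel().entries[0]
            ref = binding.RankReference.load(out / "rankref" / f"{entry.allele}.txt")
            df = density.self_presentation(
                selfp,
                entry.model,
                ref,
                lengths=config.viral_lengths,
                threshold=config.rank_threshold,
            )
            df.to_csv(out / "self_presentation.tsv", sep="\t", float_format="%.6f")
            manifest["stages"]["selfpres"] = {
                "allele": entry.allele,
                "n_proteins": len(df),
                "mean_ratio": float(df["ratio"].mean()),
            }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# Small in-process caches so run-all does not re-parse its own TSV output;
# stage boundaries still go through files when stages run in separate calls.
_LAST_REPERTOIRE: dict = {}
_LAST_TABLE: dict = {}


def _load_repertoire(config: RunConfig, out: Path):
    if out in _LAST_REPERTOIRE:
        return _LAST_REPERTOIRE[out]
    _require(out / "repertoire.tsv", "cluster/density", "repertoire")
    _require(out / "virus_totals.tsv", "cluster/density", "repertoire")
    binders: dict[tuple[str, str], set[str]] = {}
    alleles: list[str] = []
    with open(out / "repertoire.tsv") as fh:
        next(fh)
        for line in fh:
            allele, virus, pep = line.rstrip("\n").split("\t")
            if allele not in alleles:
                alleles.append(allele)
            binders.setdefault((allele, virus), set()).add(pep)
    totals: dict[str, int] = {}
    with open(out / "virus_totals.tsv") as fh:
        next(fh)
        for line in fh:
            vid, tot = line.rstrip("\n").split("\t")
            totals[vid] = int(tot)
    viruses = list(totals)
    full = {
        (a, v): frozenset(binders.get((a, v), frozenset()))
        for a in alleles
        for v in viruses
    }
    rep = repertoire_mod.BinderRepertoire(
        alleles=alleles,
        viruses=viruses,
        binders=full,
        threshold=config.rank_threshold,
        total_products=totals,
    )
    _LAST_REPERTOIRE[out] = rep
    return rep


def _load_table(config: RunConfig, out: Path):
    if out in _LAST_TABLE:
        return _LAST_TABLE[out]
    rep = _load_repertoire(config, out)
    panel = read_allele_panel(config.workspace / "panel.tsv")
    table = density.density_table(rep, groups=panel.groups)
    _LAST_TABLE[out] = table
    return table
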