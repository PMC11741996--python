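"""Synthetic inputs: reference proteomes, virus families, allele panels.

Everything the pipeline consumes can be generated here with planted ground
truth: virus sets with a controllable family structure (for redundancy
collapsing), a reference proteome for rank calibration, and allele panels
whose anchor preferences form supertype groups with tunable within-group
divergence. Fixed seed + config means byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .binding import SyntheticAlleleModel
from .io import (
    STANDARD_AA,
    AllelePanel,
    PanelEntry,
    ProteinRecord,
    ProteomeSet,
    write_allele_panel,
    write_fasta,
)

# stream tags so each generator gets an independent substream of the seed
_STREAM_REFERENCE = 1
_STREAM_VIRUS = 2
_STREAM_PANEL = 3
_STREAM_SELF = 4


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic workspace.

    Defaults mirror the pipeline's native scale where it is procedure-
    determined (a 5000-protein reference for 25,000 unique products per
    length 8–12) and a desk-scale virus panel elsewhere (50 viruses of 10
    proteins x 300 aa; 4 supertypes x 6 alleles = 24 alleles).
    """

    seed: int = 0
    background: np.ndarray | None = None  # residue frequencies, default uniform
    # reference proteome (rank calibration)
    n_reference_proteins: int = 5000
    reference_length_range: tuple[int, int] = (100, 600)
    # virus set
    n_viruses: int = 50
    proteins_per_virus: int = 10
    protein_length: int = 300
    n_families: int | None = None  # None: every virus its own family
    family_mutation_rate: float = 0.02
    virus_background: np.ndarray | None = None  # default: same as background
    # allele panel
    n_supertypes: int = 4
    alleles_per_supertype: int = 6
    anchor_strength: float = 6.0
    anchor_divergence: float = 0.25
    background_weight_scale: float = 0.3
    noise_scale: float = 0.5
    # self proteome
    n_self_proteins: int = 200

    def __post_init__(self) -> None:
        for name in (
            "n_reference_proteins",
            "n_viruses",
            "proteins_per_virus",
            "protein_length",
            "n_supertypes",
            "alleles_per_supertype",
            "n_self_proteins",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.family_mutation_rate <= 1.0:
            raise ValueError("family_mutation_rate must be in [0, 1]")
        if self.n_families is not None and not 1 <= self.n_families <= self.n_viruses:
            raise ValueError("n_families must be in [1, n_viruses]")
        for name in ("background", "virus_background"):
            p = getattr(self, name)
            if p is not None:
                p = np.asarray(p, dtype=np.float64)
                if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                    raise ValueError(f"{name} must be 20 non-negative frequencies summing to 1")
                setattr(self, name, p)

    def _bg(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1 / 20)
        return self.background

    def _virus_bg(self) -> np.ndarray:
        if self.virus_background is None:
            return self._bg()
        return self.virus_background


def _random_sequence(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    idx = rng.choice(20, size=length, replace=True, p=p)
    return "".join(STANDARD_AA[i] for i in idx)


def generate_reference_proteome(
    config: GeneratorConfig, n: int | None = None, source_id: str = "reference"
) -> ProteomeSet:
    """I.i.d. random proteins from the background distribution; lengths
    uniform over the configured range."""
    rng = np.random.default_rng([config.seed, _STREAM_REFERENCE])
    n = n if n is not None else config.n_reference_proteins
    lo, hi = config.reference_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    p = config._bg()
    records = [
        ProteinRecord(
            id=f"{source_id}_{i:05d}",
            description="synthetic random protein",
            residues=_random_sequence(rng, int(L), p),
        )
        for i, L in enumerate(lengths)
    ]
    return ProteomeSet(source_id=source_id, records=records)


def generate_self_proteome(config: GeneratorConfig) -> ProteomeSet:
    """Host self-proteome stand-in: same generative process, separate stream."""
    rng = np.random.default_rng([config.seed, _STREAM_SELF])
    lo, hi = config.reference_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_self_proteins)
    p = config._bg()
    records = [
        ProteinRecord(
            id=f"self_{i:05d}",
            description="synthetic self protein",
            residues=_random_sequence(rng, int(L), p),
        )
        for i, L in enumerate(lengths)
    ]
    return ProteomeSet(source_id="self", records=records)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution at the given rate; substitutions draw uniformly
    from the 19 other residues, so expected identity is 1 − rate."""
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        lut = {aa: [b for b in STANDARD_AA if b != aa] for aa in STANDARD_AA}
        pos = np.nonzero(hit)[0]
        for i in pos:
            choices = lut[chr(arr[i])]
            arr[i] = ord(choices[rng.integers(len(choices))])
    return arr.tobytes().decode("ascii")


def generate_virus_set(
    config: GeneratorConfig,
) -> tuple[list[ProteomeSet], dict[str, int]]:
    """Virus proteomes with planted family structure.

    Each family descends from an independent random ancestor proteome;
    members substitute each site at ``family_mutation_rate``. Returns the
    viruses and a map virus id -> family index (the redundancy ground
    truth: within-family identity ~ (1 − rate)², between-family identity
    is that of unrelated random sequences).
    """
    rng = np.random.default_rng([config.seed, _STREAM_VIRUS])
    n_fam = config.n_families if config.n_families is not None else config.n_viruses
    p = config._virus_bg()
    ancestors = [
        [
            _random_sequence(rng, config.protein_length, p)
            for _ in range(config.proteins_per_virus)
        ]
        for _ in range(n_fam)
    ]
    viruses: list[ProteomeSet] = []
    labels: dict[str, int] = {}
    for i in range(config.n_viruses):
        fam = i * n_fam // config.n_viruses
        vid = f"virus_{i:03d}"
        records = [
            ProteinRecord(
                id=f"{vid}_p{j:02d}",
                description=f"synthetic viral protein (family {fam})",
                residues=_mutate(rng, ancestors[fam][j], config.family_mutation_rate),
            )
            for j in range(config.proteins_per_virus)
        ]
        viruses.append(ProteomeSet(source_id=vid, records=records, host_tags=["synthetic"]))
        labels[vid] = fam
    return viruses, labels


def generate_allele_panel(
    config: GeneratorConfig,
) -> tuple[AllelePanel, dict[str, int]]:
    """Allele panel with planted supertype structure.

    Each supertype has an archetype with a distinct strongly preferred P2
    residue and a distinct preferred C-terminal residue; each allele is the
    archetype plus a seeded Gaussian perturbation of magnitude
    ``anchor_divergence`` on all weight tables. With divergence 0 the
    alleles of a supertype are identical binding functions.
    """
    if config.n_supertypes > 20:
        raise ValueError("cannot assign distinct anchor residues to more than 20 supertypes")
    rng = np.random.default_rng([config.seed, _STREAM_PANEL])
    entries: list[PanelEntry] = []
    labels: dict[str, int] = {}
    for s in range(config.n_supertypes):
        p2_pref = s
        c_pref = (s + 7) % 20
        arch_p2 = rng.normal(0.0, 0.2, 20)
        arch_p2[p2_pref] += config.anchor_strength
        arch_c = rng.normal(0.0, 0.2, 20)
        arch_c[c_pref] += config.anchor_strength
        arch_bg = rng.normal(0.0, config.background_weight_scale, 20)
        for a in range(config.alleles_per_supertype):
            name = f"SYN-{s:02d}:{a:02d}"
            model = SyntheticAlleleModel(
                name=name,
                supertype=f"ST{s}",
                w_p2=arch_p2 + rng.normal(0.0, config.anchor_divergence, 20),
                w_cterm=arch_c + rng.normal(0.0, config.anchor_divergence, 20),
                w_background=arch_bg + rng.normal(0.0, config.anchor_divergence, 20),
                noise_scale=config.noise_scale,
                seed=config.seed,
            )
            entries.append(PanelEntry(allele=name, group=f"ST{s}", model=model))
            labels[name] = s
    return AllelePanel(entries=entries), labels


def make_low_density_supertype(
    config: GeneratorConfig,
    panel: AllelePanel,
    focal_group: str,
    sharpening: float = 0.8,
) -> tuple[GeneratorConfig, AllelePanel]:
    """Plant the low-epitope-density contrast for one supertype.

    Because percentile ranks are self-calibrated per allele, every allele
    calls ~threshold% of exchangeable peptides binders no matter how
    selective its motif is — sharpening anchors alone cannot move the
    density off 1. A group presents viruses at low density only when the
    peptides its motif prefers are scarcer in viral proteomes than in the
    calibration reference. This helper therefore (a) sharpens the focal
    alleles' anchor weights by (1 + sharpening) and (b) returns a config
    whose ``virus_background`` depletes the focal anchors' preferred
    residues by (1 − sharpening), renormalized. Sharpening 0 changes
    nothing; strong sharpening makes the focal group's densities
    systematically lowest while mildly raising the others.
    """
    if not 0.0 <= sharpening <= 1.0:
        raise ValueError("sharpening must be in [0, 1]")
    focal_entries = [e for e in panel.entries if e.group == focal_group]
    if not focal_entries:
        raise ValueError(f"no alleles in focal group {focal_group!r}")
    if sharpening == 0.0:
        return config, panel

    # residues the focal motifs anchor on (argmax of each anchor table)
    scarce: set[int] = set()
    for e in focal_entries:
        m: SyntheticAlleleModel = e.model  # type: ignore[assignment]
        scarce.add(int(np.argmax(m.w_p2)))
        scarce.add(int(np.argmax(m.w_cterm)))

    new_entries: list[PanelEntry] = []
    for e in panel.entries:
        m = e.model  # type: ignore[assignment]
        if e.group == focal_group:
            m = SyntheticAlleleModel(
                name=m.name,
                supertype=m.supertype,
                w_p2=m.w_p2 * (1.0 + sharpening),
                w_cterm=m.w_cterm * (1.0 + sharpening),
                w_background=m.w_background,
                noise_scale=m.noise_scale,
                seed=m.seed,
            )
        new_entries.append(PanelEntry(allele=e.allele, group=e.group, model=m))

    vb = config._virus_bg().copy()
    for r in scarce:
        vb[r] *= 1.0 - sharpening
    vb /= vb.sum()
    new_config = dataclasses.replace(config, virus_background=vb)
    return new_config, AllelePanel(entries=new_entries)


# ---------------------------------------------------------------------------
# Workspace materialization
# ---------------------------------------------------------------------------


def write_workspace(config: GeneratorConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic input workspace (FASTA + panel TSV + truth).

    Layout: reference.fasta, self.fasta, viruses/<id>.fasta,
    panel.tsv + models/<allele>.json, truth_families.tsv, truth_supertypes.tsv.
    """
    outdir = Path(outdir)
    (outdir / "viruses").mkdir(parents=True, exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)

    reference = generate_reference_proteome(config)
    write_fasta(reference.records, outdir / "reference.fasta")
    selfp = generate_self_proteome(config)
    write_fasta(selfp.records, outdir / "self.fasta")

    viruses, fam_labels = generate_virus_set(config)
    for v in viruses:
        write_fasta(v.records, outdir / "viruses" / f"{v.source_id}.fasta")
    with open(outdir / "truth_families.tsv", "w") as fh:
        fh.write("virus\tfamily\n")
        for vid, fam in fam_labels.items():
            fh.write(f"{vid}\t{fam}\n")

    panel, st_labels = generate_allele_panel(config)
    for e in panel.entries:
        with open(outdir / "models" / f"{e.allele}.json", "w") as fh:
            json.dump(e.model.to_dict(), fh)  # type: ignore[union-attr]
    write_allele_panel(panel, outdir / "panel.tsv", lambda e: f"synthetic:models/{e.allele}.json")
    with open(outdir / "truth_supertypes.tsv", "w") as fh:
        fh.write("allele\tsupertype\n")
        for name, s in st_labels.items():
            fh.write(f"{name}\t{s}\n")
    return {
        "n_reference_proteins": len(reference),
        "n_self_proteins": len(selfp),
        "n_viruses": len(viruses),
        "n_alleles": len(panel),
    }
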