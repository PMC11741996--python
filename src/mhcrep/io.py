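"""Protein FASTA and allele-panel input/output.

The pipeline consumes three kinds of protein FASTA files (per-virus
proteomes, a rank-calibration reference proteome, and a host self-proteome)
plus a tab-separated allele panel that names each MHC allele, its group
label (e.g. a supertype or species tag) and the binding model that scores
peptides for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: Letters that occur in real protein FASTA but cannot be scored by
#: binding predictors (ambiguity codes, rare residues, stop).
NONSTANDARD_AA = frozenset("XBZJUO*")


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    ``residues`` may contain nonstandard letters until the record has been
    passed through :func:`sanitize_record`; downstream digestion masks any
    position that is not one of the 20 standard residues.
    """

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.residues:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteomeSet:
    """An ordered set of proteins from one source (a virus, a host, ...)."""

    source_id: str
    records: list[ProteinRecord]
    host_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"proteome {self.source_id!r} has no records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(
                    f"duplicate record id {rec.id!r} in proteome {self.source_id!r}"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)


@dataclass(frozen=True)
class PanelEntry:
    allele: str
    group: str
    model: object  # any object satisfying the BindingModel contract


@dataclass
class AllelePanel:
    """Ordered list of alleles with group labels and binding models."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        names = [e.allele for e in self.entries]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate allele name {dup!r} in panel")
        for e in self.entries:
            if not e.group:
                raise ValueError(f"allele {e.allele!r} has an empty group label")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def alleles(self) -> list[str]:
        return [e.allele for e in self.entries]

    @property
    def groups(self) -> dict[str, str]:
        return {e.allele: e.group for e in self.entries}

    def model_for(self, allele: str) -> object:
        for e in self.entries:
            if e.allele == allele:
                return e.model
        raise KeyError(allele)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The header up to the first whitespace becomes the record id, the
    remainder its description. Duplicate ids and empty files are errors
    rather than being silently tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, description=desc, residues=str(rec.seq).upper())
        )
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as protein FASTA, sequence lines wrapped at 60 columns."""
    path = Path(path)
    seqrecs = []
    for rec in records:
        r = SeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
        seqrecs.append(r)
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def read_proteome(path: str | Path, source_id: str | None = None) -> ProteomeSet:
    """Read one FASTA file as a single proteome (source id defaults to stem)."""
    path = Path(path)
    return ProteomeSet(source_id=source_id or path.stem, records=read_fasta(path))


# ---------------------------------------------------------------------------
# Sanitization
# ---------------------------------------------------------------------------


def sanitize_record(
    record: ProteinRecord, policy: str = "drop_nonstandard_peptides"
) -> tuple[ProteinRecord, np.ndarray]:
    """Validate residues and return ``(record, mask)``.

    ``mask`` is a boolean array flagging positions whose residue is not one
    of the 20 standard amino acids. Under ``drop_nonstandard_peptides`` the
    record is kept and the mask tells digestion to exclude every peptide
    window that overlaps a flagged position (predictors cannot score such
    windows). Under ``reject`` any nonstandard letter raises.
    """
    if policy not in ("drop_nonstandard_peptides", "reject"):
        raise ValueError(f"unknown sanitization policy {policy!r}")
    residues = record.residues.upper()
    mask = np.fromiter(
        (aa not in _STANDARD_SET for aa in residues), dtype=bool, count=len(residues)
    )
    bad = sorted({residues[i] for i in np.nonzero(mask)[0]})
    if bad:
        unknown = [b for b in bad if b not in NONSTANDARD_AA]
        if unknown:
            raise ValueError(
                f"record {record.id!r} contains non-amino-acid characters {unknown}"
            )
        if policy == "reject":
            raise ValueError(
                f"record {record.id!r} contains nonstandard residues {bad}"
            )
    if residues != record.residues:
        record = ProteinRecord(record.id, record.description, residues)
    return record, mask


# ---------------------------------------------------------------------------
# Allele panel TSV
# ---------------------------------------------------------------------------
# Format: three tab-separated columns (allele_name, group_label, model_spec);
# lines starting with '#' are comments. A model_spec of the form
# "synthetic:<relative/path.json>" points at a JSON-serialized synthetic
# allele model resolved relative to the panel file.


def write_allele_panel(
    panel: AllelePanel, path: str | Path, model_spec: Callable[[PanelEntry], str]
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# allele_name\tgroup_label\tmodel_spec\n")
        for e in panel.entries:
            fh.write(f"{e.allele}\t{e.group}\t{model_spec(e)}\n")


def read_allele_panel(
    path: str | Path, model_loader: Callable[[str, Path], object] | None = None
) -> AllelePanel:
    """Read a panel TSV; ``model_loader(spec, base_dir)`` materializes models.

    The default loader understands ``synthetic:<path.json>`` specs.
    """
    path = Path(path)
    if model_loader is None:
        model_loader = _default_model_loader
    entries: list[PanelEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            allele, group, spec = parts
            entries.append(
                PanelEntry(allele=allele, group=group, model=model_loader(spec, path.parent))
            )
    if not entries:
        raise ValueError(f"no panel entries in {path}")
    return AllelePanel(entries=entries)


def _default_model_loader(spec: str, base_dir: Path) -> object:
    from .binding import SyntheticAlleleModel

    if spec.startswith("synthetic:"):
        model_path = base_dir / spec[len("synthetic:"):]
        with open(model_path) as fh:
            return SyntheticAlleleModel.from_dict(json.load(fh))
    raise ValueError(f"unsupported model spec {spec!r}")
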