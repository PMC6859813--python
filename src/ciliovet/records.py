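"""Domain records: sequences with provenance, and per-taxon metadata.

Every sequence moving through the pipeline is a :class:`SeqRecordX` — a thin
record binding the residues to the taxon it came from, that taxon's class
label and provenance, and (in synthetic mode) its ground-truth origin.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Provenance(str, enum.Enum):
    """Where a library came from; drives the composition filters.

    ``genome_anchor`` marks sequences from an axenic genome assembly whose
    taxonomic origin is beyond doubt — the anchor required inside any
    accepted clade. ``curated`` corresponds to curated transcriptome
    collections (MMETSP-like), ``sra`` to re-assembled public read archives,
    ``transcriptome`` to in-house assemblies.
    """

    genome_anchor = "genome_anchor"
    transcriptome = "transcriptome"
    sra = "sra"
    curated = "curated"


HOST_GROUP = "host_group"
OUTGROUP = "outgroup"
CILIATE_CLASS_PREFIX = "ciliate_class:"


def is_ciliate(class_label: str) -> bool:
    """Host-group and named ciliate classes count as ciliate; outgroup does not."""
    return class_label == HOST_GROUP or class_label.startswith(CILIATE_CLASS_PREFIX)


@dataclass(frozen=True)
class TaxonMeta:
    """Per-taxon metadata row (taxon table, one row per taxon).

    class_label is one of ``host_group``, ``ciliate_class:<name>`` or
    ``outgroup``; provenance flags whether the taxon contributes a genome
    anchor.
    """

    taxon_id: str
    class_label: str
    provenance: Provenance
    display_name: str = ""

    def __post_init__(self):
        if not (
            self.class_label in (HOST_GROUP, OUTGROUP)
            or self.class_label.startswith(CILIATE_CLASS_PREFIX)
        ):
            raise ValueError(f"bad class_label {self.class_label!r} for {self.taxon_id}")

    @property
    def is_ciliate(self) -> bool:
        return is_ciliate(self.class_label)


@dataclass
class SeqRecordX:
    """A nucleotide or protein sequence plus pipeline metadata.

    ``origin`` is only set in synthetic mode: one of ``host``,
    ``prey_shared``, ``prey_klepto_unique``.
    """

    id: str
    seq: str
    taxon_id: Optional[str] = None
    class_label: Optional[str] = None
    provenance: Optional[Provenance] = None
    origin: Optional[str] = None
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped_len(self) -> int:
        return len(self.seq) - self.seq.count("-")


@dataclass
class TaxonTable:
    """Validated collection of TaxonMeta rows keyed by taxon_id."""

    rows: dict[str, TaxonMeta] = field(default_factory=dict)

    @classmethod
    def from_list(cls, metas) -> "TaxonTable":
        rows: dict[str, TaxonMeta] = {}
        for m in metas:
            if m.taxon_id in rows:
                raise ValueError(f"duplicate taxon_id {m.taxon_id!r}")
            rows[m.taxon_id] = m
        return cls(rows)

    def __getitem__(self, taxon_id: str) -> TaxonMeta:
        return self.rows[taxon_id]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.rows

    def __iter__(self):
        return iter(self.rows.values())

    def __len__(self) -> int:
        return len(self.rows)

    def ciliate_taxa(self) -> list[str]:
        return [m.taxon_id for m in self if m.is_ciliate]

    def outgroup_taxa(self) -> list[str]:
        return [m.taxon_id for m in self if m.class_label == OUTGROUP]

    def host_taxa(self) -> list[str]:
        return [m.taxon_id for m in self if m.class_label == HOST_GROUP]

    def annotate(self, rec: SeqRecordX) -> SeqRecordX:
        """Bind a record to its taxon's class label and provenance."""
        if rec.taxon_id is None or rec.taxon_id not in self.rows:
            raise KeyError(f"record {rec.id}: unknown taxon {rec.taxon_id!r}")
        m = self.rows[rec.taxon_id]
        rec.class_label = m.class_label
        rec.provenance = m.provenance
        return rec
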