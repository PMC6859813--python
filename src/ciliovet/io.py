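"""Readers and writers for the pipeline's interchange formats.

FASTA (nucleotide/protein, aligned or not), Newick, relaxed PHYLIP with a
partition file, and tab-separated tables (taxon metadata, annotations,
hits, decisions). All interchange coordinates are 1-based inclusive;
everything in memory is 0-based half-open.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Provenance, SeqRecordX, TaxonMeta, TaxonTable

logger = logging.getLogger("ciliovet")

_NT = set("ACGTUN-")
_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")


class FormatError(ValueError):
    pass


def _check_alphabet(seq: str, alphabet: str, rec_id: str) -> None:
    allowed = _NT if alphabet == "nt" else _AA
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise FormatError(
                f"record {rec_id!r}: illegal {alphabet} character {ch!r} at position {i + 1}"
            )


def read_fasta(path, alphabet: str = "aa") -> list[SeqRecordX]:
    """Read a FASTA file into SeqRecordX records (uppercased, ids unique)."""
    if alphabet not in ("nt", "aa"):
        raise ValueError("alphabet must be 'nt' or 'aa'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[SeqRecordX] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _check_alphabet(seq, alphabet, rec.id)
        seen[rec.id] = seen.get(rec.id, 0) + 1
        out.append(SeqRecordX(id=rec.id, seq=seq, description=rec.description))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FormatError(f"duplicate sequence ids: {dups}")
    return out


def write_fasta(records: Iterable[SeqRecordX], path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_taxon_table(path) -> TaxonTable:
    """TSV with columns taxon_id, class_label, provenance, display_name."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas = [
        TaxonMeta(
            taxon_id=row.taxon_id,
            class_label=row.class_label,
            provenance=Provenance(row.provenance),
            display_name=getattr(row, "display_name", ""),
        )
        for row in df.itertuples()
    ]
    return TaxonTable.from_list(metas)


def write_taxon_table(table: TaxonTable, path) -> None:
    pd.DataFrame(
        [
            {
                "taxon_id": m.taxon_id,
                "class_label": m.class_label,
                "provenance": m.provenance.value,
                "display_name": m.display_name,
            }
            for m in table
        ]
    ).to_csv(path, sep="\t", index=False)


def read_newick(path, taxa: Optional[Iterable[str]] = None):
    from .trees import PhyloTree

    return PhyloTree.from_newick(Path(path).read_text(), taxa=taxa)


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# -- supermatrix interchange ----------------------------------------------

def write_phylip_relaxed(sm, path) -> None:
    """Relaxed PHYLIP: 'ntaxa ncols' header, 'name  sequence' rows."""
    if len(sm.taxa) == 0 or sm.n_sites == 0:
        raise FormatError("empty supermatrix")
    lens = {len(row) for row in sm.rows()}
    if len(lens) != 1:
        raise FormatError("ragged matrix")
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_sites}\n")
        for taxon, row in zip(sm.taxa, sm.rows()):
            fh.write(f"{taxon}  {row}\n")


def write_partitions(sm, path) -> None:
    """Partition lines 'name = start-end', 1-based inclusive, tiling 1..L."""
    if not sm.partitions:
        raise FormatError("empty supermatrix")
    with open(path, "w") as fh:
        for gene, start, end in sm.partitions:
            fh.write(f"{gene} = {start + 1}-{end}\n")


def read_phylip_relaxed(path) -> tuple[list[str], list[str]]:
    lines = [l.rstrip("\n") for l in Path(path).read_text().splitlines() if l.strip()]
    n, L = (int(x) for x in lines[0].split())
    taxa, rows = [], []
    for line in lines[1 : 1 + n]:
        name, seq = line.split(None, 1)
        taxa.append(name)
        rows.append(seq.replace(" ", ""))
    if any(len(r) != L for r in rows):
        raise FormatError("sequence length disagrees with header")
    return taxa, rows


# -- manifest --------------------------------------------------------------

def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(outdir, config_dict: dict, seed: int, inputs: Iterable) -> Path:
    """Record config, seed and input digests for a CLI run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config": config_dict,
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).is_file()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
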