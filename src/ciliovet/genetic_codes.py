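"""Genetic codes, ORF recall and translation.

Ciliates are notorious for reassigned stop codons. Mesodinium reads TAA and
TAG through as tyrosine (TGA remains the sole stop), while most other
ciliates use translation table 6 (TAA/TAG as glutamine). Calling ORFs on a
mixed-culture assembly with the wrong code truncates host proteins at the
first in-frame TAA/TAG, so this module recalls ORFs as maximal stop-free
stretches (getorf-style, not ATG-anchored: transcript 5' ends are often
truncated) under a caller-chosen code and quantifies the length gained by
switching codes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable

_BASES = "TCAG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP = "*"
UNKNOWN = "X"


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table plus its stop set."""

    name: str
    codon_to_aa: dict  # codon -> single-letter aa, stops -> "*"
    stops: frozenset

    def __post_init__(self):
        codons = {a + b + c for a in _BASES for b in _BASES for c in _BASES}
        if set(self.codon_to_aa) != codons:
            raise ValueError(f"{self.name}: codon map must cover all 64 codons")
        sense = {c for c, aa in self.codon_to_aa.items() if aa != STOP}
        if self.stops & sense:
            raise ValueError(f"{self.name}: stop set overlaps sense codons")
        if self.stops != set(self.codon_to_aa) - sense:
            raise ValueError(f"{self.name}: stop set inconsistent with codon map")

    def aa(self, codon: str) -> str:
        """Translate one codon; any codon containing N (or other ambiguity) is X."""
        aa = self.codon_to_aa.get(codon)
        return UNKNOWN if aa is None else aa

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def codons_for(self, aa: str) -> tuple:
        """Sense codons encoding an amino acid (used by the back-translator)."""
        return tuple(
            sorted(c for c, a in self.codon_to_aa.items() if a == aa and a != STOP)
        )


def _from_ncbi(table_id: int, name: str) -> GeneticCode:
    t = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(t.forward_table)
    for s in t.stop_codons:
        mapping[s] = STOP
    return GeneticCode(name=name, codon_to_aa=mapping, stops=frozenset(t.stop_codons))


def build_code(name: str) -> GeneticCode:
    """Return one of the three codes the pipeline knows.

    - ``standard``: NCBI table 1 (TAA/TAG/TGA stop).
    - ``table6``: NCBI table 6, the usual ciliate code (TAA/TAG -> Q).
    - ``mesodinium``: TAA/TAG -> Y, TGA remains the only stop.
    """
    if name == "standard":
        return _from_ncbi(1, "standard")
    if name == "table6":
        return _from_ncbi(6, "table6")
    if name == "mesodinium":
        std = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(std.forward_table)
        mapping["TAA"] = "Y"
        mapping["TAG"] = "Y"
        mapping["TGA"] = STOP
        return GeneticCode(
            name="mesodinium", codon_to_aa=mapping, stops=frozenset({"TGA"})
        )
    raise ValueError(f"unknown genetic code {name!r}")


@dataclass(frozen=True)
class ORF:
    """A maximal stop-free codon run on one of the six frames.

    Coordinates are 0-based half-open on the *input* strand orientation of
    that frame: for minus frames they index into the reverse complement.
    """

    contig_id: str
    frame: int  # +1..+3, -1..-3
    start: int
    end: int
    aa_seq: str

    @property
    def nt_len(self) -> int:
        return self.end - self.start


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, code: GeneticCode) -> str:
    """Codon-wise translation; length must be a multiple of 3.

    Stops render as ``*``; codons containing N render as ``X``.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) % 3:
        raise ValueError(f"length {len(nt_seq)} not divisible by 3")
    return "".join(code.aa(nt_seq[i : i + 3]) for i in range(0, len(nt_seq), 3))


def find_orfs(
    nt_seq: str, code: GeneticCode, min_len: int = 150, contig_id: str = ""
) -> list[ORF]:
    """Maximal stop-free codon runs >= min_len nucleotides, all six frames.

    getorf-style (EMBOSS find=0): runs go stop-to-stop, not ATG-to-stop.
    Codons containing N translate to X and never terminate a run. Terminal
    partial codons are discarded.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    nt_seq = nt_seq.upper()
    out: list[ORF] = []
    for strand, seq in ((+1, nt_seq), (-1, reverse_complement(nt_seq))):
        for off in range(3):
            frame = strand * (off + 1)
            run_start = off
            aas: list[str] = []
            for pos in range(off, len(seq) - 2, 3):
                codon = seq[pos : pos + 3]
                if code.is_stop(codon):
                    if len(aas) * 3 >= min_len:
                        out.append(
                            ORF(contig_id, frame, run_start, pos, "".join(aas))
                        )
                    run_start = pos + 3
                    aas = []
                else:
                    aas.append(code.aa(codon))
            if len(aas) * 3 >= min_len:
                out.append(
                    ORF(contig_id, frame, run_start, run_start + 3 * len(aas), "".join(aas))
                )
    return out


def longest_orf_len(nt_seq: str, code: GeneticCode, min_len: int = 3) -> int:
    """Length (aa) of the longest ORF under a code; 0 if none reaches min_len."""
    orfs = find_orfs(nt_seq, code, min_len=min_len)
    return max((len(o.aa_seq) for o in orfs), default=0)


def code_gain(
    nt_seq: str, code_a: GeneticCode, code_b: GeneticCode, min_len: int = 3
) -> int:
    """Longest-ORF aa length under code_b minus under code_a.

    Positive gain flags contigs whose proteins are truncated by the wrong
    stop set; tabulating contigs with gain >= 100 aa reproduces the
    code-comparison ledger.
    """
    return longest_orf_len(nt_seq, code_b, min_len) - longest_orf_len(
        nt_seq, code_a, min_len
    )


def gain_ledger(
    records: Iterable, code_a: GeneticCode, code_b: GeneticCode, min_len: int = 150
) -> list[tuple]:
    """(contig_id, longest_a, longest_b, gain) per input nucleotide record."""
    rows = []
    for rec in records:
        la = longest_orf_len(rec.seq, code_a, min_len)
        lb = longest_orf_len(rec.seq, code_b, min_len)
        rows.append((rec.id, la, lb, lb - la))
    return rows
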