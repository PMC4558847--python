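"""Rectangular gapped alignments and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


class MsaError(ValueError):
    pass


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows per taxon.

    ``source`` tags provenance: ``"true"`` (simulator), ``"builtin"`` (the
    bundled progressive aligner) or ``"external:<tool>"``.
    """

    taxa: list
    rows: list
    source: str = "unknown"

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise MsaError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise MsaError("duplicate taxon names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise MsaError("rows must have equal length")
        for j in range(self.n_columns):
            if all(r[j] == GAP for r in self.rows):
                raise MsaError(f"column {j} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self) -> dict:
        return {t: r.replace(GAP, "") for t, r in zip(self.taxa, self.rows)}

    def subset(self, taxa, source=None) -> "Msa":
        """Rows restricted to ``taxa``; columns that become all-gap removed."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise MsaError(f"unknown taxa: {missing}")
        rows = [self.row(t) for t in taxa]
        keep = [j for j in range(self.n_columns) if any(r[j] != GAP for r in rows)]
        rows = ["".join(r[j] for j in keep) for r in rows]
        return Msa(list(taxa), rows, source or self.source)

    def to_fasta(self) -> str:
        buf = StringIO()
        recs = [
            SeqRecord(Seq(r), id=t, description="")
            for t, r in zip(self.taxa, self.rows)
        ]
        SeqIO.write(recs, buf, "fasta")
        return buf.getvalue()

    @classmethod
    def from_fasta(cls, text: str, source="unknown") -> "Msa":
        recs = list(SeqIO.parse(StringIO(text), "fasta"))
        if not recs:
            raise MsaError("no sequences in FASTA input")
        return cls([r.id for r in recs], [str(r.seq) for r in recs], source)


def write_fasta(sequences: dict) -> str:
    """Unaligned sequences (dict name -> str) as FASTA text."""
    buf = StringIO()
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(recs, buf, "fasta")
    return buf.getvalue()


def read_fasta(text: str) -> dict:
    return {r.id: str(r.seq) for r in SeqIO.parse(StringIO(text), "fasta")}
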