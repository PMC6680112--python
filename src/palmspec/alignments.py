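"""In-frame coding alignment container with FASTA round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import STOP_CODONS


@dataclass
class CodonAlignment:
    """Equal-length, in-frame nucleotide sequences for one gene.

    Internal stop codons do not raise; offending sequences are listed in
    ``flags`` so downstream stages can skip or report them.
    """

    gene_id: str
    sequences: dict[str, str]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths {lengths}")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError(f"{self.gene_id}: length not a multiple of 3")
        for name, seq in self.sequences.items():
            seq = seq.upper()
            self.sequences[name] = seq
            for i in range(0, len(seq) - 3, 3):
                if seq[i : i + 3] in STOP_CODONS:
                    self.flags.append(f"{name}: internal stop at codon {i // 3}")
                    break

    @property
    def length_codons(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values()))) // 3

    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str, gene_id: str) -> "CodonAlignment":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return cls(gene_id=gene_id, sequences=seqs)
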