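"""Strain-level paralog panels.

A panel holds the per-strain inventory of a tandem gene family: the ordered
paralog sequences (centromere to telomere), the family-shared first-exon
segment used for family-wide quantification, and optional parental/decoy
sequences against which motif specificity is checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import validate_dna


@dataclass(frozen=True)
class Paralog:
    """One family member: id, uppercase DNA sequence, 1-based genomic rank."""

    id: str
    sequence: str
    genomic_rank: int

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        validate_dna(self.sequence, f"paralog {self.id}")


@dataclass
class ParalogPanel:
    """All paralogs of one strain plus the shared and parental sequences.

    Parameters
    ----------
    strain
        Strain identifier.
    paralogs
        Ordered list of :class:`Paralog`; genomic ranks must form a
        permutation of 1..n (array order from centromere to telomere).
    family_shared_segment
        Sequence segment identical across every paralog of the family and
        absent from parental genes (the first-exon analog); used to design
        the family-wide "ALL" motif.
    parental_sequences
        Optional mapping of name -> sequence for parental/decoy genes that
        diagnostic motifs must not match.
    promoter_type
        Optional mapping paralog id -> small integer promoter class.
    """

    strain: str
    paralogs: list[Paralog]
    family_shared_segment: str = ""
    parental_sequences: dict[str, str] = field(default_factory=dict)
    promoter_type: Optional[dict[str, int]] = None

    def __post_init__(self):
        ids = [p.id for p in self.paralogs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate paralog ids in strain {self.strain}")
        ranks = sorted(p.genomic_rank for p in self.paralogs)
        if ranks != list(range(1, len(self.paralogs) + 1)):
            raise ValueError(
                f"genomic ranks must be a permutation of 1..{len(self.paralogs)}"
            )
        self.family_shared_segment = self.family_shared_segment.upper()
        validate_dna(self.family_shared_segment, "family_shared_segment")
        self.parental_sequences = {
            k: v.upper() for k, v in self.parental_sequences.items()
        }
        for name, seq in self.parental_sequences.items():
            validate_dna(seq, f"parental sequence {name}")

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.paralogs]

    def sequence_of(self, paralog_id: str) -> str:
        for p in self.paralogs:
            if p.id == paralog_id:
                return p.sequence
        raise KeyError(paralog_id)

    def to_fasta(self, path) -> None:
        """Write paralogs (and shared/parental sequences) as FASTA."""
        records = [
            SeqRecord(Seq(p.sequence), id=p.id,
                      description=f"strain={self.strain} rank={p.genomic_rank}")
            for p in self.paralogs
        ]
        if self.family_shared_segment:
            records.append(SeqRecord(Seq(self.family_shared_segment),
                                     id="__shared__", description=""))
        for name, seq in self.parental_sequences.items():
            records.append(SeqRecord(Seq(seq), id=f"__parental__{name}",
                                     description=""))
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, strain: Optional[str] = None) -> "ParalogPanel":
        """Read a panel written by :meth:`to_fasta` (or any FASTA whose
        records are paralogs in genomic order; `__shared__`/`__parental__*`
        ids are recognised as the shared segment and parental sequences)."""
        paralogs: list[Paralog] = []
        shared = ""
        parental: dict[str, str] = {}
        rank = 0
        inferred_strain = strain
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if rec.id == "__shared__":
                shared = seq
            elif rec.id.startswith("__parental__"):
                parental[rec.id[len("__parental__"):]] = seq
            else:
                rank += 1
                paralogs.append(Paralog(rec.id, seq, rank))
                if inferred_strain is None and "strain=" in rec.description:
                    inferred_strain = rec.description.split("strain=")[1].split()[0]
        return cls(strain=inferred_strain or Path(str(path)).stem,
                   paralogs=paralogs, family_shared_segment=shared,
                   parental_sequences=parental)
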