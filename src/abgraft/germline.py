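"""Germline framework library.

The bundled library (``data/germline_library.synthetic.fasta``) provides one
entry per gene named in the humanization study — three human heavy genes
(IGHV4-59, IGHV2-26, IGHV4-4), three human kappa genes (IGKV1-16, IGKV1-39,
IGKV1-6) and the two murine genes of the parental antibody (IGHV2-9,
IGKV9-124).  The sequences are synthetic stand-ins derived from the curated
consensus templates with gene-specific framework variation (including the
V/K 71 and V/F 78 heavy FR3 pair and the S/K 60, G/R 66 light FR3 pair that
the named genes differ by); they are not IMGT database alleles.  Users can
supply their own library FASTA with real allele sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

from .numbering import AntibodySequence


@dataclass(frozen=True)
class GermlineEntry:
    """One V-gene framework donor: gene name, chain class, sequence."""

    gene_name: str
    chain_class: str
    sequence: str
    source_tag: str = ""

    def as_sequence(self) -> AntibodySequence:
        return AntibodySequence(self.gene_name, self.chain_class, self.sequence)


def load_library(path) -> list[GermlineEntry]:
    """Load a germline library FASTA with ``gene|chain_class|source_tag``
    headers; gene names must be unique."""
    entries = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) < 2:
            raise ValueError(
                f"library record {rec.id!r}: header must be gene|chain_class|source_tag"
            )
        gene = fields[0].strip()
        if gene in seen:
            raise ValueError(f"duplicate gene name {gene!r} in library")
        seen.add(gene)
        entries.append(
            GermlineEntry(
                gene_name=gene,
                chain_class=fields[1].strip(),
                sequence=str(rec.seq).upper(),
                source_tag=fields[2].strip() if len(fields) > 2 else "",
            )
        )
    return entries


def load_default_library() -> list[GermlineEntry]:
    """The bundled synthetic stand-in library (see module docstring)."""
    with resources.files("abgraft.data").joinpath(
        "germline_library.synthetic.fasta"
    ).open() as fh:
        return _parse_handle(fh)


def _parse_handle(fh) -> list[GermlineEntry]:
    entries = []
    for rec in SeqIO.parse(fh, "fasta"):
        fields = rec.description.split("|")
        entries.append(
            GermlineEntry(
                gene_name=fields[0].strip(),
                chain_class=fields[1].strip(),
                sequence=str(rec.seq).upper(),
                source_tag=fields[2].strip() if len(fields) > 2 else "",
            )
        )
    return entries
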