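"""File-format plumbing: FASTA, Vienna dot-bracket, TSV and BED.

FASTA goes through Biopython; dot-bracket records are the plain 3-line
Vienna dialect (``>name`` / sequence / structure).  Tabular outputs are
TSV with optional ``#``-prefixed header lines carrying tool version, seed
and config hash, so every table is traceable to the run that produced it.
BED conversion (1-based inclusive -> 0-based half-open) happens only at
the writer boundary.
"""

from __future__ import annotations

import pathlib
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqsites import MiRNA, SeedSite, UTRSequence
from .structure import SecondaryStructure, parse_dotbracket

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mirna_fasta",
    "read_utr_fasta",
    "write_fragments_fasta",
    "read_fragments_fasta",
    "read_vienna",
    "write_vienna",
    "write_tsv",
    "read_tsv",
    "sites_to_frame",
    "write_sites_bed",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a FASTA file as ``(name, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_mirna_fasta(path) -> list[MiRNA]:
    """Mature miRNAs from FASTA (DNA input is normalized to RNA)."""
    return [MiRNA(name, seq) for name, seq in read_fasta(path)]


def read_utr_fasta(path) -> list[tuple[str, str]]:
    """Full-length UTRs as ``(gene, sequence)`` pairs."""
    return read_fasta(path)


def write_fragments_fasta(path, fragments: Iterable[UTRSequence]) -> None:
    """Fragment library FASTA with ``gene|fragment_k|start-end`` headers."""
    records = []
    for f in fragments:
        end = f.parent_offset + len(f) - 1
        records.append((f"{f.gene}|{f.fragment_id}|{f.parent_offset}-{end}",
                        f.sequence))
    write_fasta(path, records)


def read_fragments_fasta(path) -> list[UTRSequence]:
    """Parse a fragment library written by :func:`write_fragments_fasta`.

    Headers without the ``gene|fragment_k|start-end`` shape are treated as
    single whole-UTR fragments.
    """
    out = []
    for name, seq in read_fasta(path):
        parts = name.split("|")
        if len(parts) == 3 and "-" in parts[2]:
            start = int(parts[2].split("-")[0])
            out.append(UTRSequence(parts[0], parts[1], seq, parent_offset=start))
        else:
            out.append(UTRSequence(name, "fragment_1", seq))
    return out


def read_vienna(path) -> list[tuple[str, SecondaryStructure]]:
    """All records of a Vienna dot-bracket file.

    Records are ``>name`` headers followed by a sequence line and a
    structure line; headerless 2-line files yield one unnamed record.
    """
    text = pathlib.Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    records: list[tuple[str, SecondaryStructure]] = []
    block: list[str] = []
    name = ""
    for ln in lines:
        if ln.startswith(">"):
            if block:
                records.append((name, parse_dotbracket("\n".join(block))))
                block = []
            name = ln[1:].strip()
        else:
            block.append(ln)
            if len(block) == 2:
                records.append((name, parse_dotbracket("\n".join(block))))
                block = []
                name = ""
    if block:
        raise ValueError("dangling sequence line without a structure line")
    return records


def write_vienna(path, records: Iterable[tuple[str, SecondaryStructure]]) -> None:
    with open(path, "w") as fh:
        for name, struct in records:
            fh.write(f">{name}\n{struct.sequence}\n{struct.dotbracket}\n")


def write_tsv(path, table: pd.DataFrame,
              header_lines: Optional[Sequence[str]] = None) -> None:
    """TSV with optional ``#`` provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines or ():
            fh.write(line.rstrip("\n") + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sites_to_frame(
    sites_by_fragment: Iterable[tuple[UTRSequence, Sequence[SeedSite]]],
) -> pd.DataFrame:
    """Long site table: gene, fragment, miRNA, type, coordinates, bases."""
    rows = []
    for frag, sites in sites_by_fragment:
        for s in sites:
            rows.append({
                "gene": frag.gene,
                "fragment_id": frag.fragment_id,
                "mirna": s.mirna,
                "site_type": s.site_type,
                "start": s.start,
                "end": s.end,
                "target_seq": s.target_seq,
            })
    return pd.DataFrame(
        rows,
        columns=["gene", "fragment_id", "mirna", "site_type", "start", "end",
                 "target_seq"],
    )


def write_sites_bed(path, site_table: pd.DataFrame) -> None:
    """Sites as BED: 0-based half-open, name = miRNA:site_type.

    The conversion from the package's 1-based inclusive coordinates
    happens here and only here.
    """
    with open(path, "w") as fh:
        for _, row in site_table.iterrows():
            chrom = f"{row['gene']}|{row['fragment_id']}"
            fh.write(
                f"{chrom}\t{row['start'] - 1}\t{row['end']}\t"
                f"{row['mirna']}:{row['site_type']}\n"
            )
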