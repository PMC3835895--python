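"""Plain-text I/O helpers: FASTA and TSV tables used across the pipeline."""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Only the first whitespace-delimited token of each header is kept as
    the identifier; sequences are upper-cased.
    """
    records: Dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0]
            if name in records:
                raise ValueError(f"duplicate FASTA identifier: {name!r}")
            records[name] = seq.upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_tag_table(path: str | os.PathLike) -> Dict[str, int]:
    """Read a two-column (tag, count) TSV; a header line 'tag\\tcount' is skipped."""
    tags: Dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            tag, count = line.split("\t")
            if tag == "tag" and count == "count":
                continue
            tags[tag] = tags.get(tag, 0) + int(count)
    return tags


def write_tag_table(tags: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("tag\tcount\n")
        for tag in sorted(tags):
            handle.write(f"{tag}\t{tags[tag]}\n")


def read_annotation_table(path: str | os.PathLike) -> Dict[str, set]:
    """Read a (gene, term) TSV into {gene: {terms}}."""
    mapping: Dict[str, set] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, term = line.split("\t")
            if gene == "gene" and term == "term":
                continue
            mapping.setdefault(gene, set()).add(term)
    return mapping


def write_annotation_table(mapping: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tterm\n")
        for gene in sorted(mapping):
            for term in sorted(mapping[gene]):
                handle.write(f"{gene}\t{term}\n")
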