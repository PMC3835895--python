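"""Reference tag library: every CATG+17 21-mer in the transcriptome, indexed.

Each CATG occurrence with at least 17 downstream bases yields one
21-nt reference tag. By default only the sense strand is scanned; the
``both`` mode additionally scans the reverse complement. Tags whose
window contains N are skipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Literal, Mapping, NamedTuple, Set, Tuple

from Bio.Seq import reverse_complement

from tagdge.simulate import ANCHOR, TAG_LEN

StrandMode = Literal["sense_only", "both"]


class ReferenceTag(NamedTuple):
    gene_id: str
    site_offset: int  # 0-based position of the C of CATG on the tag's strand
    strand: str  # "sense" | "antisense"
    tag: str


@dataclass
class ReferenceTagIndex:
    """Exact 21-mer lookup table over all reference tags.

    ``exact_map`` maps each tag sequence to the set of
    ``(gene_id, strand, site_offset)`` triples it occurs at;
    ``unquantifiable`` lists genes that produced no tag.
    """

    exact_map: Dict[str, FrozenSet[Tuple[str, str, int]]]
    gene_count: int
    unquantifiable: List[str] = field(default_factory=list)

    @property
    def tag_count(self) -> int:
        return len(self.exact_map)

    def genes_for(self, tag: str) -> Set[str]:
        hits = self.exact_map.get(tag)
        return {g for g, _, _ in hits} if hits else set()

    def write_tsv(self, path: str | os.PathLike) -> None:
        """Serialize as TSV (gene_id, strand, site_offset_1based, tag)."""
        rows = []
        for tag, sites in self.exact_map.items():
            for gene_id, strand, offset in sites:
                rows.append((gene_id, strand, offset + 1, tag))
        rows.sort()
        with open(path, "w") as handle:
            handle.write("gene_id\tstrand\tsite_offset\ttag\n")
            handle.write(f"#genes={self.gene_count}\tunquantifiable={','.join(sorted(self.unquantifiable))}\t-\t-\n")
            for gene_id, strand, offset, tag in rows:
                handle.write(f"{gene_id}\t{strand}\t{offset}\t{tag}\n")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "ReferenceTagIndex":
        exact: Dict[str, Set[Tuple[str, str, int]]] = {}
        gene_count = 0
        unquantifiable: List[str] = []
        genes: Set[str] = set()
        with open(path) as handle:
            header = handle.readline()
            meta = handle.readline().rstrip("\n").split("\t")
            if meta and meta[0].startswith("#genes="):
                gene_count = int(meta[0].split("=", 1)[1])
                unq = meta[1].split("=", 1)[1]
                unquantifiable = [g for g in unq.split(",") if g]
            for line in handle:
                gene_id, strand, offset, tag = line.rstrip("\n").split("\t")
                exact.setdefault(tag, set()).add((gene_id, strand, int(offset) - 1))
                genes.add(gene_id)
        if gene_count == 0:
            gene_count = len(genes) + len(unquantifiable)
        return cls(
            exact_map={t: frozenset(s) for t, s in exact.items()},
            gene_count=gene_count,
            unquantifiable=unquantifiable,
        )


def extract_reference_tags(
    gene_id: str, sequence: str, strand_mode: StrandMode = "sense_only"
) -> List[ReferenceTag]:
    """All CATG+17 tags of one sequence, ordered by position.

    N-containing windows are skipped. Under ``both``, antisense tags are
    reported with offsets on the reverse-complemented sequence.
    """
    if strand_mode not in ("sense_only", "both"):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    sequence = sequence.upper()
    strands = [("sense", sequence)]
    if strand_mode == "both":
        strands.append(("antisense", reverse_complement(sequence)))
    tags: List[ReferenceTag] = []
    for strand, seq in strands:
        pos = seq.find(ANCHOR)
        while pos != -1:
            window = seq[pos : pos + TAG_LEN]
            if len(window) == TAG_LEN and "N" not in window:
                tags.append(ReferenceTag(gene_id, pos, strand, window))
            pos = seq.find(ANCHOR, pos + 1)
    return tags


def build_index(
    unigenes: Mapping[str, str], strand_mode: StrandMode = "sense_only"
) -> ReferenceTagIndex:
    """Index all reference tags of a unigene set for exact lookup."""
    if len(set(unigenes)) != len(unigenes):
        raise ValueError("duplicate gene identifiers")
    exact: Dict[str, Set[Tuple[str, str, int]]] = {}
    unquantifiable: List[str] = []
    for gene_id, seq in unigenes.items():
        gene_tags = extract_reference_tags(gene_id, seq, strand_mode)
        if not gene_tags:
            unquantifiable.append(gene_id)
            continue
        for t in gene_tags:
            exact.setdefault(t.tag, set()).add((t.gene_id, t.strand, t.site_offset))
    return ReferenceTagIndex(
        exact_map={t: frozenset(s) for t, s in exact.items()},
        gene_count=len(unigenes),
        unquantifiable=unquantifiable,
    )
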