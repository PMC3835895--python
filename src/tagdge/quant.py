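"""Tag library cleaning, mismatch-tolerant mapping, and TPM normalization.

Cleaning removes adapter-only reads, N-containing tag species and
singleton species. Mapping assigns each clean 21-mer species to genes by
exact lookup first, falling back to the full Hamming-distance-1
neighborhood (3 x 21 substitutions); a species whose candidate gene set
has exactly one member is unambiguous and its whole count accrues to
that gene, otherwise it is ambiguous (>1 gene) or unmapped (no match).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Set

import pandas as pd

from tagdge.reference import ReferenceTagIndex
from tagdge.simulate import ADAPTER_SENTINEL, TAG_LEN


@dataclass
class TagLibrary:
    """A tag library: mapping from tag sequence to read count."""

    name: str
    tags: Dict[str, int]
    total_raw: int
    total_clean: Optional[int] = None
    true_counts: Optional[pd.Series] = None  # simulator ground truth, if any

    def total(self) -> int:
        return sum(self.tags.values())


@dataclass
class ExpressionTable:
    """Per-gene unambiguous counts and TPM for one library."""

    library: str
    counts: Dict[str, int]
    tpm: Dict[str, float] = field(default_factory=dict)
    totals: Dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.counts)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "raw_count": [self.counts[g] for g in genes],
                "tpm": [self.tpm.get(g, float("nan")) for g in genes],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def clean_tags(raw: TagLibrary, adapter_sentinel: str = ADAPTER_SENTINEL) -> TagLibrary:
    """Apply the cleaning rules: drop adapter/empty reads, N species, singletons.

    Species-level rules: a tag species containing ``N`` is discarded
    regardless of count; a species whose total copy number is exactly 1
    is discarded as a likely sequencing error.
    """
    clean: Dict[str, int] = {}
    for tag, count in raw.tags.items():
        if not tag or tag == adapter_sentinel:
            continue
        if "N" in tag:
            continue
        if count == 1:
            continue
        clean[tag] = count
    total_clean = sum(clean.values())
    return TagLibrary(
        name=raw.name,
        tags=clean,
        total_raw=raw.total_raw,
        total_clean=total_clean,
        true_counts=raw.true_counts,
    )


_ALPHABET = "ACGT"


def _neighborhood(tag: str):
    """Yield all 3*len(tag) sequences at Hamming distance exactly 1."""
    for i, base in enumerate(tag):
        for sub in _ALPHABET:
            if sub != base:
                yield tag[:i] + sub + tag[i + 1 :]


def map_tags(clean: TagLibrary, index: ReferenceTagIndex) -> ExpressionTable:
    """Map clean tags to the reference with at most one mismatch.

    Exact matches take precedence: a species' candidate set is its exact
    match set when non-empty, else the union of genes over its
    distance-1 neighborhood. Counts are assigned atomically per species.
    """
    if index.tag_count == 0:
        raise ValueError("reference index is empty")
    counts: Dict[str, int] = {}
    n_unambiguous = 0
    n_ambiguous = 0
    n_unmapped = 0
    n_invalid = 0
    for tag, count in clean.tags.items():
        if len(tag) != TAG_LEN:
            n_invalid += count
            continue
        genes: Set[str] = index.genes_for(tag)
        if not genes:
            for neighbor in _neighborhood(tag):
                genes |= index.genes_for(neighbor)
        if not genes:
            n_unmapped += count
        elif len(genes) == 1:
            gene = next(iter(genes))
            counts[gene] = counts.get(gene, 0) + count
            n_unambiguous += count
        else:
            n_ambiguous += count
    totals = {
        "clean": clean.total_clean if clean.total_clean is not None else clean.total(),
        "mapped": n_unambiguous + n_ambiguous,
        "unambiguous": n_unambiguous,
        "ambiguous": n_ambiguous,
        "unmapped": n_unmapped,
        "length_invalid": n_invalid,
    }
    return ExpressionTable(library=clean.name, counts=counts, totals=totals)


def tpm_normalize(
    table: ExpressionTable, denominator: Literal["clean", "unambiguous"] = "clean"
) -> ExpressionTable:
    """Scale unambiguous counts to tags-per-million of the chosen denominator."""
    if denominator not in ("clean", "unambiguous"):
        raise ValueError(f"unknown denominator: {denominator!r}")
    total = table.totals.get(denominator, 0)
    if total <= 0:
        raise ValueError(f"denominator total {denominator!r} is zero")
    table.tpm = {g: c / total * 1e6 for g, c in table.counts.items()}
    table.totals["tpm_denominator"] = total
    return table
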