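"""Gene-family candidate curation: length filter, six-frame ORF filter,
and allelic-variant collapse by local-alignment identity.

Filters are applied in order — length first, then longest ORF — and the
survivors are single-linkage clustered: any pair aligning at
>= ``min_identity`` over >= ``min_coverage`` of the shorter sequence is
treated as allelic variants (or fragments) of one gene, and only the
longest member of each cluster is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, NamedTuple, Optional, Tuple

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


class OrfCall(NamedTuple):
    frame: int  # +1, +2, +3, -1, -2, -3
    start: int  # 0-based half-open, on the frame's strand
    end: int
    aa_length: int  # amino acids excluding the stop


@dataclass
class CurationRecord:
    gene_id: str
    length_bp: int
    longest_orf_aa: int
    disposition: str  # kept | removed_short | removed_short_orf | removed_variant
    cluster_id: Optional[str] = None


def _scan_frame(seq: str, offset: int) -> Tuple[int, int, int]:
    """Longest ATG-initiated ORF in one frame: (aa_length, start, end).

    An ORF runs from an ATG to the next in-frame stop (excluded from the
    aa count) or, failing that, to the last complete codon (open 3' end,
    all codons counted). Returns (0, 0, 0) when the frame has no ATG.
    """
    best = (0, 0, 0)
    start: Optional[int] = None
    i = offset
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                aa = (i - start) // 3
                if aa > best[0]:
                    best = (aa, start, i + 3)
                start = None
        elif codon == START_CODON and start is None:
            start = i
        i += 3
    if start is not None:  # ran off the end without a stop
        end = start + ((i - start) // 3) * 3
        aa = (end - start) // 3
        if aa > best[0]:
            best = (aa, start, end)
    return best


def longest_orf(sequence: str) -> OrfCall:
    """Longest ATG-to-stop ORF over all six frames (standard code).

    Ties break by frame order (+1, +2, +3, -1, -2, -3), then leftmost
    start. Coordinates refer to the frame's own strand. ``aa_length`` is
    0 when no ATG-initiated ORF exists.
    """
    sequence = sequence.upper()
    rc = reverse_complement(sequence)
    best = OrfCall(frame=1, start=0, end=0, aa_length=0)
    for rank, (frame, seq) in enumerate(
        [(1, sequence), (2, sequence), (3, sequence), (-1, rc), (-2, rc), (-3, rc)]
    ):
        offset = abs(frame) - 1
        aa, start, end = _scan_frame(seq, offset)
        if aa > best.aa_length:
            best = OrfCall(frame=frame, start=start, end=end, aa_length=aa)
    return best


def filter_family_candidates(
    unigenes: Mapping[str, str], min_len: int = 400, min_orf_aa: int = 100
) -> List[CurationRecord]:
    """Assign each gene a disposition by the length and ORF filters.

    The length filter is applied before the ORF filter; genes passing
    both are marked ``kept`` (variant collapse happens separately).
    """
    records = []
    for gene_id in sorted(unigenes):
        seq = unigenes[gene_id]
        orf = longest_orf(seq)
        if len(seq) < min_len:
            disposition = "removed_short"
        elif orf.aa_length < min_orf_aa:
            disposition = "removed_short_orf"
        else:
            disposition = "kept"
        records.append(CurationRecord(gene_id, len(seq), orf.aa_length, disposition))
    return records


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def alignment_identity(seq_a: str, seq_b: str, aligner: Optional[PairwiseAligner] = None) -> Tuple[float, float]:
    """(identity, coverage) of the best local alignment of two sequences.

    Identity is matching columns over aligned columns (gaps included);
    coverage is the aligned span of the shorter sequence over its length.
    """
    if aligner is None:
        aligner = _make_aligner()
    if not seq_a or not seq_b:
        return 0.0, 0.0
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    gaps, identities, mismatches = counts.gaps, counts.identities, counts.mismatches
    columns = gaps + identities + mismatches
    if columns == 0:
        return 0.0, 0.0
    identity = identities / columns
    blocks_a, blocks_b = alignment.aligned
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    short_len = min(len(seq_a), len(seq_b))
    span_short = span_a if len(seq_a) <= len(seq_b) else span_b
    return identity, span_short / short_len


def cluster_allelic_variants(
    kept: Mapping[str, str], min_identity: float = 0.95, min_coverage: float = 0.8
) -> Tuple[Dict[str, List[str]], Dict[str, str]]:
    """Single-linkage clusters of near-identical sequences, with representatives.

    Returns ``(clusters, representative_of)`` where clusters maps a
    cluster id (its representative's gene id) to its sorted members, and
    ``representative_of`` maps each gene to its cluster's representative
    (the longest member; ties broken by lexicographic id). Results are
    independent of input order.
    """
    genes = sorted(kept)
    parent = {g: g for g in genes}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    aligner = _make_aligner()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            identity, coverage = alignment_identity(kept[a], kept[b], aligner)
            if identity >= min_identity and coverage >= min_coverage:
                union(a, b)

    members: Dict[str, List[str]] = {}
    for g in genes:
        members.setdefault(find(g), []).append(g)
    clusters: Dict[str, List[str]] = {}
    representative_of: Dict[str, str] = {}
    for group in members.values():
        rep = min(group, key=lambda g: (-len(kept[g]), g))
        clusters[rep] = sorted(group)
        for g in group:
            representative_of[g] = rep
    return clusters, representative_of


def curate(
    unigenes: Mapping[str, str],
    min_len: int = 400,
    min_orf_aa: int = 100,
    min_identity: float = 0.95,
    min_coverage: float = 0.8,
) -> List[CurationRecord]:
    """Run both filters then variant collapse; every gene gets one disposition."""
    records = filter_family_candidates(unigenes, min_len=min_len, min_orf_aa=min_orf_aa)
    kept = {r.gene_id: unigenes[r.gene_id] for r in records if r.disposition == "kept"}
    clusters, rep_of = cluster_allelic_variants(
        kept, min_identity=min_identity, min_coverage=min_coverage
    )
    for record in records:
        if record.disposition != "kept":
            continue
        rep = rep_of[record.gene_id]
        record.cluster_id = rep
        if record.gene_id != rep:
            record.disposition = "removed_variant"
    return records
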