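"""Synthetic transcriptomes, tag libraries, annotations and curation fixtures.

Everything downstream of sequencing is testable against the ground truth
produced here: unigene sets with controlled CATG-site content, 21-bp tag
libraries (CATG + 17 bases) drawn multinomially from per-gene abundances
with spiked fold changes, per-base substitution errors, contaminant
reads, and gene-to-term annotations with one deliberately enriched term.

All randomness flows from a single explicit seed through one
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

TAG_LEN = 21
ANCHOR = "CATG"
#: Sentinel emitted for adapter-only reads (an adapter fragment, no CATG anchor).
ADAPTER_SENTINEL = "TCGGACTGTAGAACTCTGAAC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic transcriptome and tag libraries.

    ``catg_free_fraction`` of genes carry no sense-strand CATG and are
    therefore unobservable by the assay; every other gene carries at
    least one CATG with >= 17 downstream bases.
    """

    n_genes: int = 2000
    length_range: Tuple[int, int] = (300, 1500)
    catg_free_fraction: float = 0.0
    library_size: int = 1_000_000
    error_rate: float = 0.0
    n_contaminant_reads: int = 0
    seed: int = 0
    n_up_spiked: int = 0
    n_down_spiked: int = 0
    spike_fold: float = 8.0
    abundance_sigma: float = 1.0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, hi = self.length_range
        if lo < TAG_LEN + 4 or hi < lo:
            raise ValueError(
                f"length_range must satisfy {TAG_LEN + 4} <= min <= max, got {self.length_range}"
            )
        if not 0.0 <= self.catg_free_fraction <= 1.0:
            raise ValueError("catg_free_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_contaminant_reads < 0:
            raise ValueError("n_contaminant_reads must be non-negative")
        if self.spike_fold <= 0:
            raise ValueError("spike_fold must be positive")
        if self.n_up_spiked + self.n_down_spiked > self.n_genes:
            raise ValueError("more spiked genes than genes")


def _random_catg_free(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform random sequence (as base indices) containing no CATG."""
    seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    # Resample any CATG occurrence until none remain; each fix is local so
    # this converges in a handful of rounds.
    pattern = np.array([_BASE_INDEX[c] for c in ANCHOR], dtype=np.uint8)
    while True:
        hits = _find_pattern(seq, pattern)
        if hits.size == 0:
            return seq
        for pos in hits:
            seq[pos] = (seq[pos] + rng.integers(1, 4)) % 4


def _find_pattern(seq: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    if seq.size < pattern.size:
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(seq, pattern.size)
    return np.nonzero((windows == pattern).all(axis=1))[0]


def _indices_to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def generate_unigenes(config: SimulationConfig) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Generate a synthetic unigene set and its truth table.

    Returns ``(unigenes, truth)`` where ``unigenes`` maps gene id to
    sequence and ``truth`` is a DataFrame indexed by gene id with columns
    ``baseline_abundance``, ``fold_change``, ``de_label``, ``catg_free``
    and ``true_tag`` (the 3'-most extractable CATG+17 tag, empty for
    CATG-free genes). Identical seeds reproduce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_free = int(round(config.n_genes * config.catg_free_fraction))
    lo, hi = config.length_range
    pattern = np.array([_BASE_INDEX[c] for c in ANCHOR], dtype=np.uint8)

    width = len(str(config.n_genes))
    names = [f"gene{str(i + 1).zfill(width)}" for i in range(config.n_genes)]
    free_ids = set(rng.choice(config.n_genes, size=n_free, replace=False).tolist())

    unigenes: Dict[str, str] = {}
    true_tags: List[str] = []
    for i, name in enumerate(names):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_catg_free(rng, length)
        if i in free_ids:
            unigenes[name] = _indices_to_str(seq)
            true_tags.append("")
            continue
        # Plant one CATG with >= 17 downstream bases; planting may create
        # overlapping anchors, so the true tag is re-derived by scanning.
        pos = int(rng.integers(0, length - TAG_LEN + 1))
        seq[pos : pos + 4] = pattern
        sites = _find_pattern(seq, pattern)
        sites = sites[sites + TAG_LEN <= length]
        site = int(sites[-1])  # 3'-most extractable site: what the assay captures
        unigenes[name] = _indices_to_str(seq)
        true_tags.append(unigenes[name][site : site + TAG_LEN])

    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_genes)
    truth = pd.DataFrame(
        {
            "baseline_abundance": abundance,
            "fold_change": np.ones(config.n_genes),
            "de_label": ["null"] * config.n_genes,
            "catg_free": [i in free_ids for i in range(config.n_genes)],
            "true_tag": true_tags,
        },
        index=pd.Index(names, name="gene_id"),
    )
    if config.n_up_spiked or config.n_down_spiked:
        truth = spike_truth(
            truth,
            n_up=config.n_up_spiked,
            n_down=config.n_down_spiked,
            fold=config.spike_fold,
            seed=int(rng.integers(0, 2**31)),
        )
    return unigenes, truth


def spike_truth(
    truth: pd.DataFrame, n_up: int, n_down: int, fold: float, seed: int
) -> pd.DataFrame:
    """Assign fold changes to a random subset of observable genes.

    ``n_up`` genes get ``fold_change = fold`` (label ``up``) and
    ``n_down`` get ``1/fold`` (label ``down``); the rest stay ``null``
    with fold 1. Only genes with an extractable tag are eligible, so
    spiked truth is recoverable in principle.
    """
    if fold <= 1:
        raise ValueError("spike fold must exceed 1")
    rng = np.random.default_rng(seed)
    eligible = np.nonzero(~truth["catg_free"].to_numpy())[0]
    if n_up + n_down > eligible.size:
        raise ValueError("not enough observable genes to spike")
    chosen = rng.choice(eligible, size=n_up + n_down, replace=False)
    out = truth.copy()
    fold_col = out["fold_change"].to_numpy(dtype=float, copy=True)
    label_col = out["de_label"].to_numpy(copy=True)
    fold_col[chosen[:n_up]] = fold
    label_col[chosen[:n_up]] = "up"
    fold_col[chosen[n_up:]] = 1.0 / fold
    label_col[chosen[n_up:]] = "down"
    out["fold_change"] = fold_col
    out["de_label"] = label_col
    return out


def _mutate_reads(tag_matrix: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply independent per-base substitutions to an (n_reads, 21) index matrix."""
    if error_rate == 0.0 or tag_matrix.size == 0:
        return tag_matrix
    out = tag_matrix.copy()
    chunk = 200_000  # bound the temporary float mask at ~35 MB
    for start in range(0, out.shape[0], chunk):
        block = out[start : start + chunk]
        mask = rng.random(block.shape) < error_rate
        n_mut = int(mask.sum())
        if n_mut:
            shifts = rng.integers(1, 4, size=n_mut, dtype=np.uint8)
            block[mask] = (block[mask] + shifts) % 4
    return out


def simulate_tag_library(
    unigenes: Dict[str, str],
    truth: pd.DataFrame,
    treated: bool,
    config: SimulationConfig,
    name: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> "TagLibrary":
    """Draw a tag library of ``library_size`` informative reads plus contaminants.

    Reads are drawn multinomially over genes with weight
    ``baseline_abundance * (fold_change if treated else 1)``; CATG-free
    genes have zero weight. Each read is the gene's 3'-most CATG+17 tag
    with independent per-base substitutions at ``error_rate``.
    Contaminants are split evenly between adapter-only sentinel reads and
    single-N reads. The returned library records the per-gene multinomial
    draw in ``true_counts`` for downstream ground-truth checks.
    """
    from tagdge.quant import TagLibrary  # local import avoids a cycle

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + (1 if treated else 2))
    weights = truth["baseline_abundance"].to_numpy(dtype=float).copy()
    if treated:
        weights = weights * truth["fold_change"].to_numpy(dtype=float)
    weights[truth["catg_free"].to_numpy()] = 0.0
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero; nothing to simulate")

    counts = rng.multinomial(config.library_size, weights / total)
    tag_strings = truth["true_tag"].to_numpy()
    observed = np.nonzero(counts)[0]
    tag_rows = np.empty((observed.size, TAG_LEN), dtype=np.uint8)
    for row, gi in enumerate(observed):
        tag_rows[row] = np.frombuffer(tag_strings[gi].encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    tag_rows = lut[tag_rows]

    reads = np.repeat(np.arange(observed.size), counts[observed])
    read_matrix = _mutate_reads(tag_rows[reads], config.error_rate, rng)

    tags: Dict[str, int] = {}
    if read_matrix.size:
        ascii_rows = np.ascontiguousarray(_BASES[read_matrix])
        uniq, uniq_counts = np.unique(ascii_rows.view(f"S{TAG_LEN}").ravel(), return_counts=True)
        for tag_bytes, c in zip(uniq, uniq_counts):
            tags[tag_bytes.decode("ascii")] = int(c)

    # Contaminants: half adapter-only sentinel reads, half single-N reads
    # built from real tags so each cleaning rule fires separately.
    n_adapter = config.n_contaminant_reads // 2
    n_nreads = config.n_contaminant_reads - n_adapter
    if n_adapter:
        tags[ADAPTER_SENTINEL] = tags.get(ADAPTER_SENTINEL, 0) + n_adapter
    for _ in range(n_nreads):
        if observed.size:
            base_tag = tag_strings[int(rng.choice(observed))]
        else:
            base_tag = ANCHOR + "A" * 17
        pos = int(rng.integers(0, TAG_LEN))
        n_tag = base_tag[:pos] + "N" + base_tag[pos + 1 :]
        tags[n_tag] = tags.get(n_tag, 0) + 1

    lib_name = name or ("treated" if treated else "control")
    true_counts = pd.Series(counts, index=truth.index, name="true_count")
    return TagLibrary(
        name=lib_name,
        tags=tags,
        total_raw=config.library_size + config.n_contaminant_reads,
        true_counts=true_counts,
    )


ENRICHED_TERM = "TERM_ENRICHED"


def generate_annotations(
    truth: pd.DataFrame,
    n_terms: int,
    enriched_rate: float,
    background_rate: float,
    seed: int,
) -> Dict[str, set]:
    """Attach annotation terms to genes with one term enriched in true-DE genes.

    The designated term ``TERM_ENRICHED`` annotates true-DE genes
    (``de_label != null``) with probability ``enriched_rate`` and null
    genes with ``background_rate``; the remaining ``n_terms - 1`` terms
    annotate every gene independently at ``background_rate``.
    """
    if not (0.0 <= enriched_rate <= 1.0 and 0.0 <= background_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    genes = truth.index.to_numpy()
    is_de = (truth["de_label"] != "null").to_numpy()

    mapping: Dict[str, set] = {g: set() for g in genes}
    p_enriched = np.where(is_de, enriched_rate, background_rate)
    hit = rng.random(genes.size) < p_enriched
    for g in genes[hit]:
        mapping[g].add(ENRICHED_TERM)
    width = len(str(max(n_terms - 1, 1)))
    for t in range(1, n_terms):
        term = f"TERM_{str(t).zfill(width)}"
        hit = rng.random(genes.size) < background_rate
        for g in genes[hit]:
            mapping[g].add(term)
    return {g: ts for g, ts in mapping.items() if ts}


def generate_family_fixtures(seed: int = 0) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Constructed unigenes exercising every curation-filter branch.

    Returns ``(unigenes, expected_disposition)``. The set contains a
    350-bp sequence (``too_short``), a long sequence whose longest
    six-frame ORF is 80 aa (``short_orf``), a clean 300-aa-ORF member
    (``valid``), and a 99%-identical variant pair in which the longer
    member is expected to be kept as representative.
    """
    rng = np.random.default_rng(seed)

    def random_seq(n: int) -> str:
        return _indices_to_str(_random_catg_free(rng, n))

    def strip_orfs(seq: str) -> str:
        # Remove every ATG (either strand: ATG sense, CAT antisense) so no
        # unintended ORF competes with the constructed one. "A" only would
        # bias composition; rewrite the T of each ATG/CAT instead.
        s = list(seq)
        changed = True
        while changed:
            changed = False
            text = "".join(s)
            for motif in ("ATG", "CAT"):
                pos = text.find(motif)
                if pos != -1:
                    t_at = pos + motif.index("T")
                    s[t_at] = "G" if motif == "ATG" else "C"
                    changed = True
                    break
        return "".join(s)

    def orf_of(n_aa: int) -> str:
        # ATG + (n_aa - 1) codons + stop; codons free of A/T avoid nested ATGs
        codons = ["GGC", "GCC", "CGG", "GGG", "CCG", "CCC"]
        body = "".join(codons[int(rng.integers(0, len(codons)))] for _ in range(n_aa - 1))
        return "ATG" + body + "TAA"

    too_short = strip_orfs(random_seq(350))
    short_orf = strip_orfs(random_seq(400)) + orf_of(80) + strip_orfs(random_seq(260))
    valid = strip_orfs(random_seq(50)) + orf_of(300) + strip_orfs(random_seq(50))

    variant_a = strip_orfs(random_seq(60)) + orf_of(250) + strip_orfs(random_seq(40))
    # 99%-identical shorter variant: truncate 5' end, substitute ~1% of bases
    variant_b = list(variant_a[30:])
    n_sub = max(1, int(0.01 * len(variant_b)))
    # Substitute inside the ORF body but never touch ATG/stop codon positions
    orf_start = variant_a.find("ATG" ) - 30
    sub_positions = rng.choice(
        np.arange(orf_start + 3, orf_start + 3 + 240), size=n_sub, replace=False
    )
    for pos in sub_positions:
        codon_off = (pos - orf_start) % 3
        if codon_off == 2:  # wobble position: safe synonymous-ish change
            pass
        variant_b[pos] = {"A": "C", "C": "G", "G": "C", "T": "C"}[variant_b[pos]]
    variant_b = "".join(variant_b)

    unigenes = {
        "fix_too_short": too_short,
        "fix_short_orf": short_orf,
        "fix_valid": valid,
        "fix_variant_long": variant_a,
        "fix_variant_short": variant_b,
    }
    expected = {
        "fix_too_short": "removed_short",
        "fix_short_orf": "removed_short_orf",
        "fix_valid": "kept",
        "fix_variant_long": "kept",
        "fix_variant_short": "removed_variant",
    }
    return unigenes, expected
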