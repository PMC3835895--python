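"""Two-library differential expression for tag counts.

The per-gene test conditions on the count ``x`` observed in library 1
(total ``N1``) and asks whether the count ``y`` in library 2 (total
``N2``) is consistent with equal underlying rates:

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

The two-sided p-value doubles the smaller of the two tail sums
P(Y <= y | x) and P(Y >= y | x), capped at 1. Tails are summed exactly
in log space (log-gamma terms, no normal approximation), which is
overflow-free for library totals up to 1e7.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from tagdge.quant import ExpressionTable

__all__ = [
    "audic_claverie_tails",
    "audic_claverie_p",
    "log2_tpm_ratio",
    "bh_fdr",
    "call_degs",
    "common_degs",
    "compare_libraries",
]


def _log_pmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        k * log_r
        + gammaln(x + k + 1.0)
        - gammaln(k + 1.0)
        - gammaln(x + 1.0)
        - (x + k + 1.0) * log_1pr
    )


def audic_claverie_tails(x: int, y: int, N1: int, N2: int) -> Tuple[float, float]:
    """Exact tail probabilities (P(Y <= y | x), P(Y >= y | x)), both inclusive.

    Each tail is an exact sum of the conditional pmf; the upper tail is
    summed outward from ``y`` until a geometric-series bound certifies
    convergence, so small tails keep full relative precision.
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0 or x > N1 or y > N2:
        raise ValueError("counts must satisfy 0 <= x <= N1 and 0 <= y <= N2")
    log_r = math.log(N2) - math.log(N1)
    log_1pr = math.log1p(N2 / N1)

    lower = logsumexp(_log_pmf(np.arange(y + 1, dtype=float), x, log_r, log_1pr))

    # Upper tail: chunked summation from y upward. The pmf term ratio
    # p(k+1)/p(k) = r*(x+k+1) / ((k+1)*(1+r)) tends to r/(1+r) < 1, so a
    # geometric bound on the remainder eventually applies.
    chunk = max(1024, 4 * (x + 1))
    pieces = []
    k0 = y
    r_over_1pr = log_r - log_1pr
    while True:
        ks = np.arange(k0, k0 + chunk, dtype=float)
        logs = _log_pmf(ks, x, log_r, log_1pr)
        pieces.append(logsumexp(logs))
        k_last = k0 + chunk - 1
        log_q = r_over_1pr + math.log(x + k_last + 2) - math.log(k_last + 2)
        if log_q < 0:
            # remainder <= term(k_last+1) * q/(1-q) <= term(k_last) * q^2/(1-q)
            log_rem = logs[-1] + 2 * log_q - math.log1p(-math.exp(log_q))
            if log_rem < logsumexp(pieces) - 45.0:
                break
        k0 += chunk
    upper = logsumexp(pieces)
    return math.exp(min(lower, 0.0)), math.exp(min(upper, 0.0))


def audic_claverie_p(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided p-value: the doubled smaller tail, capped at 1.

    Note both tails include the observed ``y``, so the result is not
    exactly symmetric under swapping (x, y) even for N1 == N2; the tails
    themselves satisfy P(Y >= y+1 | x) == P(Y <= x | y) exactly.
    """
    lower, upper = audic_claverie_tails(x, y, N1, N2)
    p = 2.0 * min(lower, upper)
    return max(min(p, 1.0), 5e-324)


def log2_tpm_ratio(tpm_treat: float, tpm_ctrl: float, zero_floor: float) -> float:
    """log2 of treatment over control on the TPM scale, with a zero floor.

    Zero values are replaced by ``zero_floor`` (typically the TPM of a
    single tag in the smaller library) so ratios stay finite.
    """
    if tpm_treat < 0 or tpm_ctrl < 0:
        raise ValueError("TPM values must be non-negative")
    if zero_floor <= 0:
        raise ValueError("zero_floor must be positive")
    return math.log2(max(tpm_treat, zero_floor) / max(tpm_ctrl, zero_floor))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def call_degs(
    results: pd.DataFrame, fdr_max: float = 0.001, min_abs_log2: float = 1.0
) -> pd.DataFrame:
    """Label genes up/down/ns by the joint FDR and fold-change thresholds."""
    fdr = results["fdr"].to_numpy()
    lr = results["log2ratio"].to_numpy()
    call = np.where(
        (fdr <= fdr_max) & (lr >= min_abs_log2),
        "up",
        np.where((fdr <= fdr_max) & (lr <= -min_abs_log2), "down", "ns"),
    )
    out = results.copy()
    out["call"] = call
    return out


def compare_libraries(
    control: ExpressionTable,
    treated: ExpressionTable,
    gene_universe: Optional[Sequence[str]] = None,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    zero_floor: Optional[float] = None,
    total_key: str = "clean",
) -> pd.DataFrame:
    """Full two-library comparison: test, BH adjust, call DEGs.

    ``gene_universe`` defaults to the union of genes detected in either
    library. ``total_key`` selects which library total serves as N
    (``clean`` matches the stated mapping universe; ``unambiguous`` is
    the alternative). ``zero_floor`` defaults to the TPM of one tag in
    the smaller library.
    """
    N1 = control.totals.get(total_key)
    N2 = treated.totals.get(total_key)
    if not N1 or not N2:
        raise ValueError(f"missing {total_key!r} totals on the expression tables")
    if gene_universe is None:
        gene_universe = sorted(set(control.counts) | set(treated.counts))
    if zero_floor is None:
        zero_floor = 1e6 / min(N1, N2)

    denom1 = control.totals.get("tpm_denominator", N1)
    denom2 = treated.totals.get("tpm_denominator", N2)
    rows = []
    for gene in gene_universe:
        x = control.counts.get(gene, 0)
        y = treated.counts.get(gene, 0)
        tpm_c = control.tpm.get(gene, x / denom1 * 1e6)
        tpm_t = treated.tpm.get(gene, y / denom2 * 1e6)
        rows.append(
            (
                gene,
                x,
                y,
                tpm_c,
                tpm_t,
                log2_tpm_ratio(tpm_t, tpm_c, zero_floor),
                audic_claverie_p(x, y, N1, N2),
            )
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "x", "y", "tpm_ctrl", "tpm_treat", "log2ratio", "p_value"]
    )
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return call_degs(df, fdr_max=fdr_max, min_abs_log2=min_abs_log2)


def common_degs(
    comparison_a: pd.DataFrame, comparison_b: pd.DataFrame
) -> Dict[str, Set[str]]:
    """Genes called the same direction in both comparisons.

    Both inputs must cover the same gene universe; genes with opposite
    calls appear in neither output set.
    """
    genes_a = set(comparison_a["gene_id"])
    genes_b = set(comparison_b["gene_id"])
    if genes_a != genes_b:
        raise ValueError("comparisons cover different gene universes")
    call_a = dict(zip(comparison_a["gene_id"], comparison_a["call"]))
    call_b = dict(zip(comparison_b["gene_id"], comparison_b["call"]))
    return {
        "common_up": {g for g in genes_a if call_a[g] == "up" and call_b[g] == "up"},
        "common_down": {g for g in genes_a if call_a[g] == "down" and call_b[g] == "down"},
    }
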