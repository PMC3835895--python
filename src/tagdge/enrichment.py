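"""Hypergeometric term enrichment of a DEG set against an annotated background.

For each term, with N annotated genes overall, n DEGs among them, M
genes carrying the term and m DEGs carrying it, the enrichment p-value
is the upper hypergeometric tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n) = P(X >= m),

computed with exact log-space combinatorics. GO-style analyses use a
corrected P <= 0.05 (Bonferroni by default); KEGG-style analyses use
BH-adjusted Q-values <= 0.05.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Mapping, Set

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from tagdge.diffexpr import bh_fdr

__all__ = ["hypergeom_upper_tail", "enrich_terms"]


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_upper_tail(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) for X hypergeometric with N genes, n draws, M marked."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError("require 0 <= M <= N and 0 <= n <= N")
    if not (0 <= m <= min(n, M)):
        raise ValueError("require 0 <= m <= min(n, M)")
    if m == 0:
        return 1.0
    # Sum the tail i = m .. min(n, M) directly: exact and never suffers
    # the cancellation of the 1 - lower-tail form.
    i = np.arange(m, min(n, M) + 1, dtype=float)
    log_terms = _log_binom(M, i) + _log_binom(N - M, n - i) - _log_binom(N, np.array([float(n)]))
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def enrich_terms(
    annotation: Mapping[str, Set[str]],
    deg_set: Iterable[str],
    background_set: Iterable[str] | None = None,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every annotated term for enrichment in the DEG set.

    The universe is restricted to annotated genes (those with at least
    one term); ``background_set`` further restricts it when given. Terms
    annotating no background gene are skipped. Returns a DataFrame
    sorted by raw p-value with columns term, N, n, M, m, p_raw,
    p_corrected, significant.
    """
    annotated = {g for g, terms in annotation.items() if terms}
    if background_set is not None:
        annotated &= set(background_set)
    if not annotated:
        raise ValueError("background contains no annotated genes")
    degs = set(deg_set) & annotated
    if not set(deg_set) <= (annotated if background_set is None else set(background_set)):
        # DEGs without annotation simply fall outside the universe
        pass

    N = len(annotated)
    n = len(degs)
    term_members: dict[str, Set[str]] = {}
    for gene in annotated:
        for term in annotation[gene]:
            term_members.setdefault(term, set()).add(gene)

    rows = []
    for term, members in sorted(term_members.items()):
        M = len(members)
        if M == 0:
            continue
        m = len(members & degs)
        rows.append((term, N, n, M, m, hypergeom_upper_tail(N, n, M, m)))
    df = pd.DataFrame(rows, columns=["term", "N", "n", "M", "m", "p_raw"])
    if df.empty:
        df["p_corrected"] = []
        df["significant"] = []
        return df
    if correction == "bonferroni":
        df["p_corrected"] = np.minimum(df["p_raw"] * len(df), 1.0)
    elif correction == "bh":
        df["p_corrected"] = bh_fdr(df["p_raw"].to_numpy())
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    df["significant"] = df["p_corrected"] <= alpha
    return df.sort_values(["p_raw", "term"], kind="stable").reset_index(drop=True)
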