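"""Annotation-term enrichment for regulated-gene lists.

Implements the statistic behind the DAVID-style functional annotation
chart: a one-sided hypergeometric (Fisher) upper tail per term, with the
conservative EASE variant that decrements the observed overlap by one
before computing the tail, and Benjamini-Hochberg adjustment across the
terms tested.  The term database itself is a user-supplied gene->term
table (GMT-like); the background population is an explicit input, not a
hard-coded genome.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .preprocess import ConfigurationError


def hypergeom_tail(k: int, N: int, K: int, n: int, mode: str = "fisher") -> float:
    """Upper-tail P(X >= k) for overlap k of an n-gene list with a K-gene
    term in an N-gene background; ``mode='ease'`` uses k-1 in place of k
    (overlap of 1 or less is never significant: p = 1)."""
    if mode not in ("fisher", "ease"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if mode == "ease":
        k = k - 1
        if k <= 0:
            return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    gene_list,
    background,
    term_map: dict,
    mode: str = "fisher",
) -> pd.DataFrame:
    """Term enrichment of ``gene_list`` against ``background``.

    Parameters
    ----------
    gene_list, background : iterables of gene ids; the list must be a
        subset of the background.
    term_map : mapping term id -> iterable of gene ids.  Genes outside the
        background are dropped (one warning with the count).
    mode : 'fisher' for the plain one-sided exact test, 'ease' for the
        modified (k-1) variant.

    Returns a table with one row per term with overlap >= 1, columns
    term, n, N, K, k, p, p_adj, mode, sorted by adjusted then raw p.
    Terms with zero overlap are excluded from output and from the
    multiple-testing family.
    """
    genes = set(gene_list)
    bg = set(background)
    if not genes or not bg:
        raise ConfigurationError("gene list and background must be non-empty")
    if not genes <= bg:
        raise ConfigurationError(
            f"{len(genes - bg)} list genes are absent from the background"
        )
    N, n = len(bg), len(genes)
    dropped = 0
    rows = []
    for term, members in term_map.items():
        members = set(members)
        dropped += len(members - bg)
        members &= bg
        K = len(members)
        k = len(members & genes)
        if k == 0:
            continue
        rows.append((term, n, N, K, k, hypergeom_tail(k, N, K, n, mode)))
    if dropped:
        warnings.warn(f"dropped {dropped} term-gene links outside the background")
    out = pd.DataFrame(rows, columns=["term", "n", "N", "K", "k", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    out["mode"] = mode
    return out.sort_values(["p_adj", "p", "term"], ignore_index=True)
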