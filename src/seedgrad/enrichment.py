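"""Over-representation analysis of gene lists against annotation sets.

For each set a 2x2 table (in query & in set / in query & not / not in
query & in set / neither) is tested with a two-sided Fisher's exact test
(the minimum-likelihood convention), odds ratios use the Haldane 0.5
correction when a cell is zero, and p-values are Benjamini-Hochberg
adjusted. The background universe defaults to the analyzed gene panel,
since enrichment must be conditional on what could have been selected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSets

__all__ = ["fisher_enrichment", "fdr_bh"]


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    query,
    sets: AnnotationSets,
    background,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-set Fisher's exact over-representation of ``query`` in ``background``.

    Sets are intersected with the background before testing; a set with no
    background overlap is skipped with a warning. Columns: set_name,
    n_overlap, n_query, n_set_in_background, n_background, rich_factor,
    odds_ratio, p_value, q_value, significant. rich_factor is
    n_overlap / n_set_in_background, the fraction of the (background-
    restricted) set recovered by the query.
    """
    query = list(dict.fromkeys(query))
    background = list(dict.fromkeys(background))
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    bg = set(background)
    qset = set(query)
    if not qset <= bg:
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(bg)
    n_q = len(qset)
    rows = []
    for name, genes in sets.sets.items():
        in_bg = set(genes) & bg
        if not in_bg:
            warnings.warn(f"set {name!r} has no background overlap; skipped",
                          stacklevel=2)
            continue
        a = len(qset & in_bg)
        b = n_q - a
        c = len(in_bg) - a
        d = n_bg - n_q - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(
            (name, a, n_q, len(in_bg), n_bg, a / len(in_bg), orr, float(p))
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "set_name", "n_overlap", "n_query", "n_set_in_background",
            "n_background", "rich_factor", "odds_ratio", "p_value",
        ],
    )
    df["q_value"] = fdr_bh(df["p_value"].to_numpy()) if len(df) else []
    df["significant"] = df["q_value"] <= q_threshold if len(df) else []
    return df
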