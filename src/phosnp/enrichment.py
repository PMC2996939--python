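"""Hypergeometric term over/under-representation with BH-FDR, and Pearson
correlation of binary term-presence profiles between protein sets.

Proteins without any annotation are discarded from both the query and the
reference before testing.  Over- and under-representation are tested
one-sided per direction (upper and lower hypergeometric tails), with BH-FDR
applied within each direction across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import TermAnnotation
from .site_statistics import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    x: int  # annotated with term in query
    X: int  # annotated query size
    n: int  # annotated with term in reference
    N: int  # annotated reference size
    direction: str  # over | under
    p: float
    q: float


def term_enrichment(
    query_set: set[str],
    reference_set: set[str],
    annotations: Sequence[TermAnnotation],
    alpha: float = 5e-2,
    direction: str = "both",
    family: str = "per_direction",
) -> pd.DataFrame:
    """Over/under-represented terms in a query set versus its reference.

    Over-representation p is the upper hypergeometric tail P(K >= x) of
    drawing X annotated query proteins from the N annotated reference
    proteins of which n carry the term; under-representation is the lower
    tail P(K <= x).  ``family`` controls the BH family: ``per_direction``
    (default) adjusts each direction across terms separately, ``pooled``
    adjusts both together.
    """
    if not query_set <= reference_set:
        raise ValueError("query set must be a subset of the reference set")
    terms_of: dict[str, set[str]] = {}
    for ann in annotations:
        terms_of.setdefault(ann.protein_id, set()).add(ann.term_id)
    ref = {p for p in reference_set if terms_of.get(p)}
    query = {p for p in query_set if terms_of.get(p)}
    if not query:
        raise ValueError("no annotated proteins in the query set")
    N, X = len(ref), len(query)
    term_ref_counts: dict[str, int] = {}
    term_query_counts: dict[str, int] = {}
    for pid in ref:
        for term in terms_of[pid]:
            term_ref_counts[term] = term_ref_counts.get(term, 0) + 1
            if pid in query:
                term_query_counts[term] = term_query_counts.get(term, 0) + 1

    rows = []
    for term in sorted(term_ref_counts):
        n = term_ref_counts[term]
        x = term_query_counts.get(term, 0)
        if direction in ("over", "both"):
            p_over = float(sps.hypergeom.sf(x - 1, N, n, X))
            rows.append(
                {"term_id": term, "x": x, "X": X, "n": n, "N": N,
                 "direction": "over", "p": min(p_over, 1.0)}
            )
        if direction in ("under", "both"):
            p_under = float(sps.hypergeom.cdf(x, N, n, X))
            rows.append(
                {"term_id": term, "x": x, "X": X, "n": n, "N": N,
                 "direction": "under", "p": min(p_under, 1.0)}
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = np.nan
    if family == "pooled":
        df["q"] = bh_adjust(df["p"].to_list())
    else:
        for direc in df["direction"].unique():
            mask = (df["direction"] == direc).to_numpy()
            df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_list())
    df["significant"] = df["q"] <= alpha
    return df


def profile_correlation(
    presence_a: Sequence[int], presence_b: Sequence[int]
) -> tuple[float, bool]:
    """Pearson r between two binary term-presence profiles.

    Returns (r, defined).  When either profile is constant the correlation
    is undefined: r is NaN and the flag is False.
    """
    a = np.asarray(presence_a, dtype=float)
    b = np.asarray(presence_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if a.std() == 0 or b.std() == 0:
        return float("nan"), False
    r = float(np.corrcoef(a, b)[0, 1])
    return r, True


def presence_profile(
    protein_sets: dict[str, set[str]],
    significant_terms: dict[str, set[str]],
    term_universe: Sequence[str],
) -> dict[str, list[int]]:
    """Binary presence vectors of significant terms over an ordered universe.

    ``significant_terms`` maps a set label to the terms found significant for
    it; the output maps each label to its 0/1 vector over ``term_universe``.
    """
    return {
        label: [1 if t in significant_terms.get(label, set()) else 0
                for t in term_universe]
        for label in protein_sets
    }
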