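"""Hypergeometric overrepresentation analysis with BH correction.

Two entry points share the same machinery: GO-like term sets from GMT files
(communities >= 5 genes, terms >= 10 genes after universe intersection,
adjusted p < 0.005) and copy-number peak gene sets (no size thresholds,
adjusted p < 0.05).  Correction is applied per run across the full battery of
(community, term) pairs, which is order-invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

RECORD_COLUMNS = ["community_id", "term", "k", "K", "n", "N", "p", "p_adj", "significant"]


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if K > N or n > N:
        raise ValueError("K and n cannot exceed N")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1), original order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _run_battery(
    community_sets: dict, term_sets: dict, universe: set[str], alpha: float
) -> pd.DataFrame:
    n_universe = len(universe)
    rows = []
    for cid in sorted(community_sets):
        comm = community_sets[cid]
        for term in sorted(term_sets):
            tset = term_sets[term]
            k = len(comm & tset)
            p = hypergeometric_test(k, len(tset), len(comm), n_universe)
            rows.append((cid, term, k, len(tset), len(comm), n_universe, p))
    df = pd.DataFrame(
        rows, columns=["community_id", "term", "k", "K", "n", "N", "p"]
    )
    if len(df):
        df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df[RECORD_COLUMNS]


def enrich_communities(
    community_sets: dict[int, set[str]],
    term_sets: dict[str, set[str]],
    universe: set[str],
    min_community: int = 5,
    min_term: int = 10,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Term overrepresentation in communities (GO-style thresholds).

    Communities and terms are intersected with the universe before sizing;
    communities below ``min_community`` and terms below ``min_term`` are not
    tested at all.  BH runs over every tested (community, term) pair.
    """
    if not universe:
        raise ValueError("empty universe")
    comm = {
        cid: s & universe
        for cid, s in community_sets.items()
        if len(s & universe) >= min_community
    }
    terms = {
        t: s & universe for t, s in term_sets.items() if len(s & universe) >= min_term
    }
    return _run_battery(comm, terms, universe, alpha)


def enrich_cna_peaks(
    community_sets: dict[int, set[str]],
    peak_gene_sets: dict[str, dict[str, set[str]]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Peak-gene-set overrepresentation, amplifications and deletions apart.

    ``peak_gene_sets`` maps collection name (e.g. ``"amplification"`` /
    ``"deletion"``) to peak -> gene-set; no size thresholds apply and BH is
    run within each collection.
    """
    if not universe:
        raise ValueError("empty universe")
    comm = {cid: s & universe for cid, s in community_sets.items() if s & universe}
    frames = []
    for collection in sorted(peak_gene_sets):
        sets = {
            p: s & universe for p, s in peak_gene_sets[collection].items() if s & universe
        }
        if not sets:
            continue
        df = _run_battery(comm, sets, universe, alpha)
        df.insert(0, "collection", collection)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["collection", *RECORD_COLUMNS])
    return pd.concat(frames, ignore_index=True)
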