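"""Hypergeometric enrichment of aberrant pairs among curated signaling links.

Pathway databases give gene *sets*; the true pairwise relationships
within a pathway are taken from a manually curated signaling network.
For each pathway the test asks whether the curated links inside the
pathway overlap the predicted aberrant pairs more than chance would
allow, drawing without replacement from a universe of gene pairs:

    N = |(union of per-pathway curated links) union (all aberrant pairs)|
    M = curated links with both endpoints in the pathway
    K = all aberrant pairs (red and green pooled)
    x = |M intersect K|
    p = Pr(X >= x),  X ~ Hypergeometric(N, M, K)

p-values are corrected with Benjamini-Hochberg FDR within each database
(one family per database); pathways with q below the cutoff are called
dysregulated.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import canonical_pair

Pair = tuple[str, str]


def pathway_links(geneset: set[str], links: set[Pair]) -> set[Pair]:
    """Curated links with both endpoints inside the pathway's gene set."""
    return {(a, b) for a, b in links if a in geneset and b in geneset}


def build_universe(
    pathways: Mapping[str, set[str]],
    links: set[Pair],
    aberrant: set[Pair],
) -> tuple[set[Pair], dict[str, set[Pair]], set[Pair]]:
    """Universe, per-pathway curated-link sets, and the aberrant set K."""
    m_sets = {name: pathway_links(genes, links) for name, genes in pathways.items()}
    universe: set[Pair] = set(aberrant)
    for m in m_sets.values():
        universe |= m
    return universe, m_sets, set(aberrant)


def hypergeom_p(n: int, m: int, k: int, x: int) -> float:
    """Upper-tail Pr(X >= x) for X ~ Hypergeometric(N=n, M=m, K=k).

    Equals 1 - sum_{i<x} C(m,i) C(n-m,k-i) / C(n,k); x = 0 gives 1.
    """
    if not (0 <= m <= n and 0 <= k <= n and 0 <= x <= min(m, k)):
        raise ValueError(f"invalid counts N={n} M={m} K={k} x={x}")
    return float(stats.hypergeom.sf(x - 1, n, m, k))


def bh_fdr(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = list(p_values)
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_pathways(
    collections: Mapping[str, Mapping[str, set[str]]],
    links: set[Pair],
    red: set[Pair],
    green: set[Pair],
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """One hypergeometric test per pathway, FDR per database.

    ``collections`` maps database name -> {pathway name -> gene set}.
    Red and green pairs are pooled into one aberrant set K.  Pathways
    without curated links (M = 0) get p = 1 and stay in their family.
    Results are sorted by (database, q, pathway).
    """
    aberrant = {canonical_pair(*p) for p in red} | {
        canonical_pair(*p) for p in green
    }
    frames = []
    for db in sorted(collections):
        pathways = collections[db]
        universe, m_sets, k_set = build_universe(pathways, links, aberrant)
        n = len(universe)
        k = len(k_set)
        rows = []
        for name in sorted(pathways):
            m_links = m_sets[name]
            x = len(m_links & k_set)
            p = hypergeom_p(n, len(m_links), k, x) if n else 1.0
            rows.append((db, name, n, len(m_links), k, x, p))
        df = pd.DataFrame(
            rows, columns=["database", "pathway", "N", "M", "K", "x", "p"]
        )
        df["q"] = bh_fdr(df["p"])
        df["significant"] = df["q"] < q_cutoff
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["database", "pathway", "N", "M", "K", "x", "p", "q",
                 "significant"]
    )
    return out.sort_values(["database", "q", "pathway"]).reset_index(drop=True)
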