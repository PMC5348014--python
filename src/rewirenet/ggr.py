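"""Construction of per-condition gene-gene relationship (GGR) networks.

A GGR is an undirected graph ``(S, R)`` built for one condition (parental
or resistant) of one cell line.  The seed genes ``S`` are the union of
differentially expressed genes, cancer-census genes and *linker* genes;
the edges ``R`` combine three provenances:

* ``direct``   -- gene pairs in the top fraction of absolute Pearson
  correlation over the DE-union-cancer genes;
* ``indirect`` -- pairs lacking a direct edge but joined by at least one
  statistically significant length-2 path in the PPI network (the middle
  gene is a linker);
* ``ppi``      -- the two constituent PPI edges of each significant path.

Path significance is an exhaustive empirical test: the observed statistic
(geometric mean of the two absolute correlations along the path) is
compared against the same statistic for every eligible replacement of the
linker gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, canonical_pair

Pair = tuple[str, str]


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    expr: ExpressionMatrix,
    group_p: Iterable[str],
    group_r: Iterable[str],
    alpha: float,
) -> pd.DataFrame:
    """Two-tailed pooled-variance t-test per gene, Bonferroni corrected.

    Returns a frame indexed by gene with columns ``t``, ``p_raw``,
    ``p_bonferroni`` and boolean ``de`` (corrected p <= alpha).  Degenerate
    zero-pooled-variance genes get p=1 when the group means agree and p=0
    otherwise.
    """
    gp, gr = list(group_p), list(group_r)
    if len(gp) < 2 or len(gr) < 2:
        raise ValueError("each group needs >=2 samples for a pooled t-test")
    a = expr.values[gp].to_numpy(float)
    b = expr.values[gr].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    # zero pooled variance: scipy yields nan
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(a[degenerate].mean(axis=1), b[degenerate].mean(axis=1))
        p = p.copy()
        t = t.copy()
        p[np.flatnonzero(degenerate)[equal]] = 1.0
        t[np.flatnonzero(degenerate)[equal]] = 0.0
        p[np.flatnonzero(degenerate)[~equal]] = 0.0
        t[np.flatnonzero(degenerate)[~equal]] = np.inf
    m = len(expr.genes)
    p_bonf = np.minimum(1.0, p * m)
    return pd.DataFrame(
        {"t": t, "p_raw": p, "p_bonferroni": p_bonf, "de": p_bonf <= alpha},
        index=expr.genes,
    )


# ---------------------------------------------------------------------------
# correlations


class CorrelationTable:
    """Pearson correlations over the samples of one condition.

    Rows with zero variance are assigned correlation 0 with everything
    (undefined PCC recorded as 0), which excludes them from the top-
    fraction direct cut.  Correlations with arbitrary measured genes are
    available through :meth:`pcc` / :meth:`pcc_profile`, so path tests can
    probe genes outside any preselected subset.
    """

    def __init__(self, values: pd.DataFrame):
        if values.shape[1] < 3:
            raise ValueError("need >=3 samples to correlate")
        x = values.to_numpy(float)
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(xc, axis=1)
        ok = norm > 0
        z = np.zeros_like(xc)
        z[ok] = xc[ok] / norm[ok, None]
        self._z = z
        self._index = {g: i for i, g in enumerate(values.index)}
        self.genes = list(values.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def pcc(self, a: str, b: str) -> float:
        v = float(self._z[self._index[a]] @ self._z[self._index[b]])
        return max(-1.0, min(1.0, v))

    def pcc_profile(self, gene: str, others: list[str]) -> np.ndarray:
        idx = [self._index[g] for g in others]
        return np.clip(self._z[idx] @ self._z[self._index[gene]], -1.0, 1.0)

    def pairs(self, genes: Iterable[str]) -> pd.DataFrame:
        """All unordered pairs (gene_a < gene_b) with their PCC."""
        sel = sorted(set(genes))
        missing = [g for g in sel if g not in self._index]
        if missing:
            raise KeyError(f"genes without expression: {missing[:5]}")
        idx = [self._index[g] for g in sel]
        c = np.clip(self._z[idx] @ self._z[idx].T, -1.0, 1.0)
        iu, ju = np.triu_indices(len(sel), k=1)
        return pd.DataFrame(
            {
                "gene_a": [sel[i] for i in iu],
                "gene_b": [sel[j] for j in ju],
                "pcc": c[iu, ju],
            }
        )


def select_direct_edges(
    pairs: pd.DataFrame, fraction: float = 0.20
) -> tuple[set[Pair], float]:
    """Top-``fraction`` of |PCC| as direct edges.

    Retains exactly ``ceil(fraction * n_pairs)`` pairs, ranked by |PCC|
    descending with ties broken by lexicographic pair order.  Returns the
    edge set and the realized |PCC| value at the cut.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if pairs.empty:
        raise ValueError("empty correlation table")
    df = pairs.assign(abs_pcc=pairs["pcc"].abs()).sort_values(
        ["abs_pcc", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    k = math.ceil(fraction * len(df))
    top = df.iloc[:k]
    threshold = float(top["abs_pcc"].iloc[-1])
    edges = {canonical_pair(a, b) for a, b in zip(top["gene_a"], top["gene_b"])}
    return edges, threshold


# ---------------------------------------------------------------------------
# indirect edges via significant length-2 PPI paths


@dataclass
class PathTestResult:
    pair: Pair
    linker: str
    statistic: float
    p_value: float
    n_eligible: int
    untestable: bool = False


def _path_universe(ppi: nx.Graph, corr: CorrelationTable) -> list[str]:
    """Genes eligible as random replacement linkers: PPI nodes with data."""
    return sorted(g for g in ppi.nodes if g in corr)


def path_significance(
    i: str,
    j: str,
    linker: str,
    ppi: nx.Graph,
    corr: CorrelationTable,
    universe: list[str] | None = None,
) -> PathTestResult:
    """Empirical test of one length-2 path i - linker - j.

    The observed statistic is the geometric mean of |PCC(i, linker)| and
    |PCC(linker, j)|.  The null replaces the linker with every eligible
    gene (all network genes except i, j and any gene already on a
    length-2 PPI path between them) and the p-value is the fraction of
    null statistics >= the observed one.
    """
    if not (ppi.has_edge(i, linker) and ppi.has_edge(linker, j)):
        raise ValueError("i-linker and linker-j must be PPI edges")
    if universe is None:
        universe = _path_universe(ppi, corr)
    excluded = {i, j} | set(nx.common_neighbors(ppi, i, j))
    eligible = [g for g in universe if g not in excluded]
    observed = math.sqrt(abs(corr.pcc(i, linker)) * abs(corr.pcc(linker, j)))
    if not eligible:
        return PathTestResult((i, j), linker, observed, 1.0, 0, untestable=True)
    null = np.sqrt(
        np.abs(corr.pcc_profile(i, eligible)) * np.abs(corr.pcc_profile(j, eligible))
    )
    p = float(np.count_nonzero(null >= observed)) / len(eligible)
    return PathTestResult((i, j), linker, observed, p, len(eligible))


def find_indirect_edges(
    candidate_pairs: Iterable[Pair],
    ppi: nx.Graph,
    corr: CorrelationTable,
    alpha: float = 0.05,
) -> tuple[set[Pair], set[str], set[Pair]]:
    """Search each candidate pair for significant length-2 PPI paths.

    Returns (indirect pairs, linker genes, constituent PPI edges).  A pair
    is indirect iff at least one of its length-2 paths is significant; all
    linkers of significant paths and the PPI edges of those paths are
    collected.  Pairs with a gene missing from the PPI network are
    skipped.
    """
    universe = _path_universe(ppi, corr)
    indirect: set[Pair] = set()
    linkers: set[str] = set()
    ppi_edges: set[Pair] = set()
    for a, b in sorted(canonical_pair(*p) for p in set(candidate_pairs)):
        if a not in ppi or b not in ppi:
            continue
        middles = sorted(g for g in nx.common_neighbors(ppi, a, b) if g in corr)
        if not middles:
            continue
        excluded = {a, b} | set(nx.common_neighbors(ppi, a, b))
        eligible = [g for g in universe if g not in excluded]
        if not eligible:
            continue  # untestable paths are non-significant
        null = np.sqrt(
            np.abs(corr.pcc_profile(a, eligible))
            * np.abs(corr.pcc_profile(b, eligible))
        )
        obs = np.sqrt(
            np.abs(corr.pcc_profile(a, middles))
            * np.abs(corr.pcc_profile(b, middles))
        )
        n_elig = len(eligible)
        for linker, o in zip(middles, obs):
            p = float(np.count_nonzero(null >= o)) / n_elig
            if p <= alpha:
                indirect.add((a, b))
                linkers.add(linker)
                ppi_edges.add(canonical_pair(a, linker))
                ppi_edges.add(canonical_pair(linker, b))
    return indirect, linkers, ppi_edges


# ---------------------------------------------------------------------------
# GGR assembly and harmonization


@dataclass
class SeedGeneSet:
    condition: str
    de_genes: set[str]
    cgc_genes: set[str]
    linker_genes: set[str]

    @property
    def combined(self) -> set[str]:
        return self.de_genes | self.cgc_genes | self.linker_genes


@dataclass
class GGRNetwork:
    """Per-condition network: nodes S and edges with provenance labels."""

    condition: str
    nodes: set[str]
    edges: dict[Pair, frozenset[str]]
    seed: SeedGeneSet
    direct_threshold: float = float("nan")

    def __post_init__(self) -> None:
        for (a, b), labels in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop {a}")
            if not labels:
                raise ValueError(f"edge {(a, b)} without provenance")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)} outside node set")

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, ",".join(sorted(labels)))
            for (a, b), labels in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "provenance"])


def build_ggr(
    de: set[str],
    cgc: set[str],
    expr: ExpressionMatrix,
    ppi: nx.Graph,
    condition: str,
    direct_fraction: float = 0.20,
    path_alpha: float = 0.05,
) -> GGRNetwork:
    """Build the GGR for one condition from its expression samples.

    ``expr`` must already be restricted to the samples of the condition
    being modelled; correlations are computed over all measured genes so
    that the path test can draw replacement linkers from the whole PPI
    network.
    """
    measured = set(expr.genes)
    core = sorted((de | cgc) & measured)
    if not core:
        raise ValueError("empty DE-union-cancer gene set")
    corr = CorrelationTable(expr.values)
    pairs = corr.pairs(core)
    direct, threshold = select_direct_edges(pairs, direct_fraction)
    below_cut = [
        canonical_pair(a, b)
        for a, b in zip(pairs["gene_a"], pairs["gene_b"])
        if canonical_pair(a, b) not in direct
    ]
    indirect, linkers, ppi_edges = find_indirect_edges(
        below_cut, ppi, corr, path_alpha
    )
    edges: dict[Pair, set[str]] = {}
    for pair in direct:
        edges.setdefault(pair, set()).add("direct")
    for pair in indirect:
        edges.setdefault(pair, set()).add("indirect")
    for pair in ppi_edges:
        edges.setdefault(pair, set()).add("ppi")
    seed = SeedGeneSet(condition, de & measured, cgc & measured, linkers)
    nodes = seed.combined
    return GGRNetwork(
        condition,
        nodes,
        {p: frozenset(l) for p, l in edges.items()},
        seed,
        direct_threshold=threshold,
    )


@dataclass
class DyadTable:
    """All unordered pairs of the final seed genes with edge indicators."""

    genes: list[str]
    pairs: list[Pair]
    u_r: np.ndarray  # uint8, 1 iff pair is an edge of the resistant GGR
    u_p: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [a for a, _ in self.pairs],
                "gene_b": [b for _, b in self.pairs],
                "u_R": self.u_r.astype(int),
                "u_P": self.u_p.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DyadTable":
        pairs = [canonical_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
        genes = sorted({g for p in pairs for g in p})
        return cls(
            genes,
            pairs,
            df["u_R"].to_numpy(np.uint8),
            df["u_P"].to_numpy(np.uint8),
        )


def harmonize_conditions(
    ggr_r: GGRNetwork, ggr_p: GGRNetwork
) -> tuple[list[str], dict[str, dict[Pair, frozenset[str]]], DyadTable]:
    """Intersect the two per-condition node sets and enumerate dyads.

    The final seed set is S_R intersect S_P; both edge sets are restricted
    to pairs within it, and the dyad table enumerates every unordered pair
    of the final set with binary edge indicators for each condition.
    """
    final = sorted(ggr_r.nodes & ggr_p.nodes)
    if not final:
        raise ValueError("empty intersection of seed gene sets")
    keep = set(final)
    restricted = {
        "R": {p: l for p, l in ggr_r.edges.items() if p[0] in keep and p[1] in keep},
        "P": {p: l for p, l in ggr_p.edges.items() if p[0] in keep and p[1] in keep},
    }
    pairs = [canonical_pair(a, b) for a, b in combinations(final, 2)]
    u_r = np.fromiter((p in restricted["R"] for p in pairs), np.uint8, len(pairs))
    u_p = np.fromiter((p in restricted["P"] for p in pairs), np.uint8, len(pairs))
    return final, restricted, DyadTable(final, pairs, u_r, u_p)
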