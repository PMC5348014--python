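"""V-structure mining, pathway classification and dysregulation calls.

A V-structure is the elementary motif of signal rewiring: a *crossing
gene* g_k with one green edge (g_i, g_k) — the relationship present in
the parental network only — and one red edge (g_j, g_k) — present in the
resistant network only.  It captures a dependency switch of g_k from a
targeted partner to a bypass partner.

Against a pathway collection a V-structure is typed with precedence
III > II > I:

* Type-III — some single pathway contains all three genes;
* Type-II  — two different pathways hold the green and red pair, with
  the crossing gene in both (pathway cross-talk through g_k);
* Type-I   — all three genes are annotated but no pathway pairing above
  applies (the genes sit in different pathways);
* unclassified — at least one gene has no pathway annotation.

A gene is *dysregulated* when its log2 fold-change relative to the
parental baseline flips sign between the parental treatment contrast
(PT vs PB) and both resistant contrasts (RB vs PB, RT vs PB): the
expression move caused by the drug in sensitive cells is undone once
resistance is acquired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, canonical_pair

Pair = tuple[str, str]


@dataclass(frozen=True)
class VStructure:
    green_partner: str
    crossing: str
    red_partner: str

    @property
    def green_edge(self) -> Pair:
        return canonical_pair(self.green_partner, self.crossing)

    @property
    def red_edge(self) -> Pair:
        return canonical_pair(self.red_partner, self.crossing)

    @property
    def genes(self) -> set[str]:
        return {self.green_partner, self.crossing, self.red_partner}


def _incident(pairs: set[Pair]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for a, b in pairs:
        out.setdefault(a, set()).add(b)
        out.setdefault(b, set()).add(a)
    return out


def crossing_genes(red: set[Pair], green: set[Pair]) -> set[str]:
    """Genes incident to at least one red and at least one green edge."""
    return set(_incident(red)) & set(_incident(green))


def enumerate_vstructures(red: set[Pair], green: set[Pair]) -> list[VStructure]:
    """All (green edge, red edge) pairings at each crossing gene.

    The count is sum over crossing genes of deg_green * deg_red; red and
    green sets are mutually exclusive so each pairing shares exactly the
    crossing gene and duplicates cannot arise.
    """
    inc_r = _incident(red)
    inc_g = _incident(green)
    out = []
    for k in sorted(set(inc_r) & set(inc_g)):
        for gi in sorted(inc_g[k]):
            for gj in sorted(inc_r[k]):
                out.append(VStructure(gi, k, gj))
    return out


def classify_vstructure(
    vs: VStructure, pathways: Mapping[str, set[str]]
) -> tuple[str, list[str]]:
    """Type the motif against one pathway collection.

    Returns (type, supporting pathway names) where type is one of
    ``"III"``, ``"II"``, ``"I"``, ``"unclassified"``; precedence is
    III > II > I.
    """
    containing = {
        g: sorted(n for n, s in pathways.items() if g in s) for g in vs.genes
    }
    triple = [
        n for n, s in sorted(pathways.items()) if vs.genes <= s
    ]
    if triple:
        return "III", triple
    green_in = [
        n for n, s in sorted(pathways.items())
        if vs.green_partner in s and vs.crossing in s
    ]
    red_in = [
        n for n, s in sorted(pathways.items())
        if vs.red_partner in s and vs.crossing in s
    ]
    support = [
        f"{p1}|{p2}" for p1 in green_in for p2 in red_in if p1 != p2
    ]
    if support:
        return "II", support
    if all(containing[g] for g in vs.genes):
        return "I", []
    return "unclassified", []


def literature_overlap(
    structures: Iterable[VStructure], links: set[Pair]
) -> list[VStructure]:
    """V-structures whose red AND green edges are both curated links."""
    return [
        vs for vs in structures
        if vs.green_edge in links and vs.red_edge in links
    ]


def vstructure_table(
    structures: Iterable[VStructure],
    collections: Mapping[str, Mapping[str, set[str]]],
    links: set[Pair],
) -> pd.DataFrame:
    """One row per (V-structure, database), sorted for determinism."""
    rows = []
    for vs in structures:
        supported = vs.green_edge in links and vs.red_edge in links
        for db in sorted(collections):
            vtype, names = classify_vstructure(vs, collections[db])
            rows.append(
                (vs.green_partner, vs.crossing, vs.red_partner, vtype, db,
                 supported, ";".join(names[:5]))
            )
    df = pd.DataFrame(
        rows,
        columns=["green_gene", "crossing_gene", "red_gene", "type", "database",
                 "literature_supported", "pathways"],
    )
    return df.sort_values(
        ["green_gene", "crossing_gene", "red_gene", "database"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dysregulation


@dataclass
class DysregulationCall:
    gene: str
    fc_pt: float  # log2 FC of PT vs PB replicate means
    fc_rb: float
    fc_rt: float
    dysregulated: bool
    untestable: bool = False


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def dysregulation_call(
    expr: ExpressionMatrix, gene: str, log_scale: bool = False
) -> DysregulationCall:
    """Sign-flip call from replicate-mean fold-changes vs the PB baseline.

    With linear-scale input the fold-change is log2(mean_X / mean_PB); a
    non-positive mean leaves the gene untestable.  With ``log_scale`` the
    input is already log2 expression and fold-changes are mean
    differences.  Any strict sign flip counts; no magnitude threshold.
    """
    means = {c: expr.condition_mean(gene, c) for c in ("PB", "PT", "RB", "RT")}
    if log_scale:
        fc = {c: means[c] - means["PB"] for c in ("PT", "RB", "RT")}
    else:
        if any(v <= 0 for v in means.values()):
            return DysregulationCall(gene, math.nan, math.nan, math.nan,
                                     False, untestable=True)
        fc = {c: math.log2(means[c] / means["PB"]) for c in ("PT", "RB", "RT")}
    s = _sign(fc["PT"])
    dys = s != 0 and _sign(fc["RB"]) == _sign(fc["RT"]) == -s
    return DysregulationCall(gene, fc["PT"], fc["RB"], fc["RT"], dys)


def dysregulation_table(
    expr: ExpressionMatrix, genes: Iterable[str], log_scale: bool = False
) -> pd.DataFrame:
    rows = []
    for g in sorted(set(genes)):
        c = dysregulation_call(expr, g, log_scale=log_scale)
        rows.append((g, c.fc_pt, c.fc_rb, c.fc_rt, c.dysregulated, c.untestable))
    return pd.DataFrame(
        rows, columns=["gene", "FC_PT", "FC_RB", "FC_RT", "dysregulated",
                       "untestable"],
    )


def architecture_summary(
    red: set[Pair], green: set[Pair], calls: Mapping[str, bool]
) -> pd.DataFrame:
    """Dysregulation rates for genes with aberrant degree >= 2.

    Splits those genes into the both-colors group (>=1 red and >=1 green
    incident edge, i.e. crossing genes) and the single-color group, and
    reports the count and fraction dysregulated in each.
    """
    inc_r = _incident(red)
    inc_g = _incident(green)
    degree = {
        g: len(inc_r.get(g, ())) + len(inc_g.get(g, ()))
        for g in set(inc_r) | set(inc_g)
    }
    groups = {"both_colors": [], "single_color": []}
    for g, d in degree.items():
        if d < 2:
            continue
        key = "both_colors" if (g in inc_r and g in inc_g) else "single_color"
        groups[key].append(g)
    rows = []
    for name in ("both_colors", "single_color"):
        genes = sorted(groups[name])
        n_dys = sum(bool(calls.get(g, False)) for g in genes)
        frac = n_dys / len(genes) if genes else np.nan
        rows.append((name, len(genes), n_dys, frac))
    return pd.DataFrame(
        rows, columns=["group", "n_genes", "n_dysregulated",
                       "fraction_dysregulated"],
    )
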