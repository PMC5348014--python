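"""Selection of red/green aberrant gene pairs from edge posteriors.

Posterior edge probabilities of the resistant and parental networks live
on different scales, so each condition's posteriors are first divided by
that condition's maximum over all dyads.  Two reciprocal normalized odds
ratios are then formed per dyad,

    odds_R = norm_p_R / norm_p_P        odds_P = norm_p_P / norm_p_R,

and a two-stage empirical-threshold rule selects the aberrant pairs: per
condition, keep the top ``odds_fraction`` of the odds distribution, then
among those the top ``posterior_fraction`` of the normalized posteriors.
Pairs passing both cuts in the resistant direction are *red* (the
relationship gained in resistance), in the parental direction *green*
(the relationship lost).  "Top X%" retains ceil(X * n) values with ties
broken by lexicographic pair order, so selection is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import canonical_pair

Pair = tuple[str, str]
log = logging.getLogger(__name__)


@dataclass
class SelectionThresholds:
    odds_r: float
    odds_p: float
    posterior_r: float
    posterior_p: float

    def to_dict(self) -> dict[str, float]:
        return {
            "odds_threshold_R": self.odds_r,
            "odds_threshold_P": self.odds_p,
            "posterior_threshold_R": self.posterior_r,
            "posterior_threshold_P": self.posterior_p,
        }


def normalize_posteriors(posteriors: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Divide each condition's posteriors by its maximum over all dyads."""
    if posteriors.empty:
        raise ValueError("empty posterior table")
    out = posteriors.copy()
    maxima = {}
    for c in ("R", "P"):
        m = float(out[f"p_{c}"].max())
        if m <= 0:
            raise ValueError(f"no edge ever sampled in condition {c}")
        maxima[c] = m
        out[f"norm_p_{c}"] = out[f"p_{c}"] / m
    return out, maxima


def compute_odds(normalized: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal odds per dyad; zero-denominator dyads flagged ineligible."""
    out = normalized.copy()
    nr = out["norm_p_R"].to_numpy(float)
    np_ = out["norm_p_P"].to_numpy(float)
    eligible = (nr > 0) & (np_ > 0)
    odds_r = np.full(len(out), np.nan)
    odds_p = np.full(len(out), np.nan)
    odds_r[eligible] = nr[eligible] / np_[eligible]
    odds_p[eligible] = np_[eligible] / nr[eligible]
    out["odds_R"] = odds_r
    out["odds_P"] = odds_p
    out["odds_eligible"] = eligible
    n_dropped = int((~eligible).sum())
    if n_dropped:
        log.info("excluded %d dyads with a zero posterior from odds ranking",
                 n_dropped)
    return out


def _top_fraction(
    df: pd.DataFrame, column: str, fraction: float
) -> tuple[pd.DataFrame, float]:
    """ceil(fraction*n) largest values of ``column``, ties lexicographic."""
    ranked = df.sort_values(
        [column, "gene_a", "gene_b"], ascending=[False, True, True]
    )
    k = math.ceil(fraction * len(ranked))
    top = ranked.iloc[:k]
    return top, float(top[column].iloc[-1])


def select_aberrant(
    table: pd.DataFrame,
    odds_fraction: float = 0.20,
    posterior_fraction: float = 0.50,
) -> tuple[set[Pair], set[Pair], SelectionThresholds]:
    """Two-stage empirical-threshold selection of red and green pairs.

    A dyad that qualifies in both directions (possible only when both
    odds thresholds are <= 1) is given the color of its larger odds, with
    an exact tie resolved to red.
    """
    if not (0 < odds_fraction <= 1 and 0 < posterior_fraction <= 1):
        raise ValueError("fractions must be in (0, 1]")
    df = table[table["odds_eligible"]].copy()
    selected: dict[str, set[Pair]] = {}
    thresholds: dict[str, float] = {}
    for c in ("R", "P"):
        if df.empty:
            selected[c] = set()
            thresholds[f"odds_{c}"] = float("nan")
            thresholds[f"post_{c}"] = float("nan")
            continue
        stage1, odds_thr = _top_fraction(df, f"odds_{c}", odds_fraction)
        stage2, post_thr = _top_fraction(stage1, f"norm_p_{c}", posterior_fraction)
        selected[c] = {
            canonical_pair(a, b)
            for a, b in zip(stage2["gene_a"], stage2["gene_b"])
        }
        thresholds[f"odds_{c}"] = odds_thr
        thresholds[f"post_{c}"] = post_thr
    red, green = selected["R"], selected["P"]
    both = red & green
    if both:
        odds = {
            canonical_pair(a, b): (r, p)
            for a, b, r, p in zip(
                df["gene_a"], df["gene_b"], df["odds_R"], df["odds_P"]
            )
        }
        for pair in both:
            o_r, o_p = odds[pair]
            if o_r >= o_p:  # tie -> red
                green.discard(pair)
            else:
                red.discard(pair)
    if not red and not green:
        log.info("empty aberrant-pair selection")
    thr = SelectionThresholds(
        thresholds["odds_R"], thresholds["odds_P"],
        thresholds["post_R"], thresholds["post_P"],
    )
    return red, green, thr


def aberrant_table(
    table: pd.DataFrame, red: set[Pair], green: set[Pair]
) -> pd.DataFrame:
    """Flat output table of colored pairs, sorted by gene pair."""
    rows = []
    lookup = table.set_index(["gene_a", "gene_b"])
    for color, pairs in (("red", red), ("green", green)):
        for a, b in sorted(pairs):
            r = lookup.loc[(a, b)]
            rows.append(
                (a, b, color, r["p_R"], r["p_P"], r["norm_p_R"], r["norm_p_P"],
                 r["odds_R"], r["odds_P"])
            )
    rows.sort(key=lambda t: (t[0], t[1]))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "color", "posterior_R", "posterior_P",
            "norm_posterior_R", "norm_posterior_P", "odds_R", "odds_P",
        ],
    )


def posterior_pcc_diagnostic(
    aberrant: pd.DataFrame,
    pcc_r: dict[Pair, float],
    pcc_p: dict[Pair, float],
    window: int = 25,
) -> pd.DataFrame:
    """Posterior-vs-correlation robustness diagnostic.

    Red pairs contribute their resistant posterior as a positive value and
    their resistant |PCC|; green pairs their parental posterior negated
    and parental |PCC|.  Rows are sorted by signed posterior descending
    and the |PCC| column is smoothed with a centered moving average of
    ``window`` points (truncated at the ends).  A trend in the smoothed
    correlations mirroring the posterior curve indicates the model is
    tracking signal already present in the correlations.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for _, r in aberrant.iterrows():
        pair = canonical_pair(r["gene_a"], r["gene_b"])
        if r["color"] == "red":
            rows.append((*pair, "red", r["posterior_R"], abs(pcc_r[pair])))
        else:
            rows.append((*pair, "green", -r["posterior_P"], abs(pcc_p[pair])))
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "color", "signed_posterior", "abs_pcc"]
    )
    df = df.sort_values(
        ["signed_posterior", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["pcc_moving_avg"] = (
        df["abs_pcc"].rolling(window, center=True, min_periods=1).mean()
    )
    return df
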