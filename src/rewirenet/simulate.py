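"""Synthetic study generator with planted rewiring structure.

Produces fully synthetic versions of every pipeline input — matched
parental/resistant expression with PB/PT/RB/RT samples, a cancer-gene
list, a PPI network, pathway gene sets and a curated link network — with
known ground truth, so each stage and the end-to-end run can be scored
against planted features:

* co-expression *blocks* correlated in both conditions (shared latent
  factor; expected pairwise PCC equals the block rho);
* condition-specific *rewired mini-modules* sharing a latent factor in
  exactly one condition: each planted red anchor pair plus a few
  satellite genes correlates only in the resistant samples ("bypass"
  modules), each green anchor module only in the parental samples
  ("targeted" modules).  The p1 model detects rewiring as a coordinated
  change in connection propensity, so rewiring is planted as small
  modules rather than isolated edges — mirroring the compensatory-module
  biology the framework is meant to detect.  Each module has its own
  factor, so recovery failures are independent across modules;
* *crossing genes* carrying one planted red and one planted green edge,
  given the dysregulation sign pattern (mean shift one way under
  treatment in parental cells, the opposite way in both resistant
  conditions);
* *linker triples* (i, L, j) where L correlates with both i and j, i and
  j are uncorrelated, and the PPI network carries the i-L and L-j edges;
* one *enriched pathway* holding the planted rewired pairs as curated
  links, plus decoy pathways with background links.

All draws come from one seeded generator, so every artefact is
bit-reproducible from (scenario, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, canonical_pair, write_expression, \
    write_gene_sets, write_sample_sheet
from .p1 import expit
from .ggr import DyadTable

Pair = tuple[str, str]


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic matched-cell-line experiment."""

    n_genes: int = 120
    replicates: int = 3  # per condition x treatment level
    n_blocks: int = 1  # stable co-expression blocks (both conditions)
    block_size: int = 12
    block_rho: float = 0.7
    n_rewired_red: int = 6  # anchor pairs correlated only in resistant samples
    n_rewired_green: int = 6  # anchor pairs correlated only in parental samples
    rewired_rho: float = 0.95
    module_satellites: int = 8  # satellite genes per module factor
    off_rho: float = 0.45  # satellites' residual factor loading off-condition
    n_crossing: int = 4  # crossing genes carrying one red + one green pair
    dysreg_effect: float = 0.8  # mean shift of dysregulated crossing genes
    n_de_genes: int = 4  # background genes shifted in all resistant samples
    de_effect: float = 4.0
    n_linker_triples: int = 2
    linker_rho: float = 0.95
    ppi_background_p: float = 0.03
    noise_sd: float = 1.0
    baseline: float = 8.0
    n_decoy_pathways: int = 8
    decoy_size: int = 40
    links_per_decoy: int = 300
    cgc_extra: int = 0  # background genes added to the cancer-gene list
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.block_rho < 1 or not 0 < self.rewired_rho < 1:
            raise ValueError("correlation targets must lie in (0, 1)")
        if self.n_crossing > min(self.n_rewired_red, self.n_rewired_green):
            raise ValueError("more crossing genes than rewired pairs")
        n_extra = (
            self.n_rewired_red - self.n_crossing
            + self.n_rewired_green - self.n_crossing
        )
        if n_extra > 2 * self.n_crossing or (
            n_extra and self.module_satellites < 2
        ):
            raise ValueError(
                "extra anchor pairs are carved out of crossing-module "
                "satellites; need enough crossing modules with >=2 satellites"
            )
        need = (
            self.n_crossing * 3
            + 4 * self.module_satellites
            + 3 * self.n_linker_triples
            + self.n_blocks * self.block_size
            + self.n_de_genes
        )
        if need > self.n_genes:
            raise ValueError(f"n_genes too small for planted structure ({need})")

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    red_pairs: list[Pair]
    green_pairs: list[Pair]
    red_modules: list[list[str]]  # anchor pair + satellites, resistant-only
    green_modules: list[list[str]]
    crossing_genes: list[str]
    dysregulated: dict[str, int]  # gene -> sign of the PT shift
    de_genes: dict[str, int]  # gene -> sign of the resistant-condition shift
    linker_triples: list[tuple[str, str, str]]
    blocks: list[list[str]]
    cancer_genes: list[str]
    enriched_pathway: str

    def to_json(self) -> str:
        d = asdict(self)
        d["red_pairs"] = [list(p) for p in self.red_pairs]
        d["green_pairs"] = [list(p) for p in self.green_pairs]
        d["linker_triples"] = [list(t) for t in self.linker_triples]
        return json.dumps(d, indent=1, sort_keys=True)


def _layout(sc: SyntheticScenario) -> dict:
    """Deterministic assignment of gene indices to planted roles."""
    g = sc.genes
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = g[cursor:cursor + k]
        cursor += k
        return out

    crossing = take(sc.n_crossing)
    red_partner = take(sc.n_crossing)
    green_partner = take(sc.n_crossing)
    # two modules per color; each crossing gene joins one red and one
    # green module, with the two colorings split differently so module-
    # level recovery failures decorrelate across crossing genes
    n_c = sc.n_crossing
    red_split = [list(range(0, n_c, 2)), list(range(1, n_c, 2))]
    green_split = [list(range(0, (n_c + 1) // 2)), list(range((n_c + 1) // 2, n_c))]
    red_modules = [
        [crossing[i] for i in ix] + [red_partner[i] for i in ix]
        + take(sc.module_satellites)
        for ix in red_split
    ]
    green_modules = [
        [crossing[i] for i in ix] + [green_partner[i] for i in ix]
        + take(sc.module_satellites)
        for ix in green_split
    ]
    # extra anchor pairs beyond the crossing genes are satellite pairs
    # inside the modules (they share that module's factor)
    red_anchor = [(c, p) for c, p in zip(crossing, red_partner)]
    for m in range(sc.n_rewired_red - sc.n_crossing):
        sats = red_modules[m % len(red_modules)][-sc.module_satellites:]
        red_anchor.append((sats[2 * (m // 2)], sats[2 * (m // 2) + 1]))
    green_anchor = [(c, p) for c, p in zip(crossing, green_partner)]
    for m in range(sc.n_rewired_green - sc.n_crossing):
        sats = green_modules[m % len(green_modules)][-sc.module_satellites:]
        green_anchor.append((sats[2 * (m // 2)], sats[2 * (m // 2) + 1]))
    triples = [tuple(take(3)) for _ in range(sc.n_linker_triples)]
    blocks = [take(sc.block_size) for _ in range(sc.n_blocks)]
    de_genes = take(sc.n_de_genes)
    background = g[cursor:]
    return {
        "crossing": crossing,
        "red": [canonical_pair(*p) for p in red_anchor],
        "green": [canonical_pair(*p) for p in green_anchor],
        "red_modules": red_modules,
        "green_modules": green_modules,
        "triples": triples,  # (i, linker, j)
        "blocks": blocks,
        "de_genes": de_genes,
        "background": background,
    }


def _factor_pair(rho: float, f: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """x = sqrt(rho) f + sqrt(1-rho) eps gives corr rho between carriers."""
    return np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps


def simulate_expression(
    sc: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Parental and resistant expression matrices plus the ground truth.

    Values are linear-scale (positive around ``baseline``); the latent
    stochastic part of every gene has unit variance scaled by
    ``noise_sd``, so planted pairs have expected sample PCC close to
    their target rho.
    """
    rng = rng or np.random.default_rng(sc.seed)
    lay = _layout(sc)
    n_per_cond = 2 * sc.replicates
    gene_ix = {g: k for k, g in enumerate(sc.genes)}

    cond_samples = {
        "P": [("PB", r) for r in range(1, sc.replicates + 1)]
        + [("PT", r) for r in range(1, sc.replicates + 1)],
        "R": [("RB", r) for r in range(1, sc.replicates + 1)]
        + [("RT", r) for r in range(1, sc.replicates + 1)],
    }

    signs = {g: (1 if k % 2 == 0 else -1) for k, g in enumerate(lay["crossing"])}
    de_signs = {g: (1 if k % 2 == 0 else -1) for k, g in enumerate(lay["de_genes"])}

    values = {}
    for cond in ("P", "R"):
        z = rng.standard_normal((sc.n_genes, n_per_cond))
        # stable blocks: shared factor in both conditions with graded
        # per-gene loadings, so pairwise correlations form a continuum
        # whose ranking is stable across conditions (the top of the
        # direct-edge quota is then occupied by the same pairs in both
        # networks, as in real co-expression data)
        for block in lay["blocks"]:
            f = rng.standard_normal(n_per_cond)
            rhos = np.linspace(0.15, sc.block_rho, len(block))
            for g, rho_g in zip(block, rhos):
                z[gene_ix[g]] = _factor_pair(rho_g, f, z[gene_ix[g]])
        # rewired modules: full co-expression in the module's own
        # condition; in the other condition the anchor genes (crossing
        # genes and partners) decouple completely while satellites keep a
        # weak residual correlation (the bypass program pre-exists at low
        # coherence before rewiring amplifies it)
        for color, modules in (("R", lay["red_modules"]),
                               ("P", lay["green_modules"])):
            for module in modules:
                f = rng.standard_normal(n_per_cond)
                sats = set(module[-sc.module_satellites:])
                for g in module:
                    if cond == color:
                        rho = sc.rewired_rho
                        if color == "P" and g in signs:
                            # the parental treatment shift adds variance to
                            # dysregulated genes; a higher loading keeps
                            # their realized parental |PCC| near target
                            rho = min(0.99, sc.rewired_rho + 0.04)
                        z[gene_ix[g]] = _factor_pair(rho, f, z[gene_ix[g]])
                    elif g in sats and sc.off_rho > 0:
                        z[gene_ix[g]] = _factor_pair(sc.off_rho, f,
                                                     z[gene_ix[g]])
        # linker triples: L correlates with both ends, ends uncorrelated
        for i, linker, j in lay["triples"]:
            f1 = rng.standard_normal(n_per_cond)
            f2 = rng.standard_normal(n_per_cond)
            z[gene_ix[i]] = _factor_pair(sc.linker_rho, f1, z[gene_ix[i]])
            z[gene_ix[j]] = _factor_pair(sc.linker_rho, f2, z[gene_ix[j]])
            z[gene_ix[linker]] = (
                np.sqrt(sc.linker_rho / 2.0) * (f1 + f2)
                + np.sqrt(1.0 - sc.linker_rho) * z[gene_ix[linker]]
            )
        x = sc.baseline + sc.noise_sd * z
        # dysregulation mean shifts relative to the PB baseline
        for s_i, (label, _rep) in enumerate(cond_samples[cond]):
            for g, sign in signs.items():
                if label == "PT":
                    x[gene_ix[g], s_i] += sign * sc.dysreg_effect
                elif label in ("RB", "RT"):
                    x[gene_ix[g], s_i] -= sign * sc.dysreg_effect
            if cond == "R":
                # resistant-vs-parental expression shifts (DE genes); the
                # shift is constant within the condition so it leaves the
                # within-condition correlation structure untouched
                for g, sign in de_signs.items():
                    x[gene_ix[g], s_i] += sign * sc.de_effect
        names = [f"{label}_{rep}" for label, rep in cond_samples[cond]]
        values[cond] = pd.DataFrame(x, index=sc.genes, columns=names)

    truth = GroundTruth(
        red_pairs=sorted(lay["red"]),
        green_pairs=sorted(lay["green"]),
        red_modules=[list(m) for m in lay["red_modules"]],
        green_modules=[list(m) for m in lay["green_modules"]],
        crossing_genes=list(lay["crossing"]),
        dysregulated=signs,
        de_genes=de_signs,
        linker_triples=list(lay["triples"]),
        blocks=[list(b) for b in lay["blocks"]],
        cancer_genes=[],  # filled by simulate_cancer_genes
        enriched_pathway="PLANTED_REWIRED",
    )

    def _matrix(cond: str) -> ExpressionMatrix:
        cols = list(values[cond].columns)
        conditions = pd.Series(
            [c.split("_")[0] for c in cols], index=cols, name="condition"
        )
        reps = pd.Series(
            [int(c.split("_")[1]) for c in cols], index=cols, name="replicate"
        )
        return ExpressionMatrix(values[cond], conditions, reps)

    return _matrix("P"), _matrix("R"), truth


def combine_conditions(
    parental: ExpressionMatrix, resistant: ExpressionMatrix
) -> ExpressionMatrix:
    """Single four-condition matrix (shared gene universe)."""
    values = pd.concat([parental.values, resistant.values], axis=1)
    conditions = pd.concat([parental.conditions, resistant.conditions])
    reps = pd.concat([parental.replicates, resistant.replicates])
    return ExpressionMatrix(values, conditions, reps)


def simulate_cancer_genes(
    sc: SyntheticScenario, truth: GroundTruth, rng: np.random.Generator
) -> set[str]:
    """Synthetic cancer-gene list: planted-structure genes + background."""
    lay = _layout(sc)
    cgc = {g for m in truth.red_modules + truth.green_modules for g in m}
    cgc |= {i for i, _l, _j in truth.linker_triples}
    cgc |= {j for _i, _l, j in truth.linker_triples}
    pool = [g for g in lay["background"] + sum(truth.blocks, []) if g not in cgc]
    extra = rng.choice(pool, size=min(sc.cgc_extra, len(pool)), replace=False)
    cgc |= set(extra.tolist())
    truth.cancer_genes = sorted(cgc)
    return cgc


def simulate_ppi(
    sc: SyntheticScenario, truth: GroundTruth, rng: np.random.Generator
) -> set[Pair]:
    """Background random graph plus the planted linker paths."""
    genes = sc.genes
    pairs = list(combinations(genes, 2))
    mask = rng.random(len(pairs)) < sc.ppi_background_p
    edges = {canonical_pair(*p) for p, m in zip(pairs, mask) if m}
    for i, linker, j in truth.linker_triples:
        edges.add(canonical_pair(i, linker))
        edges.add(canonical_pair(linker, j))
        edges.discard(canonical_pair(i, j))  # keep the pair strictly indirect
    return edges


def simulate_pathways(
    sc: SyntheticScenario, truth: GroundTruth, rng: np.random.Generator
) -> tuple[dict[str, set[str]], set[Pair]]:
    """One enriched pathway plus decoys, and the curated link network.

    The enriched pathway holds the genes of every planted rewired module
    and all within-module pairs as curated links; decoy pathways carry
    background links uncorrelated with the planted rewiring.
    """
    planted_links: set[Pair] = set()
    for module in truth.red_modules + truth.green_modules:
        planted_links |= {
            canonical_pair(a, b) for a, b in combinations(sorted(module), 2)
        }
    enriched_genes = {g for p in planted_links for g in p}
    pathways = {truth.enriched_pathway: set(enriched_genes)}
    links: set[Pair] = set(planted_links)
    for d in range(sc.n_decoy_pathways):
        members = rng.choice(sc.genes, size=min(sc.decoy_size, sc.n_genes),
                             replace=False)
        name = f"DECOY_{d:02d}"
        pathways[name] = set(members.tolist())
        # decoy links stay outside the planted modules' pair space
        member_pairs = [
            canonical_pair(a, b)
            for a, b in combinations(sorted(members.tolist()), 2)
            if not (a in enriched_genes and b in enriched_genes)
        ]
        take = rng.choice(
            len(member_pairs),
            size=min(sc.links_per_decoy, len(member_pairs)),
            replace=False,
        )
        links |= {member_pairs[i] for i in take}
    return pathways, links


def simulate_p1_network(
    n_genes: int,
    theta: float,
    alpha: np.ndarray | float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Forward draw from the p1 model: independent logistic dyads.

    Returns a symmetric boolean adjacency matrix where dyad (i, j) is an
    edge with probability expit(theta + alpha_i + alpha_j).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    alpha = np.broadcast_to(np.asarray(alpha, float), (n_genes,))
    eta = theta + alpha[:, None] + alpha[None, :]
    p = expit(eta)
    draw = rng.random((n_genes, n_genes))
    adj = np.triu(draw < p, k=1)
    return adj | adj.T


def p1_dyad_table(
    adj_r: np.ndarray, adj_p: np.ndarray, genes: list[str] | None = None
) -> DyadTable:
    """Package two simulated adjacencies as a fit-ready dyad table."""
    n = adj_r.shape[0]
    genes = genes or [f"G{i:04d}" for i in range(n)]
    pairs = [canonical_pair(genes[i], genes[j]) for i, j in combinations(range(n), 2)]
    iu, ju = np.triu_indices(n, k=1)
    return DyadTable(
        sorted(genes), pairs,
        adj_r[iu, ju].astype(np.uint8), adj_p[iu, ju].astype(np.uint8),
    )


def write_scenario(sc: SyntheticScenario, out_dir: str | Path) -> GroundTruth:
    """Write every pipeline input file for a scenario into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sc.seed)
    parental, resistant, truth = simulate_expression(sc, rng)
    combined = combine_conditions(parental, resistant)
    cgc = simulate_cancer_genes(sc, truth, rng)
    ppi = simulate_ppi(sc, truth, rng)
    pathways, links = simulate_pathways(sc, truth, rng)

    write_expression(out / "expression.tsv", combined)
    write_sample_sheet(out / "samples.tsv", combined)
    (out / "cancer_genes.txt").write_text("\n".join(sorted(cgc)) + "\n")
    pd.DataFrame(sorted(ppi), columns=["gene_a", "gene_b"]).to_csv(
        out / "ppi.tsv", sep="\t", index=False, header=False
    )
    write_gene_sets(out / "pathways_SYN.gmt", pathways)
    pd.DataFrame(sorted(links), columns=["source", "target"]).to_csv(
        out / "links.tsv", sep="\t", index=False, header=False
    )
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
    return truth
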