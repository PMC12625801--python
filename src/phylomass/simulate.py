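"""Synthetic trees, extant trait tables, and fossil specimens.

The generator emulates the statistical structure of the extant primate
reference data the allometry is fit to: a pure-birth tree standardized to
unit depth, log-log linear trait relationships, and multivariate-normal
residuals whose covariance is a λ-scaled tree covariance.  Defaults follow
the fitted extant allometry — slope 1.26 and intercept 3.48 on the
ln-gram scale for FCSA, phylogenetic signal λ = 0.64, residual SD 0.37 per
unit depth — so simulated datasets behave like the reference data the
pipeline was designed for.  Fossil FCSA defaults span 55–710 mm², the range
observed across the subfossil lemur femora, so prediction is exercised out
to the same leverage.

Tree depth is standardized to 1, which makes σ interpretable as the
residual SD of ln body mass for one unit of independent evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import random as _random
import scipy.linalg as sla

from .predict import FossilPlacement
from .tree import PhyloTree, lambda_transform, vcv_from_tree

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_traits",
    "simulate_fossils",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a synthetic reference + fossil dataset.

    Defaults mirror the extant-primate study conditions: 62 reference
    species, FCSA allometry slope 1.26 with intercept 3.48 (ln grams),
    λ = 0.64, residual SD 0.37 per unit depth; femoral-length allometry
    slope 2.65, intercept −5.19, λ = 0.88.
    """

    n_extant: int = 62
    n_fossil_species: int = 15
    specimens_per_species: tuple[int, int] = (1, 10)
    slope: float = 1.26
    intercept: float = 3.48          # ln grams at FCSA = 1 mm²
    sigma: float = 0.37              # residual SD per unit standardized depth
    lambda_true: float = 0.64
    fcsa_range: tuple[float, float] = (5.0, 1000.0)        # extant, mm²
    fossil_fcsa_range: tuple[float, float] = (55.0, 710.0)  # mm²
    fcsa_jitter_sd: float = 0.05     # log-normal within-species measurement spread
    include_fl: bool = False
    fl_slope: float = 2.65
    fl_intercept: float = -5.19
    fl_sigma: float = 0.7
    fl_lambda: float = 0.88
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_extant < 2 or self.n_fossil_species < 1:
            raise ValueError("need at least 2 extant taxa and 1 fossil species")
        lo, hi = self.specimens_per_species
        if not (1 <= lo <= hi):
            raise ValueError("specimens_per_species must be an ordered range >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for rng_ in (self.fcsa_range, self.fossil_fcsa_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError("FCSA ranges must be positive and ordered")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")


def simulate_tree(n: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n`` extant tips, scaled to unit depth.

    The tree is ultrametric by construction and reproducible under ``seed``.
    Tips are labelled ``sp001`` ... in tree order.
    """
    if n < 2:
        raise ValueError("need at least 2 taxa")
    rng = _random.Random(int(seed))
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n,
        rng=rng,
    )
    dtree.seed_node.edge.length = 0.0
    # the process stops exactly at the n-th speciation, which leaves two
    # zero-length pendant edges (a singular Brownian covariance); grow all
    # tips by the Exp(n*birth_rate) wait to the next unobserved event
    extra = rng.expovariate(n * 1.0)
    for lf in dtree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    tree = PhyloTree(dtree)
    depth = max(tree.depths().values())
    for nd in dtree.preorder_node_iter():
        if nd.edge.length:
            nd.edge.length = nd.edge.length / depth
    width = len(str(n))
    for i, lf in enumerate(dtree.leaf_node_iter(), start=1):
        lf.taxon.label = f"sp{i:0{width}d}"
    return tree


def _phylo_noise(
    tree: PhyloTree,
    taxa: tuple[str, ...],
    sigma: float,
    lam: float,
    rng: np.random.Generator,
) -> np.ndarray:
    cov = lambda_transform(vcv_from_tree(tree, taxa), lam)
    L = sla.cholesky(cov.V, lower=True)
    return sigma * (L @ rng.standard_normal(len(taxa)))


def simulate_traits(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_residuals: bool = False,
):
    """Draw a species-mean trait table on ``tree`` under the config's model.

    ln(FCSA) is uniform over the log of the configured range; ln(BM, grams)
    follows the allometric line plus phylogenetic noise ε ~ N(0, σ²V(λ)),
    drawn through the Cholesky factor of the λ-scaled tree covariance.
    Femoral length, when requested, is generated by inverting its own
    allometry with independent phylogenetic noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    taxa = tuple(tree.tip_labels)
    if len(taxa) < 2:
        raise ValueError("tree must have at least 2 tips")
    lo, hi = np.log(config.fcsa_range)
    ln_fcsa = rng.uniform(lo, hi, size=len(taxa))
    eps = _phylo_noise(tree, taxa, config.sigma, config.lambda_true, rng)
    ln_bm_g = config.intercept + config.slope * ln_fcsa + eps
    table = pd.DataFrame(
        {
            "species": taxa,
            "bm_kg": np.exp(ln_bm_g) / 1000.0,
            "fcsa_mm2": np.exp(ln_fcsa),
        }
    )
    if config.include_fl:
        eps_fl = _phylo_noise(tree, taxa, config.fl_sigma, config.fl_lambda, rng)
        table["fl_mm"] = np.exp(
            (ln_bm_g - config.fl_intercept - eps_fl) / config.fl_slope
        )
    if return_residuals:
        return table, eps
    return table


def _graft_fossil_tips(
    tree: PhyloTree, labels: list[str], rng: np.random.Generator
) -> PhyloTree:
    """Attach pendant tips at random points on the tree, keeping it ultrametric."""
    out = tree.copy()
    dt = out._dtree
    tip_depth = max(out.depths().values()) - (dt.seed_node.edge.length or 0.0)
    for label in labels:
        nodes, depths, lengths = [], [], []
        cum = {id(dt.seed_node): 0.0}
        for nd in dt.preorder_node_iter():
            if nd.parent_node is None:
                continue
            d_par = cum[id(nd.parent_node)]
            ell = nd.edge.length or 0.0
            cum[id(nd)] = d_par + ell
            if ell > 0:
                nodes.append(nd)
                depths.append(d_par)
                lengths.append(ell)
        w = np.asarray(lengths)
        pick = rng.choice(len(nodes), p=w / w.sum())
        child, d_par, ell = nodes[pick], depths[pick], lengths[pick]
        u = rng.uniform(0.0, ell)  # attachment distance below the parent node
        parent = child.parent_node
        junction = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(junction)
        junction.edge.length = u
        junction.add_child(child)
        child.edge.length = ell - u
        taxon = dendropy.Taxon(label=label)
        dt.taxon_namespace.add_taxon(taxon)
        tip = dendropy.Node(taxon=taxon)
        junction.add_child(tip)
        tip.edge.length = tip_depth - (d_par + u)
    return out


def simulate_fossils(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    extant_residuals: np.ndarray | None = None,
):
    """Fossil species with true masses drawn from the generating process.

    Each fossil species is grafted at a random point on the tree; its true
    ln mass follows the same allometric line with a residual drawn jointly
    with the extant residuals (conditionally, when ``extant_residuals`` for
    the tree's tips are supplied) under the λ-scaled covariance of the
    extended tree.  Per-species specimen FCSAs are jittered log-normally.

    Returns ``(specimens, true_mass_kg, placements)``: a specimen table,
    a species-indexed Series of true masses, and per-species
    :class:`FossilPlacement` objects for BLUP-mode prediction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ext_taxa = tuple(tree.tip_labels)
    width = len(str(config.n_fossil_species))
    fossils = [f"fossil{i:0{width}d}" for i in range(1, config.n_fossil_species + 1)]
    grafted = _graft_fossil_tips(tree, fossils, rng)
    all_taxa = ext_taxa + tuple(fossils)
    C_full = vcv_from_tree(grafted, taxa=all_taxa).C
    ne = len(ext_taxa)
    lam = config.lambda_true
    S = lam * C_full
    np.fill_diagonal(S, np.diag(C_full))
    S_ee, S_fe, S_ff = S[:ne, :ne], S[ne:, :ne], S[ne:, ne:]

    if extant_residuals is not None:
        if len(extant_residuals) != ne:
            raise ValueError("extant residuals do not match the tree's tips")
        A = sla.solve(S_ee, S_fe.T, assume_a="pos")  # Σee⁻¹ Σef
        mean = A.T @ (np.asarray(extant_residuals) / config.sigma)
        cov = S_ff - S_fe @ A
    else:
        mean = np.zeros(len(fossils))
        cov = S_ff
    # guard tiny asymmetries / negative eigenvalues from the Schur complement
    cov = (cov + cov.T) / 2.0
    w, Q = np.linalg.eigh(cov)
    L = Q * np.sqrt(np.clip(w, 0.0, None))
    eps_f = config.sigma * (mean + L @ rng.standard_normal(len(fossils)))

    lo, hi = np.log(config.fossil_fcsa_range)
    ln_fcsa_sp = rng.uniform(lo, hi, size=len(fossils))
    ln_bm_true = config.intercept + config.slope * ln_fcsa_sp + eps_f
    true_mass = pd.Series(np.exp(ln_bm_true) / 1000.0, index=fossils,
                          name="true_bm_kg")

    klo, khi = config.specimens_per_species
    rows = []
    for i, sp in enumerate(fossils):
        k = int(rng.integers(klo, khi + 1))
        jitter = rng.normal(0.0, config.fcsa_jitter_sd, size=k)
        for j in range(k):
            rows.append(
                {
                    "specimen_id": f"{sp}-{j + 1}",
                    "species": sp,
                    "dataset": "simulated",
                    "fcsa_mm2": float(np.exp(ln_fcsa_sp[i] + jitter[j])),
                }
            )
    specimens = pd.DataFrame(rows)
    placements = {
        sp: FossilPlacement(
            cov_to_extant=C_full[ne + i, :ne].copy(),
            depth=float(C_full[ne + i, ne + i]),
        )
        for i, sp in enumerate(fossils)
    }
    return specimens, true_mass, placements


@dataclass
class SimulatedDataset:
    """A complete synthetic study: tree, reference traits, and fossils."""

    tree: PhyloTree
    traits: pd.DataFrame
    residuals: np.ndarray = field(repr=False)
    specimens: pd.DataFrame
    true_mass_kg: pd.Series
    placements: Mapping[str, FossilPlacement]
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate tree, extant traits, and fossils under one seeded process.

    Fossil residuals are drawn conditionally on the extant residuals, so the
    joint law over extant and fossil taxa is exactly the λ-scaled
    multivariate normal the PGLS model assumes.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_extant, seed=int(rng.integers(2**31 - 1)))
    traits, eps = simulate_traits(tree, config, rng=rng, return_residuals=True)
    specimens, truth, placements = simulate_fossils(
        tree, config, rng=rng, extant_residuals=eps
    )
    return SimulatedDataset(
        tree=tree, traits=traits, residuals=eps, specimens=specimens,
        true_mass_kg=truth, placements=placements, config=config,
    )
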