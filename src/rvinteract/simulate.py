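"""Two-gene interaction simulations for power and type-I-error studies.

Genotypes are drawn under Hardy-Weinberg equilibrium with rare minor
allele frequencies; disease status follows a two-locus penetrance placed
on the causal-burden scale (number of causal rare alleles carried per
gene) under one of four interaction models: multiplicative, additive, and
maximum / minimum carrier-threshold effects. The effective SNP ratio
controls which fraction of each causal gene's variants carries signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .collapse import GenotypeDataset, WeightScheme, collapse
from .search import exhaustive_search, permutation_pvalue

__all__ = [
    "MODELS",
    "SimConfig",
    "TruthLabels",
    "simulate_genotypes",
    "penetrance",
    "simulate_dataset",
    "calibrate_theta",
    "power_study",
    "type1_study",
]

MODELS = ("multiplicative", "additive", "threshold_max", "threshold_min")


@dataclass(frozen=True)
class SimConfig:
    """One executable simulation setting.

    ``effective_snp_ratio`` is the fraction of non-zero-weight (causal)
    SNPs per causal gene. ``weight_regime`` controls how annotation
    metadata is filled: ``none``/``maf`` leave annotations uninformative,
    ``cons`` draws a conservation score agreeing with true causality with
    probability ``cons_concordance``. ``theta_marginal`` defaults to
    ``theta`` when a marginal effect is requested.
    """

    model: str = "threshold_min"
    n_samples: int = 600
    n_snps_per_gene: int = 20
    n_genes: int = 2
    effective_snp_ratio: float = 1.0
    direction: str = "unidirectional"
    marginal_effect: bool = False
    weight_regime: str = "none"
    cons_concordance: float = 1.0
    f0: float = 0.1
    theta: float = 1.0
    theta_marginal: Optional[float] = None
    maf_range: tuple = (0.001, 0.01)
    threshold: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model: {self.model!r}")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes (the causal pair)")
        if self.n_samples < 1 or self.n_snps_per_gene < 1:
            raise ValueError("n_samples and n_snps_per_gene must be positive")
        if not 0.0 <= self.effective_snp_ratio <= 1.0:
            raise ValueError("effective_snp_ratio must lie in [0, 1]")
        if self.direction not in ("unidirectional", "bidirectional"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        if self.weight_regime not in ("none", "maf", "cons"):
            raise ValueError(f"unknown weight_regime: {self.weight_regime!r}")
        if not 0.0 < self.f0 < 1.0:
            raise ValueError("f0 must lie in (0, 1)")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5)")

    @property
    def n_causal_per_gene(self) -> int:
        return int(round(self.effective_snp_ratio * self.n_snps_per_gene))

    def is_null(self) -> bool:
        return self.theta == 0.0 or self.n_causal_per_gene == 0


@dataclass
class TruthLabels:
    """Ground truth of a simulated dataset."""

    causal_pair: tuple
    causal: np.ndarray      # per-variant bool
    sign: np.ndarray        # per-variant +1 deleterious / -1 protective / 0 non-causal


def _variant_names(config: SimConfig):
    genes = [f"G{k + 1:02d}" for k in range(config.n_genes)]
    gene_of = np.repeat(genes, config.n_snps_per_gene)
    variant_ids = [
        f"{g}_S{j + 1:02d}" for g in genes for j in range(config.n_snps_per_gene)
    ]
    return genes, gene_of, variant_ids


def simulate_genotypes(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GenotypeDataset:
    """HWE genotypes: per-variant MAF ~ U(maf_range), counts ~ Binomial(2, MAF)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes, gene_of, variant_ids = _variant_names(config)
    n_variants = config.n_genes * config.n_snps_per_gene
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_variants)
    genotypes = rng.binomial(2, mafs, size=(config.n_samples, n_variants)).astype(np.int8)
    return GenotypeDataset(
        genotypes=genotypes,
        variant_ids=variant_ids,
        gene_of=gene_of,
        sample_ids=[f"S{i + 1:05d}" for i in range(config.n_samples)],
        maf=mafs,  # generating MAFs are known; real data estimates instead
    )


def penetrance(model, u1, u2, f0, theta, marginal_effect=False, theta_marginal=None,
               threshold=1):
    """Disease probability given the two causal burdens.

    Baseline odds ``f0/(1-f0)`` are multiplied by an interaction factor:
    multiplicative ``(1+theta)^(u1*u2)``, additive ``(1+theta)^(u1+u2)``,
    threshold_max ``1+theta`` iff ``max(u1,u2) >= threshold``, and
    threshold_min ``1+theta`` iff ``min(u1,u2) >= threshold``. A marginal
    effect multiplies in ``(1+theta_m)^(u1+u2)``. Negative (net-protective)
    burdens are floored at 0 for the risk terms.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model: {model!r}")
    scalar = np.isscalar(u1) and np.isscalar(u2)
    u1 = np.maximum(np.asarray(u1, dtype=float), 0.0)
    u2 = np.maximum(np.asarray(u2, dtype=float), 0.0)
    if model == "multiplicative":
        m = (1.0 + theta) ** (u1 * u2)
    elif model == "additive":
        m = (1.0 + theta) ** (u1 + u2)
    elif model == "threshold_max":
        m = np.where(np.maximum(u1, u2) >= threshold, 1.0 + theta, 1.0)
    else:
        m = np.where(np.minimum(u1, u2) >= threshold, 1.0 + theta, 1.0)
    if marginal_effect:
        tm = theta if theta_marginal is None else theta_marginal
        m = m * (1.0 + tm) ** (u1 + u2)
    odds = (f0 / (1.0 - f0)) * m
    prob = odds / (1.0 + odds)
    return float(prob) if scalar else prob


def calibrate_theta(model: str, carrier_odds_ratio: float) -> float:
    """theta giving the target odds ratio for a single-carrier-pair cell.

    For the threshold and multiplicative models a (1,1) burden pair scales
    the odds by ``1+theta``; for the additive model by ``(1+theta)^2``.
    """
    if carrier_odds_ratio < 1.0:
        raise ValueError("carrier odds ratio must be >= 1")
    if model == "additive":
        return float(np.sqrt(carrier_odds_ratio) - 1.0)
    if model in ("multiplicative", "threshold_max", "threshold_min"):
        return float(carrier_odds_ratio - 1.0)
    raise ValueError(f"unknown model: {model!r}")


def simulate_dataset(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Simulate genotypes, causal structure, annotations and phenotype.

    Returns ``(GenotypeDataset, TruthLabels)``. The first two genes are
    causal; the first ``round(ratio * n_snps)`` variants of each are
    flagged causal. Under the bidirectional condition the second half of
    each gene's causal set is flipped to protective (sign -1) and burdens
    are signed sums floored at 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.model == "additive" and not config.marginal_effect and not config.is_null():
        raise ValueError(
            "the additive model carries marginal effects by construction; "
            "set marginal_effect=True for additive simulations"
        )
    dataset = simulate_genotypes(config, rng)
    n_variants = dataset.n_variants
    causal = np.zeros(n_variants, dtype=bool)
    sign = np.zeros(n_variants, dtype=np.int8)
    k = config.n_causal_per_gene
    genes = dataset.genes
    for g in range(2):
        start = g * config.n_snps_per_gene
        causal[start:start + k] = True
        sign[start:start + k] = 1
        if config.direction == "bidirectional":
            n_flip = k // 2
            if n_flip:
                sign[start + k - n_flip:start + k] = -1

    g_matrix = dataset.genotypes.astype(np.int64)
    burdens = []
    for g in range(2):
        start = g * config.n_snps_per_gene
        idx = np.arange(start, start + config.n_snps_per_gene)
        u = (g_matrix[:, idx] * sign[idx]).sum(axis=1)
        burdens.append(np.maximum(u, 0))
    prob = penetrance(
        config.model, burdens[0], burdens[1], config.f0, config.theta,
        marginal_effect=config.marginal_effect, theta_marginal=config.theta_marginal,
        threshold=config.threshold,
    )
    dataset.phenotype = rng.binomial(1, prob).astype(float)

    # annotation metadata: informative only under the 'cons' regime
    if config.weight_regime == "cons":
        agree = rng.random(n_variants) < config.cons_concordance
        informative = causal == agree  # True -> score drawn above the 0.5 cutoff
        low = rng.uniform(0.0, 0.5, size=n_variants)
        high = rng.uniform(0.5, 1.0, size=n_variants)
        conservation = np.where(informative, high, low)
        category = np.where(conservation >= 0.5, "high", "other").astype(object)
    else:
        conservation = np.full(n_variants, np.nan)
        category = np.full(n_variants, "high", dtype=object)
    dataset.conservation = conservation
    dataset.category = category
    truth = TruthLabels(causal_pair=(genes[0], genes[1]), causal=causal, sign=sign)
    return dataset, truth


def _scheme_or_default(scheme: Optional[WeightScheme]) -> WeightScheme:
    return scheme if scheme is not None else WeightScheme(kind="maf", n_bins=2)


def power_study(
    configs: Sequence[SimConfig],
    scheme: Optional[WeightScheme] = None,
    measure: str = "ig",
    n_replicates: int = 100,
    alpha: float = 0.05,
    detection_rule: str = "top1",
    n_folds: int = 10,
    n_permutations: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical detection power over a grid of simulation settings.

    ``detection_rule='top1'`` scores a replicate as detected when the
    causal pair ranks first in the exhaustive search; ``'pvalue'`` when
    the causal pair's permutation p-value falls below ``alpha``. Returns a
    table with one row per config: power and its binomial standard error.
    """
    if detection_rule not in ("top1", "pvalue"):
        raise ValueError(f"unknown detection_rule: {detection_rule!r}")
    scheme = _scheme_or_default(scheme)
    master = np.random.default_rng(seed)
    rows = []
    for config in configs:
        detected = 0
        for _ in range(n_replicates):
            # distinct streams for data and analysis: sharing one seed couples
            # fold construction to the simulated genotypes via the rng state
            sim_seed = int(master.integers(2 ** 31 - 1))
            analysis_seed = int(master.integers(2 ** 31 - 1))
            dataset, truth = simulate_dataset(config, np.random.default_rng(sim_seed))
            collapsed = collapse(dataset, scheme)
            pair = tuple(sorted(truth.causal_pair))
            if detection_rule == "top1":
                result = exhaustive_search(
                    collapsed, dataset.phenotype, dataset.covariates,
                    order=2, measure=measure, n_folds=n_folds, seed=analysis_seed,
                )
                detected += int(tuple(result.records[0].genes) == pair)
            else:
                p = permutation_pvalue(
                    collapsed, dataset.phenotype, dataset.covariates, pair,
                    statistic=measure, n_permutations=n_permutations,
                    seed=analysis_seed, n_folds=n_folds,
                )
                detected += int(p < alpha)
        power = detected / n_replicates
        rows.append(
            {
                "model": config.model,
                "n_samples": config.n_samples,
                "effective_snp_ratio": config.effective_snp_ratio,
                "theta": config.theta,
                "n_replicates": n_replicates,
                "power": power,
                "se": float(np.sqrt(power * (1 - power) / n_replicates)),
            }
        )
    return pd.DataFrame(rows)


def type1_study(
    config: SimConfig,
    n_replicates: int = 500,
    alpha: float = 0.05,
    n_permutations: int = 199,
    scheme: Optional[WeightScheme] = None,
    measure: str = "ig",
    n_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the full pipeline under a null simulation.

    Per replicate: simulate (no causal signal), collapse, exhaustively
    search order-2 combinations, and permutation-test the top pair; the
    rate is the fraction of replicates with p < alpha.
    """
    if not config.is_null():
        raise ValueError("type1_study requires a null config (theta=0 or ratio=0)")
    scheme = _scheme_or_default(scheme)
    master = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        # see power_study: analysis gets its own stream to keep folds
        # independent of the simulated data
        sim_seed = int(master.integers(2 ** 31 - 1))
        analysis_seed = int(master.integers(2 ** 31 - 1))
        dataset, _ = simulate_dataset(config, np.random.default_rng(sim_seed))
        collapsed = collapse(dataset, scheme)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = exhaustive_search(
                collapsed, dataset.phenotype, dataset.covariates,
                order=2, measure=measure, n_folds=n_folds, seed=analysis_seed,
            )
            p = permutation_pvalue(
                collapsed, dataset.phenotype, dataset.covariates,
                result.records[0].genes, statistic=measure,
                n_permutations=n_permutations, seed=analysis_seed, n_folds=n_folds,
            )
        rejections += int(p < alpha)
    rate = rejections / n_replicates
    return {
        "rate": rate,
        "se": float(np.sqrt(rate * (1 - rate) / n_replicates)),
        "rejections": rejections,
        "n_replicates": n_replicates,
        "alpha": alpha,
        "n_permutations": n_permutations,
    }
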