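"""Collapse rare variants into gene-level genotypes.

A samples x variants minor-allele-count matrix is reduced to a
samples x genes matrix of collapsed genotypes under one of three
per-variant weighting schemes:

``maf``
    weight 1 for variants with MAF below a rarity threshold, 0 otherwise;
    the weighted sum is binned into 2 levels (carrier yes/no) or 3 levels
    (0 / 1 / 2+ rare alleles).
``functional``
    weight 1 for variants in retained functional categories (by default
    the highly and moderately deleterious classes), 0 otherwise; always
    2 levels. A per-variant conservation score can substitute for the
    category labels via a cutoff.
``effect``
    per-direction (deleterious / protective) forward selection of variants
    by information gain with the phenotype; the collapsed genotype encodes
    net carrier direction on 3 levels (0 none, 1 net deleterious, 2 net
    protective).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .measures import information_gain

__all__ = [
    "MISSING",
    "CATEGORIES",
    "GenotypeDataset",
    "WeightScheme",
    "CollapsedMatrix",
    "DegenerateGeneWarning",
    "compute_maf",
    "maf_collapse",
    "functional_collapse",
    "directional_ig",
    "effect_collapse",
    "collapse",
]

#: Sentinel for a missing genotype call.
MISSING = -1

#: Recognized functional category labels (lower case).
CATEGORIES = ("high", "moderate", "low", "other", "unknown")


class DegenerateGeneWarning(UserWarning):
    """A gene collapsed to a constant column (useless for MDR downstream)."""


def _as_str_array(values, n, what):
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise ValueError(f"{what} must have length {n}")
    return arr


@dataclass
class GenotypeDataset:
    """Genotypes plus variant/sample metadata.

    ``genotypes`` holds minor-allele counts in {0, 1, 2} with ``MISSING``
    (-1) for no-calls. ``gene_of`` maps each variant column to exactly one
    gene symbol. ``phenotype`` is binary 0/1 (case-control) or real valued;
    it may be ``None`` for genotype-only datasets. ``covariates`` is an
    ``n_samples x k`` real matrix (k may be 0).
    """

    genotypes: np.ndarray
    variant_ids: list
    gene_of: np.ndarray
    phenotype: Optional[np.ndarray] = None
    covariates: Optional[np.ndarray] = None
    sample_ids: Optional[list] = None
    maf: Optional[np.ndarray] = None
    category: Optional[np.ndarray] = None
    conservation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x variants matrix")
        if not np.isin(g, (0, 1, 2, MISSING)).all():
            raise ValueError("genotype values must be in {0,1,2} or missing (-1)")
        self.genotypes = g.astype(np.int8, copy=False)
        n, v = g.shape
        self.variant_ids = list(self.variant_ids)
        if len(self.variant_ids) != v:
            raise ValueError("variant_ids length must equal n_variants")
        self.gene_of = _as_str_array(self.gene_of, v, "gene_of")
        if self.sample_ids is not None:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length must equal n_samples")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (n,):
                raise ValueError("phenotype length must equal n_samples")
        if self.covariates is None:
            self.covariates = np.empty((n, 0), dtype=float)
        else:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows must equal n_samples")
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (v,):
                raise ValueError("maf length must equal n_variants")
            finite = self.maf[np.isfinite(self.maf)]
            if ((finite < 0) | (finite > 0.5)).any():
                raise ValueError("maf values must lie in [0, 0.5]")
        if self.category is not None:
            cat = _as_str_array(self.category, v, "category")
            cat = np.array([str(c).lower() for c in cat], dtype=object)
            bad = sorted(set(cat) - set(CATEGORIES))
            if bad:
                raise ValueError(f"unknown functional categories: {bad}")
            self.category = cat
        if self.conservation is not None:
            self.conservation = np.asarray(self.conservation, dtype=float)
            if self.conservation.shape != (v,):
                raise ValueError("conservation length must equal n_variants")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def gene_blocks(self) -> dict:
        """Map gene symbol -> variant column indices, first-appearance order."""
        blocks: dict = {}
        for j, gene in enumerate(self.gene_of):
            blocks.setdefault(gene, []).append(j)
        return {g: np.asarray(idx) for g, idx in blocks.items()}

    @property
    def genes(self) -> list:
        return list(self.gene_blocks())

    def is_binary_phenotype(self) -> bool:
        if self.phenotype is None:
            return False
        return bool(np.isin(self.phenotype, (0.0, 1.0)).all())


@dataclass(frozen=True)
class WeightScheme:
    """Per-variant weighting rule producing the collapsed genotype.

    ``n_bins`` is only meaningful for ``kind='maf'``; the functional scheme
    always yields 2 bins and the effect scheme 3. ``use_conservation``
    switches the functional scheme from category labels to thresholding the
    conservation score at ``conservation_cutoff``.
    """

    kind: str = "maf"
    maf_threshold: float = 0.01
    n_bins: int = 2
    functional_keep: frozenset = frozenset({"high", "moderate"})
    use_conservation: bool = False
    conservation_cutoff: float = 0.5
    direction_mode: str = "bidirectional"

    def __post_init__(self) -> None:
        if self.kind not in ("maf", "functional", "effect"):
            raise ValueError(f"unknown scheme kind: {self.kind!r}")
        if self.n_bins not in (2, 3):
            raise ValueError("n_bins must be 2 or 3")
        if self.direction_mode not in ("unidirectional", "bidirectional"):
            raise ValueError(f"unknown direction_mode: {self.direction_mode!r}")

    @property
    def n_levels(self) -> int:
        """Number of collapsed genotype levels this scheme can produce."""
        if self.kind == "maf":
            return self.n_bins
        if self.kind == "functional":
            return 2
        return 3 if self.direction_mode == "bidirectional" else 2


@dataclass
class CollapsedMatrix:
    """Samples x genes collapsed genotypes plus the scheme that made them."""

    values: np.ndarray
    genes: list
    scheme: WeightScheme
    sample_ids: Optional[list] = None
    selected_variants: Optional[dict] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.genes):
            raise ValueError("values must be n_samples x n_genes")
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > self.scheme.n_levels - 1:
            raise ValueError("collapsed values exceed the scheme's bin range")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.scheme.n_levels

    def column(self, gene) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]


def compute_maf(dataset: GenotypeDataset) -> np.ndarray:
    """Folded per-variant minor allele frequency.

    Missing genotypes are excluded from the denominator; a variant with all
    calls missing gets MAF ``nan`` and a warning.
    """
    g = dataset.genotypes
    if g.shape[0] < 1:
        raise ValueError("need at least one sample")
    observed = g != MISSING
    n_obs = observed.sum(axis=0)
    alleles = np.where(observed, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alleles / (2.0 * n_obs)
    freq = np.where(n_obs > 0, freq, np.nan)
    if (n_obs == 0).any():
        bad = [dataset.variant_ids[j] for j in np.nonzero(n_obs == 0)[0]]
        warnings.warn(f"variants with all genotypes missing: {bad}", UserWarning)
    return np.minimum(freq, 1.0 - freq)


def _weighted_sum_collapse(dataset, weights, scheme, n_bins):
    """Shared weighted-sum + binning step; weights are per-variant 0/1."""
    g = np.where(dataset.genotypes == MISSING, 0, dataset.genotypes).astype(float)
    blocks = dataset.gene_blocks()
    values = np.zeros((dataset.n_samples, len(blocks)), dtype=np.int8)
    for k, (gene, idx) in enumerate(blocks.items()):
        w = weights[idx]
        if not w.any():
            warnings.warn(
                f"gene {gene!r} has no weight-1 variants; collapsed column is constant 0",
                DegenerateGeneWarning,
            )
            continue
        s = g[:, idx] @ w
        if n_bins == 2:
            values[:, k] = (s > 0).astype(np.int8)
        else:
            values[:, k] = np.minimum(s, 2).astype(np.int8)
    return CollapsedMatrix(values, list(blocks), scheme, sample_ids=dataset.sample_ids)


def maf_collapse(dataset: GenotypeDataset, scheme: WeightScheme) -> CollapsedMatrix:
    """Collapse by MAF-based weights (rare variants only count)."""
    if scheme.kind != "maf":
        raise ValueError("scheme kind must be 'maf'")
    maf = dataset.maf if dataset.maf is not None else compute_maf(dataset)
    with np.errstate(invalid="ignore"):
        weights = (maf < scheme.maf_threshold) & np.isfinite(maf)
    return _weighted_sum_collapse(dataset, weights.astype(float), scheme, scheme.n_bins)


def functional_collapse(dataset: GenotypeDataset, scheme: WeightScheme) -> CollapsedMatrix:
    """Collapse by functional-category (or conservation-score) weights."""
    if scheme.kind != "functional":
        raise ValueError("scheme kind must be 'functional'")
    if scheme.use_conservation:
        if dataset.conservation is None:
            raise ValueError("conservation scores required for conservation weighting")
        with np.errstate(invalid="ignore"):
            weights = np.nan_to_num(dataset.conservation, nan=-1.0) >= scheme.conservation_cutoff
    else:
        if dataset.category is None:
            raise ValueError("functional categories required for functional collapsing")
        keep = {c.lower() for c in scheme.functional_keep}
        weights = np.array([c in keep for c in dataset.category])
    return _weighted_sum_collapse(dataset, weights.astype(float), scheme, 2)


def directional_ig(carriers, phenotype, direction: str) -> float:
    """Information gain of carrier status, gated on effect direction.

    For ``direction='deleterious'`` the IG is reported only when the case
    carrier rate is at least the control carrier rate (otherwise 0);
    ``'protective'`` is the mirror image. The phenotype must be binary and
    non-constant.
    """
    if direction not in ("deleterious", "protective"):
        raise ValueError(f"unknown direction: {direction!r}")
    c = np.asarray(carriers).astype(bool)
    y = np.asarray(phenotype)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    n_case = int(y.sum())
    n_ctrl = int(y.size - n_case)
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("constant phenotype: association entropy undefined")
    case_rate = c[y == 1].mean()
    ctrl_rate = c[y == 0].mean()
    if direction == "deleterious" and case_rate < ctrl_rate:
        return 0.0
    if direction == "protective" and ctrl_rate < case_rate:
        return 0.0
    return information_gain(y, c.astype(int))


def _forward_select(carriers, y, variant_ids, direction):
    """Rank variants by directional IG and keep the best prefix set.

    Returns column indices (into ``carriers``) of the selected set; empty
    when no variant has positive directional IG.
    """
    igs = np.array(
        [directional_ig(carriers[:, j], y, direction) for j in range(carriers.shape[1])]
    )
    candidates = [j for j in range(carriers.shape[1]) if igs[j] > 0.0]
    # deterministic ranking: IG descending, then variant id
    candidates.sort(key=lambda j: (-igs[j], str(variant_ids[j])))
    best_set: list = []
    best_ig = 0.0
    for m in range(1, len(candidates) + 1):
        prefix = candidates[:m]
        joint = carriers[:, prefix].any(axis=1).astype(int)
        jig = information_gain(y, joint)
        if jig > best_ig + 1e-12:
            best_ig = jig
            best_set = list(prefix)
    return best_set


def effect_collapse(dataset: GenotypeDataset, scheme: WeightScheme) -> CollapsedMatrix:
    """Collapse by IG-driven forward selection per effect direction.

    Per gene and direction, variants are ranked by directional IG and nested
    prefix sets are scored by the IG between the phenotype and the set's
    carrier indicator; the smallest maximizing set is kept. The collapsed
    genotype encodes the signed selected-carrier count d = (#deleterious
    carried) - (#protective carried): d>0 -> 1, d<0 -> 2, d=0 -> 0. Under
    ``direction_mode='unidirectional'`` only deleterious sets are built and
    the coding is binary.
    """
    if scheme.kind != "effect":
        raise ValueError("scheme kind must be 'effect'")
    if dataset.phenotype is None or not dataset.is_binary_phenotype():
        raise ValueError("effect collapsing requires a binary phenotype")
    y = dataset.phenotype.astype(int)
    carriers_all = (np.where(dataset.genotypes == MISSING, 0, dataset.genotypes) >= 1)
    blocks = dataset.gene_blocks()
    values = np.zeros((dataset.n_samples, len(blocks)), dtype=np.int8)
    selected: dict = {}
    directions = ("deleterious",) if scheme.direction_mode == "unidirectional" else (
        "deleterious",
        "protective",
    )
    for k, (gene, idx) in enumerate(blocks.items()):
        carriers = carriers_all[:, idx]
        vids = [dataset.variant_ids[j] for j in idx]
        sets = {}
        for direction in directions:
            cols = _forward_select(carriers, y, vids, direction)
            sets[direction] = [vids[j] for j in cols]
        del_cols = [vids.index(v) for v in sets["deleterious"]]
        pro_cols = [vids.index(v) for v in sets.get("protective", [])]
        if not del_cols and not pro_cols:
            warnings.warn(
                f"gene {gene!r}: all directional IG values are 0; collapsed column is constant 0",
                DegenerateGeneWarning,
            )
            selected[gene] = ([], [])
            continue
        d = carriers[:, del_cols].sum(axis=1) - carriers[:, pro_cols].sum(axis=1)
        values[:, k] = np.where(d > 0, 1, np.where(d < 0, 2, 0)).astype(np.int8)
        selected[gene] = (sets["deleterious"], sets.get("protective", []))
    return CollapsedMatrix(
        values, list(blocks), scheme, sample_ids=dataset.sample_ids, selected_variants=selected
    )


def collapse(dataset: GenotypeDataset, scheme: WeightScheme) -> CollapsedMatrix:
    """Dispatch to the collapsing routine matching ``scheme.kind``."""
    if scheme.kind == "maf":
        return maf_collapse(dataset, scheme)
    if scheme.kind == "functional":
        return functional_collapse(dataset, scheme)
    return effect_collapse(dataset, scheme)
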