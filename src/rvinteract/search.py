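"""Exhaustive gene-combination search and permutation testing.

Every combination of the requested interaction order is cross-validated
with a shared fold assignment; combinations are ranked by weighted CV
consistency (per-fold max-normalized train statistic), tie-broken by mean
test statistic and then gene names. Permutation p-values re-run the CV
statistic under label shuffles with the fold assignment held fixed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .collapse import CollapsedMatrix
from .gmdr import (
    _cell_sums,
    _joint_codes,
    _risk_from_sums,
    cross_validate,
    fit_null_residuals,
    make_stratified_folds,
)
from .measures import _mi2x2, cvc as _cvc_count

__all__ = [
    "SearchRecord",
    "SearchResult",
    "exhaustive_search",
    "permutation_pvalue",
    "export_network",
]


@dataclass
class SearchRecord:
    """One ranked combination with its aggregate statistics."""

    genes: tuple
    wcvc: float
    cvc: int
    ba_train: float
    ba_test: float
    ig_test: float
    pvalue: Optional[float] = None


@dataclass
class SearchResult:
    """Ranked combinations plus the search settings that produced them."""

    records: list
    order: int
    measure: str
    n_folds: int
    seed: Optional[int]
    n_permutations: int = 0
    skipped_genes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": i + 1,
                "genes": ",".join(r.genes),
                "wcvc": r.wcvc,
                "ba_train": r.ba_train,
                "ba_test": r.ba_test,
                "ig_test": r.ig_test,
                "pvalue": r.pvalue,
            }
            for i, r in enumerate(self.records)
        ]
        return pd.DataFrame(
            rows, columns=["rank", "genes", "wcvc", "ba_train", "ba_test", "ig_test", "pvalue"]
        )


def exhaustive_search(
    collapsed: CollapsedMatrix,
    phenotype,
    covariates=None,
    order: int = 2,
    measure: str = "ig",
    n_folds: int = 10,
    seed: Optional[int] = 0,
    tie_high: bool = False,
    family: str = "auto",
) -> SearchResult:
    """Cross-validate every gene combination of the given order and rank.

    Constant collapsed columns are skipped with a warning. The fold-best
    combination of each fold is chosen by training statistic; CVC counts
    fold-best hits and WCVC sums per-fold train statistics normalized by
    the fold maximum.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    usable = [g for i, g in enumerate(collapsed.genes)
              if np.unique(collapsed.values[:, i]).size > 1]
    skipped = [g for g in collapsed.genes if g not in usable]
    if skipped:
        warnings.warn(f"skipping constant collapsed genes: {skipped}", UserWarning)
    if order > len(usable):
        raise ValueError(f"order {order} exceeds the {len(usable)} usable genes")
    rng = np.random.default_rng(seed)
    folds = make_stratified_folds(y, n_folds, rng)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.size == 0:
        cov = None
    # the null model is genotype-free, so one fit per fold serves all combinations
    fold_models = [
        fit_null_residuals(y[folds != f], None if cov is None else cov[folds != f], family)
        for f in range(n_folds)
    ]
    combos = [tuple(c) for c in itertools.combinations(sorted(usable), order)]
    results = [
        cross_validate(
            collapsed, y, cov, combo,
            n_folds=n_folds, measure=measure, seed=seed, folds=folds,
            tie_high=tie_high, family=family, fold_models=fold_models,
        )
        for combo in combos
    ]
    train_stats = np.array([r.fold_train_stat for r in results])  # combos x folds
    fold_best = [combos[int(np.argmax(train_stats[:, f]))] for f in range(n_folds)]
    with np.errstate(invalid="ignore", divide="ignore"):
        fold_max = train_stats.max(axis=0)
        norm = np.where(fold_max > 0, train_stats / np.where(fold_max > 0, fold_max, 1.0), 0.0)
    wcvc_scores = norm.sum(axis=1)
    records = [
        SearchRecord(
            genes=combo,
            wcvc=float(wcvc_scores[i]),
            cvc=_cvc_count(fold_best, combo),
            ba_train=results[i].mean_train_ba,
            ba_test=results[i].mean_test_ba,
            ig_test=results[i].mean_test_ig,
        )
        for i, combo in enumerate(combos)
    ]
    key = {"ig": "ig_test", "ba": "ba_test"}[measure]
    records.sort(key=lambda r: (-r.wcvc, -getattr(r, key), r.genes))
    return SearchResult(records, order, measure, n_folds, seed, skipped_genes=skipped)


def _binary_no_covariate_stats(codes, n_cells, Y, folds, n_folds, measure, tie_high):
    """Mean CV test statistic for each label row of ``Y`` (vectorized).

    Y is a B x n matrix of 0/1 label vectors (row 0 is typically the
    observed phenotype, the rest permutations). For the covariate-free
    binomial null, residuals are y - mean(y_train), so the per-cell signed
    sums reduce to case/control counts scaled by the training prevalence.
    Degenerate test folds contribute IG 0 / BA 0.5.
    """
    B, n = Y.shape
    # one GEMM tabulates case counts per (fold, cell) for every label row
    fc = folds * n_cells + codes
    onehot = np.zeros((n, n_folds * n_cells))
    onehot[np.arange(n), fc] = 1.0
    fold_cell_cases = (Y @ onehot).reshape(B, n_folds, n_cells)
    cell_n = np.bincount(fc, minlength=n_folds * n_cells).reshape(n_folds, n_cells)
    total_cases = fold_cell_cases.sum(axis=1)        # B x cells
    total_n = cell_n.sum(axis=0)                     # cells
    stats = np.zeros((B, n_folds))
    for f in range(n_folds):
        te = folds == f
        case_tr = total_cases - fold_cell_cases[:, f, :]
        n_tr_cell = total_n - cell_n[f]
        n_tr = int(n_tr_cell.sum())
        ybar = case_tr.sum(axis=1, keepdims=True) / n_tr
        pos = case_tr * (1.0 - ybar)
        neg = (n_tr_cell[None, :] - case_tr) * ybar
        seen = n_tr_cell > 0
        tol = 1e-9 * (pos + neg)
        if tie_high:
            risk = seen[None, :] & (pos >= neg - tol)
        else:
            risk = seen[None, :] & (pos > neg + tol)
        risk_te = np.take(risk, codes[te], axis=1)   # B x n_test
        Yte = Y[:, te] > 0.5
        tp = (risk_te & Yte).sum(axis=1)
        fp = (risk_te & ~Yte).sum(axis=1)
        fn = (~risk_te & Yte).sum(axis=1)
        tn = (~risk_te & ~Yte).sum(axis=1)
        if measure == "ig":
            stats[:, f] = _mi2x2(tp, fp, fn, tn)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.5)
                spec = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), 0.5)
            stats[:, f] = 0.5 * (sens + spec)
    return stats.mean(axis=1)


def _loop_stats(collapsed, Y, covariates, combination, folds, measure, tie_high, family):
    """Per-row CV statistic via the generic (covariate-aware) fold loop."""
    codes, levels = _joint_codes(collapsed, combination)
    n_cells = int(np.prod(levels))
    n_folds = int(folds.max()) + 1
    out = np.zeros(Y.shape[0])
    for b, y in enumerate(Y):
        vals = np.zeros(n_folds)
        for f in range(n_folds):
            tr = folds != f
            te = ~tr
            null = fit_null_residuals(y[tr], None if covariates is None else covariates[tr],
                                      family)
            pos, neg, seen = _cell_sums(np.asarray(null.residuals, float), codes[tr], n_cells)
            risk = _risk_from_sums(pos, neg, seen, tie_high)
            high_te = risk[codes[te]]
            yte = y[te] > 0.5
            tp = int(np.sum(high_te & yte)); fp = int(np.sum(high_te & ~yte))
            fn = int(np.sum(~high_te & yte)); tn = int(np.sum(~high_te & ~yte))
            if measure == "ig":
                vals[f] = float(_mi2x2(tp, fp, fn, tn))
            else:
                sens = tp / (tp + fn) if tp + fn > 0 else 0.5
                spec = tn / (tn + fp) if tn + fp > 0 else 0.5
                vals[f] = 0.5 * (sens + spec)
        out[b] = vals.mean()
    return out


def permutation_pvalue(
    collapsed: CollapsedMatrix,
    phenotype,
    covariates=None,
    combination: Sequence = (),
    statistic: str = "ig",
    n_permutations: int = 1000,
    seed: Optional[int] = 0,
    n_folds: int = 10,
    tie_high: bool = False,
    family: str = "auto",
    return_null: bool = False,
):
    """Permutation p-value for the CV test statistic of one combination.

    Phenotype labels alone are shuffled (covariate rows stay attached to
    their samples and the null GLM is refit per permutation); the fold
    assignment of the observed analysis is reused for every permutation and
    labels are permuted within folds, so permuted datasets keep the same
    per-fold class balance as the (stratified) observed analysis. The
    add-one estimator p = (1 + #{perm >= obs}) / (1 + B) is returned.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if statistic not in ("ig", "ba"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    combination = tuple(combination)
    y = np.asarray(phenotype, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("permutation testing requires a binary 0/1 phenotype")
    rng = np.random.default_rng(seed)
    folds = make_stratified_folds(y, n_folds, rng)
    n_folds_eff = int(folds.max()) + 1
    Y = np.empty((n_permutations + 1, y.size))
    Y[0] = y
    for f in range(n_folds_eff):
        idx = np.nonzero(folds == f)[0]
        Y[1:, idx] = rng.permuted(np.tile(y[idx], (n_permutations, 1)), axis=1)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.size == 0:
        cov = None
    if cov is None:
        codes, levels = _joint_codes(collapsed, combination)
        stats = _binary_no_covariate_stats(
            codes, int(np.prod(levels)), Y, folds, int(folds.max()) + 1, statistic, tie_high
        )
    else:
        stats = _loop_stats(collapsed, Y, cov, combination, folds, statistic, tie_high, family)
    observed = stats[0]
    p = (1.0 + np.sum(stats[1:] >= observed - 1e-12)) / (1.0 + n_permutations)
    if return_null:
        return float(p), float(observed), stats[1:]
    return float(p)


def export_network(result: SearchResult, top_k: int, path=None) -> pd.DataFrame:
    """Edge list (gene_a, gene_b, wcvc, pvalue) of the top-k order-2 pairs."""
    if result.order != 2:
        raise ValueError("network export requires order-2 (pairwise) results")
    if top_k < 0:
        raise ValueError("top_k must be non-negative")
    rows = [
        {"gene_a": r.genes[0], "gene_b": r.genes[1], "wcvc": r.wcvc, "pvalue": r.pvalue}
        for r in result.records[:top_k]
    ]
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "wcvc", "pvalue"])
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    return frame
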