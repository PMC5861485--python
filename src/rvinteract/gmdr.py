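"""Generalized MDR over collapsed gene genotypes.

The engine fits a covariate-only GLM (no genotype terms), pools each
sample's response-scale residual into the joint collapsed-genotype cell of
a gene combination, and labels a cell High risk when the summed positive
residual mass exceeds the summed negative mass. High/Low labels are then
scored against the phenotype under stratified k-fold cross-validation with
balanced accuracy and information gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .collapse import CollapsedMatrix
from .measures import ContingencySummary, balanced_accuracy, information_gain

__all__ = [
    "NullModel",
    "GmdrModel",
    "CvResult",
    "fit_null_residuals",
    "assign_risk",
    "classify",
    "cross_validate",
    "make_stratified_folds",
]


@dataclass
class NullModel:
    """Covariate-only GLM fit; residuals are on the response scale."""

    family: str
    params: np.ndarray
    residuals: np.ndarray
    covariate_names: Optional[list] = None


@dataclass
class GmdrModel:
    """Per-cell H/L risk map over the joint collapsed-genotype space."""

    combination: tuple
    cell_risk: dict
    cell_sums: dict
    levels: tuple
    _risk_dense: np.ndarray = field(repr=False, default=None)


@dataclass
class CvResult:
    """Per-fold train/test statistics of one gene combination."""

    combination: tuple
    measure: str
    fold_train_ba: np.ndarray
    fold_test_ba: np.ndarray
    fold_train_ig: np.ndarray
    fold_test_ig: np.ndarray
    n_folds: int
    seed: Optional[int] = None
    cvc: Optional[int] = None
    wcvc: Optional[float] = None

    def _stat(self, which: str, split: str) -> np.ndarray:
        return getattr(self, f"fold_{split}_{which}")

    @property
    def fold_train_stat(self) -> np.ndarray:
        return self._stat(self.measure, "train")

    @property
    def fold_test_stat(self) -> np.ndarray:
        return self._stat(self.measure, "test")

    @property
    def mean_train_ba(self) -> float:
        return float(np.mean(self.fold_train_ba))

    @property
    def mean_test_ba(self) -> float:
        return float(np.mean(self.fold_test_ba))

    @property
    def mean_train_ig(self) -> float:
        return float(np.mean(self.fold_train_ig))

    @property
    def mean_test_ig(self) -> float:
        return float(np.mean(self.fold_test_ig))

    @property
    def mean_test_stat(self) -> float:
        return float(np.mean(self.fold_test_stat))


def _check_full_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # walk columns to name the first one that adds no rank
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            label = names[j - 1] if names and j - 1 < len(names) else f"column {j - 1}"
            raise ValueError(f"covariate matrix is rank deficient: {label} is collinear")
    raise ValueError("covariate matrix is rank deficient")


def fit_null_residuals(
    phenotype,
    covariates=None,
    family: str = "auto",
    covariate_names: Optional[list] = None,
) -> NullModel:
    """Fit the genotype-free null GLM and return response-scale residuals.

    ``family`` is ``'binomial'`` (logit link), ``'gaussian'`` (identity) or
    ``'auto'`` (binomial iff the phenotype is 0/1). With no covariates the
    residual reduces to ``y - mean(y)`` for both families.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("phenotype must be a non-empty 1-D vector")
    binary = bool(np.isin(y, (0.0, 1.0)).all())
    if family == "auto":
        family = "binomial" if binary else "gaussian"
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family: {family!r}")
    if family == "binomial" and not binary:
        raise ValueError("binomial family requires a binary 0/1 phenotype")

    if covariates is None:
        cov = np.empty((y.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != y.size:
            raise ValueError("covariate rows must match phenotype length")

    if cov.shape[1] == 0:
        mu = y.mean()
        if family == "binomial":
            if mu in (0.0, 1.0):
                raise ValueError("constant binary phenotype: null model undefined")
            params = np.array([np.log(mu / (1 - mu))])
        else:
            params = np.array([mu])
        return NullModel(family, params, y - mu, covariate_names)

    X = np.column_stack([np.ones(y.size), cov])
    _check_full_rank(X, covariate_names)
    import statsmodels.api as sm

    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    result = sm.GLM(y, X, family=fam).fit()
    if not getattr(result, "converged", True):
        raise RuntimeError("null GLM did not converge")
    return NullModel(family, np.asarray(result.params), y - np.asarray(result.fittedvalues),
                     covariate_names)


def _joint_codes(collapsed: CollapsedMatrix, combination: Sequence) -> tuple:
    """Encode each sample's joint genotype tuple as an integer cell code."""
    cols = [collapsed.genes.index(g) for g in combination]
    L = collapsed.n_levels
    codes = np.zeros(collapsed.n_samples, dtype=np.int64)
    for j, c in enumerate(cols):
        codes += collapsed.values[:, c].astype(np.int64) * (L ** j)
    return codes, (L,) * len(cols)


def _risk_from_sums(pos: np.ndarray, neg: np.ndarray, seen: np.ndarray, tie_high: bool):
    """Dense H(True)/L(False) labels per cell; unseen cells are always L.

    Comparisons use a small relative tolerance so that sums equal in exact
    arithmetic (e.g. the covariate-free case/control ratio rule) register
    as ties regardless of floating-point rounding.
    """
    tol = 1e-9 * (pos + neg)
    if tie_high:
        return seen & (pos >= neg - tol)
    return seen & (pos > neg + tol)


def _cell_sums(residuals: np.ndarray, codes: np.ndarray, n_cells: int):
    pos = np.bincount(codes, weights=np.clip(residuals, 0, None), minlength=n_cells)
    neg = np.bincount(codes, weights=-np.clip(residuals, None, 0), minlength=n_cells)
    seen = np.bincount(codes, minlength=n_cells) > 0
    return pos, neg, seen


def assign_risk(
    model: NullModel,
    collapsed: CollapsedMatrix,
    combination: Sequence,
    train_idx=None,
    tie_high: bool = False,
) -> GmdrModel:
    """Group training residuals by joint genotype cell and label H/L.

    ``model.residuals`` must align with ``train_idx`` (``None`` = all
    samples). A cell is H iff its positive-residual sum strictly exceeds
    its absolute negative-residual sum; ties (including empty cells) are L
    unless ``tie_high``. Cells never observed in training are omitted from
    the map and classified L.
    """
    combination = tuple(combination)
    codes, levels = _joint_codes(collapsed, combination)
    if train_idx is None:
        train_idx = np.arange(collapsed.n_samples)
    train_idx = np.asarray(train_idx)
    resid = np.asarray(model.residuals, dtype=float)
    if resid.shape != train_idx.shape:
        raise ValueError("residuals must align with the training index")
    n_cells = int(np.prod(levels))
    pos, neg, seen = _cell_sums(resid, codes[train_idx], n_cells)
    risk = _risk_from_sums(pos, neg, seen, tie_high)
    cell_risk, cell_sums = {}, {}
    L = levels[0]
    for cell in np.nonzero(seen)[0]:
        key = tuple(int(cell // L ** j) % L for j in range(len(levels)))
        cell_risk[key] = "H" if risk[cell] else "L"
        cell_sums[key] = (float(pos[cell]), float(neg[cell]))
    return GmdrModel(combination, cell_risk, cell_sums, levels, _risk_dense=risk)


def classify(model: GmdrModel, collapsed: CollapsedMatrix, sample_idx=None) -> np.ndarray:
    """Predict 'H'/'L' for samples by cell lookup (unseen cells -> 'L')."""
    codes, levels = _joint_codes(collapsed, model.combination)
    if levels != model.levels:
        raise ValueError("collapsed matrix levels do not match the trained model")
    if sample_idx is not None:
        codes = codes[np.asarray(sample_idx)]
    return np.where(model._risk_dense[codes], "H", "L")


def make_stratified_folds(phenotype, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded fold assignment, stratified on case/control for binary traits."""
    y = np.asarray(phenotype)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    fold_ids = np.empty(y.size, dtype=np.int64)
    binary = bool(np.isin(y, (0, 1)).all())
    if binary:
        for cls in (0, 1):
            idx = np.nonzero(y == cls)[0]
            perm = rng.permutation(idx)
            fold_ids[perm] = np.arange(perm.size) % n_folds
    else:
        perm = rng.permutation(y.size)
        fold_ids[perm] = np.arange(y.size) % n_folds
    if binary:
        for f in range(n_folds):
            in_fold = y[fold_ids == f]
            if in_fold.size == 0 or len(np.unique(in_fold)) < 2:
                raise ValueError(
                    f"fold {f} lacks both classes; use fewer folds for this sample size"
                )
    return fold_ids


def _fold_confusion(y: np.ndarray, high: np.ndarray) -> ContingencySummary:
    return ContingencySummary.from_predictions(y, high)


def _safe_ba(y: np.ndarray, high: np.ndarray) -> float:
    try:
        return balanced_accuracy(_fold_confusion(y, high))
    except ValueError:
        return float("nan")


def cross_validate(
    collapsed: CollapsedMatrix,
    phenotype,
    covariates=None,
    combination: Sequence = (),
    n_folds: int = 10,
    measure: str = "ig",
    seed: Optional[int] = 0,
    folds: Optional[np.ndarray] = None,
    tie_high: bool = False,
    family: str = "auto",
    fold_models: Optional[list] = None,
) -> CvResult:
    """k-fold cross-validated GMDR evaluation of one gene combination.

    Folds are stratified on case/control and derived from ``seed`` unless an
    explicit ``folds`` assignment is given. Per fold, the null model is fit
    on the training split only, cells are labeled H/L from training
    residuals, and both balanced accuracy (H predicted case) and information
    gain (H/L factor vs phenotype) are recorded on train and test splits.
    ``measure`` ('ig' or 'ba') selects the headline statistic.
    """
    if measure not in ("ig", "ba"):
        raise ValueError(f"unknown measure: {measure!r}")
    combination = tuple(combination)
    if not combination:
        raise ValueError("empty gene combination")
    y = np.asarray(phenotype, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("cross-validation requires a binary 0/1 phenotype")
    if folds is None:
        folds = make_stratified_folds(y, n_folds, np.random.default_rng(seed))
    else:
        folds = np.asarray(folds)
        n_folds = int(folds.max()) + 1
    codes, levels = _joint_codes(collapsed, combination)
    n_cells = int(np.prod(levels))
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.size == 0:
        cov = None

    train_ba = np.empty(n_folds)
    test_ba = np.empty(n_folds)
    train_ig = np.empty(n_folds)
    test_ig = np.empty(n_folds)
    for f in range(n_folds):
        tr = folds != f
        te = ~tr
        if fold_models is not None:
            null = fold_models[f]
        else:
            null = fit_null_residuals(y[tr], None if cov is None else cov[tr], family)
        pos, neg, seen = _cell_sums(np.asarray(null.residuals, float), codes[tr], n_cells)
        risk = _risk_from_sums(pos, neg, seen, tie_high)
        high_tr = risk[codes[tr]]
        high_te = risk[codes[te]]
        train_ba[f] = _safe_ba(y[tr], high_tr)
        test_ba[f] = _safe_ba(y[te], high_te)
        train_ig[f] = information_gain(y[tr].astype(int), high_tr.astype(int))
        test_ig[f] = information_gain(y[te].astype(int), high_te.astype(int))
    return CvResult(
        combination=combination,
        measure=measure,
        fold_train_ba=train_ba,
        fold_test_ba=test_ba,
        fold_train_ig=train_ig,
        fold_test_ig=test_ig,
        n_folds=n_folds,
        seed=seed,
    )
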