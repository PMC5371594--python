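"""Cross-validated evaluation of the region-kernel classifier.

This module implements the full experimental harness: stratified k-fold
cross-validation with in-fold region selection, nested grid search over the
SVM trade-off C and the simplex of kernel weights q, classification metrics,
permutation-test significance of the cross-validated accuracy, ROC/AUC, and
a voxelwise two-sample t-map with cluster extraction.

Per outer fold the pipeline (a) trains a whole-brain linear SVM on the
training subjects only, (b) averages |w| per region to score importance and
keeps the top-k regions, (c) grid-searches (C, q) by inner cross-validation
on the training partition over the selected region kernels, (d) trains the
multi-kernel model and (e) predicts the held-out fold.  Region selection and
hyperparameter tuning therefore never see test data.

The permutation test re-runs this complete pipeline (including region
selection) for each relabeling and reports the fraction of null accuracies
greater than or equal to the observed one.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import svm as _svm
from ._smo import DEFAULT_TOL, grid_fold_counts
from .importance import region_weights, select_top_regions, voxel_weight_map
from .parcellation import merged_region_names, region_voxel_index
from .phantom import SubjectRecord
from .volumes import Atlas, BrainMask, Volume, compute_brain_mask


# ---------------------------------------------------------------------------
# hyperparameter grid

@dataclass
class GridSpec:
    """Search grid: C = 2^e over ``c_exponents``; q on a step-``q_step``
    simplex lattice; validated by ``inner_folds``-fold CV on the training
    partition."""

    c_exponents: tuple[int, ...] = tuple(range(-3, 6))
    q_step: float = 0.1
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not self.c_exponents:
            raise ValueError("need at least one C value")
        denom = round(1.0 / self.q_step)
        if abs(denom * self.q_step - 1.0) > 1e-9:
            raise ValueError("q_step must divide 1")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    @property
    def c_values(self) -> np.ndarray:
        return np.array([2.0**e for e in self.c_exponents])


def enumerate_simplex_grid(n_k: int, step: float = 0.1) -> np.ndarray:
    """All weight vectors on the step lattice with q_m >= step, sum q = 1.

    Returned in lexicographic order, shape (n_candidates, n_k).  For
    ``n_k == 1`` the single vector (1.0) is returned.
    """
    if n_k < 1:
        raise ValueError("n_k must be >= 1")
    denom = round(1.0 / step)
    if abs(denom * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    if n_k > denom:
        raise ValueError(f"infeasible: {n_k} kernels with step {step}")
    if n_k == 1:
        return np.array([[1.0]])

    out: list[list[int]] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            if remaining >= 1:
                out.append(prefix + [remaining])
            return
        for c in range(1, remaining - (slots - 1) + 1):
            rec(prefix + [c], remaining - c, slots - 1)

    rec([], denom, n_k)
    return np.array(out, dtype=np.float64) / denom


# ---------------------------------------------------------------------------
# folds and metrics

def stratified_kfold(labels: Sequence, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1 per sample), class-stratified, seeded shuffle.

    Fold sizes differ by at most one, as do per-class counts across folds.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        # stratification impossible (a class has fewer members than folds)
        warnings.warn(
            f"class with {counts.min()} members < k={k}; falling back to "
            "unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)), labels)
    assign = np.empty(n, dtype=np.int64)
    for f, (_, test_idx) in enumerate(split):
        assign[test_idx] = f
    return assign


def metrics(
    y_true: Sequence, y_pred: Sequence, positive_class
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); rates for the positive class.

    Sensitivity = TP / (TP + FN), specificity = TN / (TN + FP).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must be nonempty and equal length")
    pos = y_true == positive_class
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present in y_true")
    acc = float(np.mean(y_true == y_pred))
    sens = float(np.mean(y_pred[pos] == positive_class))
    spec = float(np.mean(y_pred[~pos] != positive_class))
    return acc, sens, spec


def per_class_accuracy(y_true: Sequence, y_pred: Sequence) -> dict[str, float]:
    """Per-class recall: correct within the class / class size."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {}
    for c in np.unique(y_true):
        sel = y_true == c
        out[str(c)] = float(np.mean(y_pred[sel] == c))
    return out


# ---------------------------------------------------------------------------
# grid search over (C, q)

def grid_search_kernels(
    K_blocks: np.ndarray,
    y: np.ndarray,
    grid: GridSpec,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Pick (C, q) maximizing inner-CV accuracy over precomputed block kernels.

    ``K_blocks`` has shape (n_kernels, n, n) over the training samples only.
    Ties go to the smaller C, then the lexicographically smallest q, so the
    result does not depend on enumeration order.  Returns (C, q, accuracy).
    """
    K_blocks = np.asarray(K_blocks, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    Q = enumerate_simplex_grid(K_blocks.shape[0], grid.q_step)
    Cs = grid.c_values
    order = np.argsort(Cs, kind="stable")  # ascending C enables warm starts
    Cs_sorted = Cs[order]

    n_splits = min(grid.inner_folds, int(min(np.sum(y > 0), np.sum(y < 0))))
    n_splits = max(2, n_splits)
    assign = stratified_kfold(y, k=n_splits, seed=seed)
    counts = np.zeros((Q.shape[0], Cs_sorted.size), dtype=np.float64)
    for f in range(n_splits):
        val = assign == f
        tr = ~val
        Btr = K_blocks[:, tr][:, :, tr]
        Bval = K_blocks[:, val][:, :, tr]
        grid_fold_counts(Btr, Bval, y[tr], y[val], Q, Cs_sorted, DEFAULT_TOL, 200_000, counts)

    best = counts.max()
    # ties: smallest C first, then lexicographically smallest q
    for cj in range(Cs_sorted.size):
        for ci in range(Q.shape[0]):
            if counts[ci, cj] == best:
                return float(Cs_sorted[cj]), Q[ci].copy(), float(best / n)
    raise RuntimeError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# the cross-validated pipeline

@dataclass
class EvalOptions:
    """Configuration of the cross-validated experiment."""

    mode: str = "binary"  # binary | multiclass | multimodal
    k: int = 10
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    top_regions: int = 5
    primary_modality: str = "DMFP"
    #: extra (modality, region) kernel blocks appended in multimodal mode
    extra_blocks: tuple[tuple[str, str], ...] = (("DaTSCAN", "striatum"),)
    selection_C: float = 1.0
    mask_frac: float = 0.05
    merge_lr: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "multiclass", "multimodal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class FoldResult:
    fold: int
    test_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    decision: list[float] | None
    selected_regions: list[str]
    C: float | dict
    q: list | dict


@dataclass
class CVReport:
    """Per-fold predictions plus pooled metrics of one CV experiment."""

    mode: str
    classes: list[str]
    positive_class: str | None
    folds: list[FoldResult]

    @property
    def y_true(self) -> list[str]:
        return [y for f in self.folds for y in f.y_true]

    @property
    def y_pred(self) -> list[str]:
        return [y for f in self.folds for y in f.y_pred]

    @property
    def subject_ids(self) -> list[str]:
        return [s for f in self.folds for s in f.test_ids]

    @property
    def decision_values(self) -> list[float] | None:
        if any(f.decision is None for f in self.folds):
            return None
        return [d for f in self.folds for d in f.decision]

    @property
    def accuracy(self) -> float:
        return float(np.mean(np.asarray(self.y_true) == np.asarray(self.y_pred)))

    def binary_metrics(self) -> tuple[float, float, float]:
        if self.positive_class is None:
            raise ValueError("binary metrics require a positive class")
        return metrics(self.y_true, self.y_pred, self.positive_class)

    def class_accuracies(self) -> dict[str, float]:
        return per_class_accuracy(self.y_true, self.y_pred)

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "classes": self.classes,
            "positive_class": self.positive_class,
            "accuracy": self.accuracy,
            "folds": [
                {
                    "fold": f.fold,
                    "test_ids": f.test_ids,
                    "y_true": f.y_true,
                    "y_pred": f.y_pred,
                    "decision": f.decision,
                    "selected_regions": f.selected_regions,
                    "C": f.C,
                    "q": f.q,
                }
                for f in self.folds
            ],
        }
        if self.positive_class is not None:
            acc, sens, spec = self.binary_metrics()
            d.update(sensitivity=sens, specificity=spec)
        else:
            d["per_class_accuracy"] = self.class_accuracies()
        return d

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


BINARY_POSITIVE = "atypical"  # MSA u PSP pooled
BINARY_NEGATIVE = "PD"


def binary_label(diagnosis: str) -> str:
    return BINARY_NEGATIVE if diagnosis == "PD" else BINARY_POSITIVE


@dataclass
class PipelinePrecomp:
    """Label-independent precomputation shared by CV and permutation runs."""

    ids: list[str]
    diagnoses: np.ndarray
    atlas: Atlas
    opts: EvalOptions
    mask: BrainMask
    wb_index: np.ndarray
    X_wb: np.ndarray
    K_wb: np.ndarray
    candidate_regions: list[str]
    X_region: dict[tuple[str, str], np.ndarray]
    K_region: dict[tuple[str, str], np.ndarray]


def prepare_pipeline(
    subjects: list[SubjectRecord], atlas: Atlas, opts: EvalOptions
) -> PipelinePrecomp:
    """Extract features and Gram matrices once; labels are not consulted."""
    n = len(subjects)
    if n < opts.k:
        raise ValueError("fewer subjects than folds")
    primary = opts.primary_modality
    vols = [s.volumes[primary] for s in subjects]
    mean_img = np.mean([v.data for v in vols], axis=0)
    intensity_mask = compute_brain_mask(
        Volume(mean_img, affine=vols[0].affine), frac=opts.mask_frac
    ).data
    mask = BrainMask(intensity_mask | (atlas.labels > 0))
    wb_index = np.argwhere(mask.data)
    X_wb = np.stack(
        [v.data[wb_index[:, 0], wb_index[:, 1], wb_index[:, 2]] for v in vols]
    )
    K_wb = _svm.linear_kernel(X_wb)

    candidates = merged_region_names(atlas) if opts.merge_lr else sorted(atlas.names.values())
    blocks = [(primary, r) for r in candidates]
    if opts.mode == "multimodal":
        blocks += list(opts.extra_blocks)
    X_region: dict[tuple[str, str], np.ndarray] = {}
    K_region: dict[tuple[str, str], np.ndarray] = {}
    for modality, region in blocks:
        coords = region_voxel_index(atlas, region, opts.merge_lr)
        X = np.stack(
            [
                s.volumes[modality].data[coords[:, 0], coords[:, 1], coords[:, 2]]
                for s in subjects
            ]
        )
        X_region[(modality, region)] = X
        K_region[(modality, region)] = _svm.linear_kernel(X)

    return PipelinePrecomp(
        ids=[s.id for s in subjects],
        diagnoses=np.array([s.diagnosis for s in subjects]),
        atlas=atlas,
        opts=opts,
        mask=mask,
        wb_index=wb_index,
        X_wb=X_wb,
        K_wb=K_wb,
        candidate_regions=candidates,
        X_region=X_region,
        K_region=K_region,
    )


def _select_regions_for_fold(
    pre: PipelinePrecomp, tr: np.ndarray, y_sel: np.ndarray
) -> list[str]:
    """Whole-brain linear SVM on the training part -> |w| -> top-k regions."""
    opts = pre.opts
    model = _svm.train_svm(
        pre.K_wb[np.ix_(tr, tr)], y_sel, opts.selection_C, check_kernel=False
    )
    wmap = voxel_weight_map(
        model,
        pre.X_wb[tr],
        pre.wb_index,
        pre.atlas.labels.shape,
        affine=pre.atlas.affine,
        normalize=True,
    )
    rw = region_weights(wmap, pre.atlas, pre.candidate_regions, opts.merge_lr)
    return select_top_regions(rw, opts.top_regions)


def _fit_predict_binary(
    pre: PipelinePrecomp,
    blocks: list[tuple[str, str]],
    tr: np.ndarray,
    te: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Grid search + final MKL fit on tr; decision values on te."""
    Ks = np.stack([pre.K_region[b] for b in blocks])
    C, q, _ = grid_search_kernels(Ks[:, tr][:, :, tr], y[tr], pre.opts.grid, seed)
    K_tr = np.tensordot(q, Ks[:, tr][:, :, tr], axes=1)
    model = _svm.train_svm(K_tr, y[tr], C, check_kernel=False)
    K_te = np.tensordot(q, Ks[:, te][:, :, tr], axes=1)
    g = _svm.decision_values(model, K_te)
    return C, q, g


def run_cv_pipeline(
    subjects: list[SubjectRecord],
    atlas: Atlas,
    opts: EvalOptions | None = None,
    labels: Sequence[str] | None = None,
) -> CVReport:
    """The full cross-validated experiment; see the module docstring.

    ``labels`` optionally overrides the subjects' diagnoses (used by the
    permutation test); it must use the same PD/MSA/PSP vocabulary.
    """
    opts = opts or EvalOptions()
    pre = prepare_pipeline(subjects, atlas, opts)
    return run_cv_from_precomp(pre, labels)


def run_cv_from_precomp(
    pre: PipelinePrecomp, labels: Sequence[str] | None = None
) -> CVReport:
    opts = pre.opts
    diagnoses = pre.diagnoses if labels is None else np.asarray(labels)
    if diagnoses.size != len(pre.ids):
        raise ValueError("labels length mismatch")
    multiclass = opts.mode == "multiclass"
    # binary task: idiopathic PD vs pooled atypical (MSA u PSP)
    y_bin = np.where(diagnoses == "PD", -1.0, 1.0)
    strat = diagnoses if multiclass else y_bin
    classes = sorted(np.unique(diagnoses).tolist()) if multiclass else [
        BINARY_NEGATIVE,
        BINARY_POSITIVE,
    ]
    assign = stratified_kfold(strat, k=opts.k, seed=opts.seed)

    folds: list[FoldResult] = []
    for f in range(opts.k):
        te = assign == f
        tr = ~te
        if np.unique(strat[tr]).size < 2:
            raise ValueError(f"fold {f}: training partition has a single class")
        # region selection always uses the idiopathic-vs-atypical contrast
        selected = _select_regions_for_fold(pre, tr, y_bin[tr])
        blocks = [(opts.primary_modality, r) for r in selected]
        if opts.mode == "multimodal":
            blocks += list(opts.extra_blocks)

        if not multiclass:
            C, q, g = _fit_predict_binary(pre, blocks, tr, te, y_bin, opts.seed + f)
            y_pred = [BINARY_POSITIVE if gi >= 0 else BINARY_NEGATIVE for gi in g]
            folds.append(
                FoldResult(
                    fold=f,
                    test_ids=[pre.ids[i] for i in np.flatnonzero(te)],
                    y_true=[binary_label(d) for d in diagnoses[te]],
                    y_pred=y_pred,
                    decision=[float(x) for x in g],
                    selected_regions=selected,
                    C=C,
                    q=list(np.round(q, 12)),
                )
            )
        else:
            Ks = np.stack([pre.K_region[b] for b in blocks])
            votes = {c: np.zeros(int(te.sum())) for c in classes}
            strength = {c: np.zeros(int(te.sum())) for c in classes}
            C_pairs: dict[str, float] = {}
            q_pairs: dict[str, list] = {}
            for a, b in itertools.combinations(classes, 2):
                pair_tr = tr & ((diagnoses == a) | (diagnoses == b))
                y_pair = np.where(diagnoses == b, 1.0, -1.0)
                C, q, g = _fit_predict_binary(
                    pre, blocks, pair_tr, te, y_pair, opts.seed + f
                )
                winners = np.where(g >= 0, b, a)
                for c in (a, b):
                    won = winners == c
                    votes[c][won] += 1
                    strength[c][won] += np.abs(g[won])
                C_pairs[f"{a}|{b}"] = C
                q_pairs[f"{a}|{b}"] = list(np.round(q, 12))
            y_pred = []
            for i in range(int(te.sum())):
                y_pred.append(
                    max(
                        classes,
                        key=lambda c: (votes[c][i], strength[c][i], -classes.index(c)),
                    )
                )
            folds.append(
                FoldResult(
                    fold=f,
                    test_ids=[pre.ids[i] for i in np.flatnonzero(te)],
                    y_true=list(diagnoses[te]),
                    y_pred=y_pred,
                    decision=None,
                    selected_regions=selected,
                    C=C_pairs,
                    q=q_pairs,
                )
            )
    return CVReport(
        mode=opts.mode,
        classes=classes,
        positive_class=None if multiclass else BINARY_POSITIVE,
        folds=folds,
    )


def cv_accuracy_closure(
    subjects: list[SubjectRecord], atlas: Atlas, opts: EvalOptions
) -> Callable[[Sequence[str], int], float]:
    """Accuracy of the full pipeline as a function of the label vector.

    Features and Gram matrices are computed once (they do not depend on the
    labels); each call re-runs region selection, grid search, training and
    prediction under the given labels.  Intended for the permutation test.
    """
    pre = prepare_pipeline(subjects, atlas, opts)

    def accuracy(labels: Sequence[str], seed: int = 0) -> float:  # noqa: ARG001
        return run_cv_from_precomp(pre, labels).accuracy

    return accuracy


# ---------------------------------------------------------------------------
# permutation test

@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int


def permutation_test(
    accuracy_fn: Callable[[Sequence, int], float],
    labels: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
    plus_one: bool = False,
) -> PermutationResult:
    """Significance of an accuracy by random relabeling.

    ``accuracy_fn(labels, seed)`` must re-run the full procedure under the
    given label vector.  The p-value is the plain fraction of null
    accuracies >= the observed one; with ``plus_one`` the (b+1)/(m+1)
    estimator is used instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = accuracy_fn(labels, 0)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = accuracy_fn(rng.permutation(labels), b + 1)
    b_ge = int(np.sum(null >= observed))
    p = (b_ge + 1) / (n_perm + 1) if plus_one else b_ge / n_perm
    return PermutationResult(observed=observed, null=null, p_value=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# ROC

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence, positive_class) -> ROCCurve:
    """ROC over all distinct score thresholds; AUC by the trapezoid rule.

    With ties the AUC equals the Mann-Whitney statistic counting ties as
    one half.
    """
    from sklearn import metrics as skm

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    y = labels == positive_class
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = skm.roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# voxelwise two-sample t-map

@dataclass
class TMap:
    t: Volume
    z: Volume
    df: int
    p_thresh: float
    clusters: pd.DataFrame
    zero_variance: np.ndarray


def voxelwise_ttest(
    group_a: list[Volume],
    group_b: list[Volume],
    p_thresh: float = 0.001,
) -> TMap:
    """Pooled-variance two-sample t per voxel (A minus B), df = n1 + n2 - 2.

    Voxels beyond the one-sided p threshold (either direction) are grouped
    into 26-connected clusters; the table lists voxel count, volume in mm^3,
    peak |t| and peak z per cluster.  Inputs are expected pre-smoothed.
    Zero-pooled-variance voxels get t = 0 and are flagged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two volumes per group")
    shapes = {v.shape for v in group_a + group_b}
    if len(shapes) != 1:
        raise ValueError("all volumes must share one grid")
    A = np.stack([v.data for v in group_a])
    B = np.stack([v.data for v in group_b])
    n1, n2 = A.shape[0], B.shape[0]
    df = n1 + n2 - 2
    m1, m2 = A.mean(axis=0), B.mean(axis=0)
    v1 = A.var(axis=0, ddof=1)
    v2 = B.var(axis=0, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    zero_var = denom == 0
    t = np.zeros_like(m1)
    np.divide(m1 - m2, denom, out=t, where=~zero_var)

    # one-sided tail mapping to z, per direction (directional contrasts)
    sf = stats.t.sf(np.abs(t), df)
    sf = np.maximum(sf, 1e-300)
    z = np.sign(t) * stats.norm.isf(sf)
    z[zero_var] = 0.0

    t_crit = stats.t.isf(p_thresh, df)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    vox_vol = float(np.prod(group_a[0].voxel_size))
    rows = []
    cid = 0
    for sign, supra in (("+", t > t_crit), ("-", t < -t_crit)):
        labeled, n_clusters = ndi.label(supra, structure=structure)
        for lab in range(1, n_clusters + 1):
            sel = labeled == lab
            cid += 1
            tvals = t[sel]
            zvals = z[sel]
            peak = np.argmax(np.abs(tvals))
            rows.append(
                {
                    "cluster": cid,
                    "sign": sign,
                    "n_voxels": int(sel.sum()),
                    "volume_mm3": float(sel.sum() * vox_vol),
                    "peak_t": float(tvals[peak]),
                    "peak_z": float(zvals[peak]),
                }
            )
    clusters = pd.DataFrame(
        rows, columns=["cluster", "sign", "n_voxels", "volume_mm3", "peak_t", "peak_z"]
    )
    aff = group_a[0].affine
    return TMap(
        t=Volume(t, affine=aff),
        z=Volume(z, affine=aff),
        df=df,
        p_thresh=p_thresh,
        clusters=clusters,
        zero_variance=zero_var,
    )
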