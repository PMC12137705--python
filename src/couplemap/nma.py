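"""Node-measure-assignment (NMA) prediction of a phenotype from coupling.

The Basic NMA model (B-NMA) predicts a phenotype from one condition's
region-specific coupling values: in the training folds, each region's four
coupling measures are partially correlated with the phenotype (controlling
for age, gender, handedness and condition-specific motion), yielding r_P per
region x measure; the measure with the most positive r_P defines the positive
assignment mask, the most negative the negative mask.  Each participant then
contributes two features -- the mean coupling over regions under the positive
mask (X1) and under the negative mask (X2) -- and the phenotype is fit by
ordinary least squares y = b0 + b1*X1 + b2*X2.  Prediction runs in k-fold
cross-validation, masks and coefficients always estimated on training folds
only; performance is the Pearson correlation between fold-concatenated
predictions and observed scores, averaged over repetitions with fresh fold
splits.  The Expanded NMA model (E-NMA) builds the two features per task
condition (resting state excluded) and fits one regression on all of them.

Significance comes from phenotype-permutation tests; model comparisons from
shared-permutation differences in performance; out-of-sample generalization
from freezing every trained fold model and applying it to a replication
cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .association import partial_correlation_matrix
from .coupling import CouplingTable
from .datatypes import AnalysisConfig, ParticipantTable, ValidationError

__all__ = [
    "NMAMask",
    "PredictionResult",
    "build_nma_mask",
    "extract_features",
    "fit_predict_bnma",
    "fit_predict_enma",
    "permutation_test",
    "model_difference_test",
    "cross_sample_generalize",
]

log = logging.getLogger("couplemap")


@dataclass
class NMAMask:
    """Per-region assignment of one coupling measure, for one condition.

    ``positive[i]``/``negative[i]`` index the measure with the most
    positive/negative training-sample phenotype association r_P in region i.
    Regions where no association of the required sign exists keep the
    argmax/argmin assignment but are flagged.
    """

    condition: str
    positive: np.ndarray
    negative: np.ndarray
    r_P: np.ndarray
    measures: list[str] = field(default_factory=list)
    flagged_positive: np.ndarray | None = None
    flagged_negative: np.ndarray | None = None


def build_nma_mask(
    coupling: np.ndarray,
    g: np.ndarray,
    Z: np.ndarray | None,
    condition: str = "NA",
    measures: list[str] | None = None,
) -> NMAMask:
    """Construct the positive/negative assignment masks from training data.

    ``coupling`` is the (n_train, n_regions, n_measures) slice for one
    condition.  Ties are broken by measure order; degenerate coupling cells
    get r_P = 0.
    """
    n, n_regions, n_meas = coupling.shape
    rP = partial_correlation_matrix(
        coupling.reshape(n, n_regions * n_meas), g, Z
    ).reshape(n_regions, n_meas)
    pos = np.argmax(rP, axis=1)
    neg = np.argmin(rP, axis=1)
    idx = np.arange(n_regions)
    flag_pos = rP[idx, pos] <= 0
    flag_neg = rP[idx, neg] >= 0
    if flag_pos.any() or flag_neg.any():
        log.info(
            "condition %s: %d region(s) without positive and %d without negative "
            "association; argmax/argmin convention applied",
            condition, int(flag_pos.sum()), int(flag_neg.sum()),
        )
    return NMAMask(condition, pos, neg, rP,
                   measures=list(measures or []),
                   flagged_positive=flag_pos, flagged_negative=flag_neg)


def extract_features(mask: NMAMask, coupling: np.ndarray) -> np.ndarray:
    """Per-participant feature pair (X1, X2) from a coupling slice.

    X1 is the mean over regions of each participant's coupling under the
    positive mask, X2 the same under the negative mask.  ``coupling`` is
    (n, n_regions, n_measures); returns (n, 2).
    """
    idx = np.arange(coupling.shape[1])
    x1 = coupling[:, idx, mask.positive].mean(axis=1)
    x2 = coupling[:, idx, mask.negative].mean(axis=1)
    return np.column_stack([x1, x2])


@dataclass
class PredictionResult:
    """Cross-validated prediction performance of one NMA model.

    ``r`` is the mean over repetitions of the Pearson correlation between
    fold-concatenated predicted and observed scores; ``R2 = r**2`` and
    ``R2_mean_per_rep`` the mean per-repetition squared correlation are both
    reported.  ``p`` is filled in by :func:`permutation_test`.
    """

    model: str
    condition: str | None
    r: float
    R2: float
    R2_mean_per_rep: float
    per_repetition_r: np.ndarray
    seed: int
    n_repetitions: int
    p: float | None = None


# ---------------------------------------------------------------------------
# cross-validation internals
#
# Fold "contexts" precompute everything that does not depend on the phenotype:
# the orthonormal covariate bases per condition and the residualized,
# normalized coupling columns used for mask building.  A permutation run then
# only residualizes the shuffled phenotype and re-derives masks/coefficients,
# which keeps 1000-permutation protocols tractable.

@dataclass
class _FoldContext:
    train: np.ndarray
    test: np.ndarray
    q: dict[str, np.ndarray]          # per condition: orthonormal [1, Z] basis
    xnorm: dict[str, np.ndarray]      # per condition: residualized unit coupling cols
    c_train: dict[str, np.ndarray]    # per condition: raw coupling (train)
    c_test: dict[str, np.ndarray]


def _fold_splits(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    if n < n_folds * 3:
        raise ValidationError(
            f"cannot form {n_folds} folds with >= 3 participants each from n={n}"
        )
    return np.array_split(rng.permutation(n), n_folds)


def _build_contexts(
    C: dict[str, np.ndarray],
    Z: dict[str, np.ndarray],
    n: int,
    cfg: AnalysisConfig,
    n_repetitions: int,
    seed: int,
) -> list[list[_FoldContext]]:
    ss = np.random.SeedSequence([seed, 101])
    contexts: list[list[_FoldContext]] = []
    for rep_seed in ss.spawn(n_repetitions):
        rng = np.random.default_rng(rep_seed)
        folds = _fold_splits(n, cfg.n_folds, rng)
        rep_ctx = []
        for fi in range(cfg.n_folds):
            test = np.sort(folds[fi])
            train = np.sort(np.concatenate(
                [folds[j] for j in range(cfg.n_folds) if j != fi]
            ))
            q, xnorm, ctr, cte = {}, {}, {}, {}
            for cond, cc in C.items():
                design = np.column_stack([np.ones(len(train)), Z[cond][train]])
                qq, _ = np.linalg.qr(design)
                ct = cc[train]
                flat = ct.reshape(len(train), -1)
                resid = flat - qq @ (qq.T @ flat)
                norms = np.linalg.norm(resid, axis=0)
                resid /= np.where(norms == 0, 1.0, norms)
                resid[:, norms == 0] = 0.0
                q[cond], xnorm[cond] = qq, resid
                ctr[cond], cte[cond] = ct, cc[test]
            rep_ctx.append(_FoldContext(train, test, q, xnorm, ctr, cte))
        contexts.append(rep_ctx)
    return contexts


def _fold_fit_predict(
    ctx: _FoldContext, g: np.ndarray, conditions: list[str]
) -> tuple[np.ndarray, list[NMAMask], np.ndarray]:
    """Masks + OLS on the training fold, predictions for the test fold."""
    gtr = g[ctx.train]
    feats_tr, feats_te, masks = [], [], []
    n_regions = next(iter(ctx.c_train.values())).shape[1]
    idx = np.arange(n_regions)
    for cond in conditions:
        qq = ctx.q[cond]
        gres = gtr - qq @ (qq.T @ gtr)
        gn = np.linalg.norm(gres)
        gres = gres / gn if gn > 0 else gres
        rP = (ctx.xnorm[cond].T @ gres).reshape(n_regions, -1)
        pos = np.argmax(rP, axis=1)
        neg = np.argmin(rP, axis=1)
        masks.append(NMAMask(cond, pos, neg, rP))
        ctr, cte = ctx.c_train[cond], ctx.c_test[cond]
        feats_tr.append(ctr[:, idx, pos].mean(axis=1))
        feats_tr.append(ctr[:, idx, neg].mean(axis=1))
        feats_te.append(cte[:, idx, pos].mean(axis=1))
        feats_te.append(cte[:, idx, neg].mean(axis=1))
    Xtr = np.column_stack([np.ones(len(ctx.train))] + feats_tr)
    if Xtr.shape[1] >= Xtr.shape[0]:
        raise ValidationError(
            f"{Xtr.shape[1] - 1} features saturate a training fold of "
            f"{Xtr.shape[0]} participants"
        )
    gram = Xtr.T @ Xtr
    try:
        beta = np.linalg.solve(gram, Xtr.T @ gtr)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(Xtr, gtr, rcond=None)
    Xte = np.column_stack([np.ones(len(ctx.test))] + feats_te)
    return Xte @ beta, masks, beta


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _run_cv(
    contexts: list[list[_FoldContext]],
    g: np.ndarray,
    conditions: list[str],
) -> np.ndarray:
    """Per-repetition prediction r for a fixed phenotype vector."""
    n = len(g)
    per_rep = np.empty(len(contexts))
    for ri, rep_ctx in enumerate(contexts):
        pred = np.empty(n)
        for ctx in rep_ctx:
            pred[ctx.test] = _fold_fit_predict(ctx, g, conditions)[0]
        per_rep[ri] = _pearson(pred, g)
    return per_rep


def _prepare(
    table: CouplingTable,
    participants: ParticipantTable,
    conditions: list[str],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    sub = participants.subset(table.participants)
    C = {c: table.condition_slice(c) for c in conditions}
    Z = {c: sub.covariates(c) for c in conditions}
    return C, Z, sub.g


def _fit_predict(
    table: CouplingTable,
    participants: ParticipantTable,
    conditions: list[str],
    cfg: AnalysisConfig,
    model: str,
    n_repetitions: int | None = None,
) -> PredictionResult:
    n_reps = n_repetitions or cfg.n_repetitions
    C, Z, g = _prepare(table, participants, conditions)
    contexts = _build_contexts(C, Z, len(g), cfg, n_reps, cfg.rng_seed)
    per_rep = _run_cv(contexts, g, conditions)
    r = float(per_rep.mean())
    return PredictionResult(
        model=model,
        condition=conditions[0] if model == "B-NMA" else None,
        r=r, R2=r**2, R2_mean_per_rep=float(np.mean(per_rep**2)),
        per_repetition_r=per_rep, seed=cfg.rng_seed, n_repetitions=n_reps,
    )


def fit_predict_bnma(
    table: CouplingTable,
    participants: ParticipantTable,
    condition: str,
    cfg: AnalysisConfig | None = None,
    n_repetitions: int | None = None,
) -> PredictionResult:
    """Cross-validated Basic NMA prediction from one condition's coupling."""
    cfg = cfg or AnalysisConfig()
    if condition not in table.conditions:
        raise ValidationError(f"condition {condition!r} not in coupling table")
    return _fit_predict(table, participants, [condition], cfg, "B-NMA",
                        n_repetitions)


def fit_predict_enma(
    table: CouplingTable,
    participants: ParticipantTable,
    cfg: AnalysisConfig | None = None,
    conditions: list[str] | None = None,
    n_repetitions: int | None = None,
) -> PredictionResult:
    """Cross-validated Expanded NMA prediction from task-combined coupling.

    Uses two features per task condition (resting state excluded by default)
    in a single regression.
    """
    cfg = cfg or AnalysisConfig()
    if conditions is None:
        conditions = [c for c in table.conditions if c != cfg.rest_condition]
    if not conditions:
        raise ValidationError("E-NMA needs at least one task condition")
    return _fit_predict(table, participants, list(conditions), cfg, "E-NMA",
                        n_repetitions)


def _model_conditions(result: PredictionResult, table: CouplingTable,
                      cfg: AnalysisConfig) -> list[str]:
    if result.model == "B-NMA":
        return [result.condition]
    return [c for c in table.conditions if c != cfg.rest_condition]


def permutation_test(
    result: PredictionResult,
    table: CouplingTable,
    participants: ParticipantTable,
    cfg: AnalysisConfig | None = None,
    n_permutations: int | None = None,
) -> float:
    """Phenotype-permutation significance of a prediction result.

    Phenotype scores are shuffled across participants (covariates stay
    attached to the imaging data, preserving the confound structure under the
    null); the full cross-validation pipeline is re-run per permutation with
    the reduced repetition count ``cfg.perm_repetitions`` and the same fold
    scheme.  p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).  Sets ``result.p``.
    """
    cfg = cfg or AnalysisConfig()
    n_perm = n_permutations or cfg.n_permutations
    conditions = _model_conditions(result, table, cfg)
    C, Z, g = _prepare(table, participants, conditions)
    contexts = _build_contexts(C, Z, len(g), cfg, cfg.perm_repetitions,
                               cfg.rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 202]))
    exceed = 0
    for _ in range(n_perm):
        g_perm = rng.permutation(g)
        r_perm = float(_run_cv(contexts, g_perm, conditions).mean())
        if r_perm >= result.r:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    result.p = p
    return p


def model_difference_test(
    result_a: PredictionResult,
    result_b: PredictionResult,
    table: CouplingTable,
    participants: ParticipantTable,
    cfg: AnalysisConfig | None = None,
    n_permutations: int | None = None,
) -> float:
    """Permutation test of the performance difference between two models.

    |delta r| observed is compared against |delta r| when both models are
    trained on the same permuted phenotype; both models share each
    permutation's shuffle.  Requires both results to come from the same
    cohort.
    """
    cfg = cfg or AnalysisConfig()
    n_perm = n_permutations or cfg.n_permutations
    conds_a = _model_conditions(result_a, table, cfg)
    conds_b = _model_conditions(result_b, table, cfg)
    all_conds = sorted(set(conds_a) | set(conds_b),
                       key=lambda c: table.conditions.index(c))
    C, Z, g = _prepare(table, participants, all_conds)
    contexts = _build_contexts(C, Z, len(g), cfg, cfg.perm_repetitions,
                               cfg.rng_seed)
    d_obs = abs(result_a.r - result_b.r)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 303]))
    exceed = 0
    for _ in range(n_perm):
        g_perm = rng.permutation(g)
        ra = float(_run_cv(contexts, g_perm, conds_a).mean())
        rb = float(_run_cv(contexts, g_perm, conds_b).mean())
        if abs(ra - rb) >= d_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def cross_sample_generalize(
    main_table: CouplingTable,
    main_participants: ParticipantTable,
    repl_table: CouplingTable,
    repl_participants: ParticipantTable,
    model: str = "B-NMA",
    condition: str | None = None,
    cfg: AnalysisConfig | None = None,
    n_repetitions: int | None = None,
    n_permutations: int | None = None,
) -> PredictionResult:
    """Apply frozen main-sample models to an independent replication cohort.

    For every repetition's training-test split of the main sample, the model
    (masks + coefficients) trained on each 4/5-fold training set is frozen
    and applied to the full replication cohort; performance per model is the
    Pearson correlation between predicted and observed replication scores,
    and the reported r is the mean over all n_folds x n_repetitions models.
    Significance permutes the replication phenotype against the frozen
    predictions.
    """
    cfg = cfg or AnalysisConfig()
    n_reps = n_repetitions or cfg.n_repetitions
    if model == "B-NMA":
        if condition is None:
            raise ValidationError("B-NMA generalization needs a condition")
        conditions = [condition]
    else:
        conditions = [c for c in main_table.conditions if c != cfg.rest_condition]
    missing = [c for c in conditions if c not in repl_table.conditions]
    if missing:
        raise ValidationError(
            f"replication cohort lacks condition(s) {missing}; model skipped"
        )
    C, Z, g = _prepare(main_table, main_participants, conditions)
    contexts = _build_contexts(C, Z, len(g), cfg, n_reps, cfg.rng_seed)
    repl_sub = repl_participants.subset(repl_table.participants)
    g_repl = repl_sub.g
    C_repl = {c: repl_table.condition_slice(c) for c in conditions}
    idx = np.arange(main_table.n_regions)
    preds = []
    for rep_ctx in contexts:
        for ctx in rep_ctx:
            _, masks, beta = _fold_fit_predict(ctx, g, conditions)
            feats = []
            for mask, cond in zip(masks, conditions):
                cc = C_repl[cond]
                feats.append(cc[:, idx, mask.positive].mean(axis=1))
                feats.append(cc[:, idx, mask.negative].mean(axis=1))
            X = np.column_stack([np.ones(len(g_repl))] + feats)
            preds.append(X @ beta)
    pred_matrix = np.asarray(preds)  # (models, n_repl)
    per_model_r = np.array([_pearson(p, g_repl) for p in pred_matrix])
    r = float(per_model_r.mean())
    res = PredictionResult(
        model=f"{model}-transfer", condition=condition, r=r, R2=r**2,
        R2_mean_per_rep=float(np.mean(per_model_r**2)),
        per_repetition_r=per_model_r, seed=cfg.rng_seed, n_repetitions=n_reps,
    )
    n_perm = n_permutations if n_permutations is not None else cfg.n_permutations
    if n_perm:
        # vectorized: standardize predictions once, correlate with shuffles
        pm = pred_matrix - pred_matrix.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(pm, axis=1)
        pm = pm / np.where(norms == 0, 1.0, norms)[:, None]
        rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 404]))
        exceed = 0
        for _ in range(n_perm):
            gp = rng.permutation(g_repl)
            gp = gp - gp.mean()
            gp /= np.linalg.norm(gp)
            if float((pm @ gp).mean()) >= r:
                exceed += 1
        res.p = (1 + exceed) / (1 + n_perm)
    return res
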