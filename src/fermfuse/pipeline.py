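"""End-to-end orchestration of the fusion-monitoring study.

The workflow mirrors the intermediate-level fusion architecture: each
modality is preprocessed to its characteristic-value matrix and
compressed by PCA; the per-modality PC counts are picked by
leave-one-out cross-validation of the boosted classifier at the first
local maximum of the identification-rate curve; the selected PC blocks
are concatenated and unmixed by ICA, whose component count is selected
the same way; finally boosted ensembles are trained for the
e-nose-only, NIRS-only and fused feature sets and evaluated on the
run-based train/validation split (runs 1-3 train, run 4 validation
under the default four-run design, i.e. a 105/35 split).

Feature extraction (standardization, PCA, ICA) is fitted on training
rows only; validation rows are always projected with training
statistics.  Within the LOOCV loop only the classifier is refitted per
fold by default — the component scores are computed once from the full
training block — matching the component-selection procedure this
toolkit models.  ``RunConfig(strict_loocv=True)`` additionally refits
the decomposition stage (standardization + PCA, or ICA for the fused
branch) on each fold's remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .bp_adaboost import (
    BPNetConfig,
    StrongPredictor,
    UNASSIGNED,
    predict,
    train_ensemble,
)
from .containers import FeatureMatrix
from .decomposition import concat_features, fit_ica, fit_pca, project_pca, transform_ica
from .preprocessing import enose_feature_matrix, spectra_feature_matrix, standardize
from .synthetic_data import StudyConfig, generate_study

__all__ = [
    "split_by_run",
    "loocv_rate",
    "select_components",
    "SelectionCurve",
    "EvaluationReport",
    "evaluate",
    "format_rate",
    "run_study",
]


def split_by_run(manifest: pd.DataFrame, train_runs=(1, 2, 3)) -> tuple[list, list]:
    """Partition sample ids by fermentation run.

    Samples whose run is in ``train_runs`` form the training set, all
    others the validation set.  Under the default 4-run design this is
    the 105/35 split.  Unknown run ids raise; an empty validation set
    draws a warning.
    """
    runs = set(manifest["run"])
    unknown = set(train_runs) - runs
    if unknown:
        raise ValueError(f"unknown run id(s) {sorted(unknown)}; present: {sorted(runs)}")
    is_train = manifest["run"].isin(set(train_runs))
    train_ids = manifest.loc[is_train, "sample_id"].tolist()
    val_ids = manifest.loc[~is_train, "sample_id"].tolist()
    if not val_ids:
        warnings.warn("validation set is empty: every run is a training run", UserWarning)
    return train_ids, val_ids


def loocv_rate(
    features,
    days,
    cfg: BPNetConfig | None = None,
    T: int = 10,
    seed: int = 0,
    classes=None,
    refit=None,
) -> float:
    """Leave-one-out identification rate (%) of the boosted classifier.

    Each training sample is held out in turn, an ensemble is trained on
    the remainder (with a per-fold seed substream), and the held-out
    sample is identified; the rate is 100 * correct / m.  UNASSIGNED
    predictions count as errors.  A fold whose remainder lacks a class
    draws a warning and counts as an error.

    ``refit``, if given, is a callable ``(rest_indices, held_index) ->
    (X_rest, x_held)`` that re-derives the feature representation from
    scratch on each fold's remainder (strict mode); by default the
    supplied feature matrix is used as-is for every fold.
    """
    X = features.to_numpy() if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    days = np.asarray(days)
    m = X.shape[0]
    if m < 2:
        raise ValueError("leave-one-out needs at least two samples")
    if classes is None:
        classes = np.unique(days)
    correct = 0
    mask = np.ones(m, dtype=bool)
    for i in range(m):
        mask[i] = False
        rest_days = days[mask]
        if len(np.unique(rest_days)) < 2:
            warnings.warn(f"fold {i}: fewer than two classes remain; counted as error")
            mask[i] = True
            continue
        if refit is not None:
            X_rest, x_held = refit(np.flatnonzero(mask), i)
        else:
            X_rest, x_held = X[mask], X[i]
        fold_classes = classes[np.isin(classes, rest_days)]
        strong = train_ensemble(
            X_rest, rest_days, cfg=cfg, T=T, classes=fold_classes,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
        )
        label, _ = predict(strong, x_held)
        correct += int(label[0] == days[i])
        mask[i] = True
    return 100.0 * correct / m


@dataclass
class SelectionCurve:
    """LOOCV identification rate per candidate component count."""

    candidates: list[int]
    rates: list[float]
    chosen: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_components": self.candidates, "loocv_rate": self.rates,
             "chosen": [c == self.chosen for c in self.candidates]}
        )


def select_components(curve_fn, candidates, full_curve: bool = False) -> SelectionCurve:
    """Pick the component count at the first local maximum of the rate curve.

    The chosen count is the smallest candidate whose rate strictly
    exceeds its predecessor's (the rate before the first candidate is
    -inf, so the first candidate qualifies on that side) and is >= its
    successor's (the rate after the last is -inf).  On a strictly
    increasing curve this degenerates to the global maximum at the last
    candidate.

    Because the rule is sequential, the curve is evaluated lazily: once
    a local maximum is confirmed by its successor, larger candidates
    are never costed.  Pass ``full_curve=True`` to evaluate every
    candidate anyway (e.g. to plot the whole selection curve); the
    chosen count is identical either way.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if sorted(candidates) != candidates:
        raise ValueError("candidates must be sorted ascending")
    rates: dict[int, float] = {}

    def rate(i: int) -> float:
        if i not in rates:
            rates[i] = float(curve_fn(candidates[i]))
        return rates[i]

    chosen = None
    for i in range(len(candidates)):
        prev = rate(i - 1) if i > 0 else -np.inf
        nxt = rate(i + 1) if i + 1 < len(candidates) else -np.inf
        if rate(i) > prev and rate(i) >= nxt:
            chosen = candidates[i]
            break
    if chosen is None:  # no local max: fall back to the global maximum
        chosen = candidates[int(np.argmax([rate(i) for i in range(len(candidates))]))]
    if full_curve:
        for i in range(len(candidates)):
            rate(i)
    evaluated = sorted(rates)
    return SelectionCurve(
        [candidates[i] for i in evaluated], [rates[i] for i in evaluated], chosen
    )


def format_rate(correct: int, total: int) -> float:
    """Identification rate 100*correct/total rounded half-up to 2 decimals."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(100) * Decimal(correct) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class EvaluationReport:
    """Confusion matrix (+ UNASSIGNED bucket) and identification rates."""

    confusion: pd.DataFrame          # classes x (classes + UNASSIGNED)
    per_class_rate: pd.Series        # %, rounded half-up to 2 dp
    overall_rate: float              # %, rounded half-up to 2 dp
    overall_rate_exact: float        # full precision
    n_correct: int
    n_total: int
    model: dict = field(default_factory=dict)


def evaluate(strong: StrongPredictor, features, days, model_info=None) -> EvaluationReport:
    """Confusion matrix and identification rates of a fitted ensemble.

    The confusion matrix has one row per true class and an extra
    UNASSIGNED column for cutoff failures, which count as
    misclassifications in every rate.  Rates are reported rounded
    half-up to two decimals; the exact overall rate is retained.
    """
    X = features.to_numpy() if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    days = np.asarray(days)
    labels, _ = predict(strong, X)
    classes = list(strong.classes)
    cols = classes + ["UNASSIGNED"]
    conf = pd.DataFrame(0, index=classes, columns=cols)
    for truth, pred in zip(days, labels):
        conf.loc[truth, "UNASSIGNED" if pred == UNASSIGNED else pred] += 1
    per_class = pd.Series(
        {
            c: format_rate(int(conf.loc[c, c]), int(conf.loc[c].sum()))
            for c in classes
        }
    )
    n_correct = int(np.trace(conf.loc[classes, classes].to_numpy()))
    n_total = len(days)
    return EvaluationReport(
        confusion=conf,
        per_class_rate=per_class,
        overall_rate=format_rate(n_correct, n_total),
        overall_rate_exact=100.0 * n_correct / n_total,
        n_correct=n_correct,
        n_total=n_total,
        model=dict(model_info or {}),
    )


@dataclass
class RunConfig:
    """Configuration of a full comparison study."""

    study: StudyConfig = field(default_factory=lambda: StudyConfig.split_study())
    train_runs: tuple = (1, 2, 3)
    bp: BPNetConfig = field(default_factory=BPNetConfig)
    T: int = 10
    pc_candidates: tuple = tuple(range(1, 11))
    full_curves: bool = False
    strict_loocv: bool = False
    seed: int = 0


_MOD_TAG = {"enose": 1, "nirs": 2, "fusion": 3}


def _modality_branch(fm, train_ids, val_ids, days_train, cfg, name):
    """Standardize on training rows, fit PCA, LOOCV-select the PC count.

    The raw (eigenvalue-scaled) PC scores are kept for the fusion
    stage, where ICA needs the variance structure to order components;
    classifier inputs are column z-scored (training statistics) so
    every input is on a comparable scale.
    """
    std = standardize(fm, fit_rows=train_ids)
    train_block = std.rows(train_ids)
    max_k = min(len(train_ids) - 1, train_block.shape[1])
    candidates = [k for k in cfg.pc_candidates if k <= max_k]
    pca_full = fit_pca(train_block, k=max(candidates))
    raw_scores = project_pca(pca_full, std)
    z_scores = standardize(raw_scores, fit_rows=train_ids)

    loocv_seed = int(
        np.random.SeedSequence([cfg.seed, 90, _MOD_TAG[name]]).generate_state(1)[0] % 2**31
    )

    def rate_at(k):
        refit = None
        if cfg.strict_loocv:
            def refit(rest_idx, held_i, k=k):
                rest_ids = [train_ids[j] for j in rest_idx]
                std_f = standardize(fm, fit_rows=rest_ids)
                sc = standardize(
                    project_pca(fit_pca(std_f.rows(rest_ids), k=k), std_f),
                    fit_rows=rest_ids,
                )
                return (
                    sc.values.loc[rest_ids].to_numpy(),
                    sc.values.loc[train_ids[held_i]].to_numpy(),
                )
        cols = z_scores.values.columns[:k]
        return loocv_rate(
            z_scores.values.loc[train_ids, cols].to_numpy(),
            days_train, cfg=cfg.bp, T=cfg.T, seed=loocv_seed, refit=refit,
        )

    curve = select_components(rate_at, candidates, full_curve=cfg.full_curves)
    k = curve.chosen
    classifier_block = FeatureMatrix(z_scores.values.iloc[:, :k])
    # balance the fused block across modalities by each block's PC1
    # scale so neither instrument dominates the ICA by raw units
    pc1_sd = float(raw_scores.values.loc[train_ids].iloc[:, 0].std(ddof=1))
    fusion_block = FeatureMatrix(raw_scores.values.iloc[:, :k] / pc1_sd)
    return classifier_block, fusion_block, curve


def run_study(config: RunConfig | None = None) -> dict:
    """Run the full three-model comparison on a (synthetic) study.

    Generates the study, splits by run, builds the e-nose-only,
    NIRS-only and ICA-fused models with LOOCV-selected component
    counts, and evaluates each on the training and validation sets.

    Returns a JSON-serializable report with one row per model
    (modality, latent-vector count, training and validation ratios and
    rates), the selection curves, and both confusion matrices of the
    fused model.  Byte-identical across reruns at the same config.
    """
    cfg = config or RunConfig()
    manifest, recordings, spectra = generate_study(config=cfg.study)
    train_ids, val_ids = split_by_run(manifest, cfg.train_runs)
    day_of = dict(zip(manifest["sample_id"], manifest["day"]))
    days_train = np.array([day_of[s] for s in train_ids])
    days_val = np.array([day_of[s] for s in val_ids])

    fe = enose_feature_matrix(recordings)
    fn = spectra_feature_matrix(spectra)

    branches = {}
    fusion_blocks = {}
    curves = {}
    for name, fm in (("enose", fe), ("nirs", fn)):
        classifier_block, fusion_block, curve = _modality_branch(
            fm, train_ids, val_ids, days_train, cfg, name
        )
        branches[name] = classifier_block
        fusion_blocks[name] = fusion_block
        curves[name] = curve

    # fusion: concatenate the selected PC blocks and unmix with ICA.
    # Each candidate count n is a genuine n-component model: the fit
    # whitens to the top-n variance directions of the fused block and
    # rotates those, so low-variance residual dimensions never get
    # inflated into unit-variance distractors.
    fused_input = concat_features(fusion_blocks["enose"], fusion_blocks["nirs"])
    n_total = fused_input.shape[1]
    ica_seed = int(np.random.SeedSequence([cfg.seed, 91]).generate_state(1)[0] % 2**31)

    def ic_scores(n):
        model = fit_ica(fused_input.rows(train_ids), n_ics=n, seed=ica_seed)
        return standardize(transform_ica(model, fused_input), fit_rows=train_ids)

    ic_loocv_seed = int(np.random.SeedSequence([cfg.seed, 92]).generate_state(1)[0] % 2**31)

    def ic_rate(n):
        refit = None
        if cfg.strict_loocv:
            def refit(rest_idx, held_i, n=n):
                rest_ids = [train_ids[j] for j in rest_idx]
                model = fit_ica(fused_input.rows(rest_ids), n_ics=n, seed=ica_seed)
                sc = standardize(transform_ica(model, fused_input), fit_rows=rest_ids)
                return (
                    sc.values.loc[rest_ids].to_numpy(),
                    sc.values.loc[train_ids[held_i]].to_numpy(),
                )
        return loocv_rate(
            ic_scores(n).values.loc[train_ids].to_numpy(),
            days_train, cfg=cfg.bp, T=cfg.T, seed=ic_loocv_seed, refit=refit,
        )

    ic_curve = select_components(ic_rate, list(range(1, n_total + 1)), full_curve=cfg.full_curves)
    curves["fusion"] = ic_curve
    branches["fusion"] = ic_scores(ic_curve.chosen)

    report_rows = []
    evaluations = {}
    for name in ("nirs", "enose", "fusion"):
        feats = branches[name]
        final_seed = int(
            np.random.SeedSequence([cfg.seed, 93, _MOD_TAG[name]]).generate_state(1)[0] % 2**31
        )
        strong = train_ensemble(
            feats.values.loc[train_ids].to_numpy(), days_train,
            cfg=cfg.bp, T=cfg.T, classes=np.arange(cfg.study.design.n_days), seed=final_seed,
        )
        rep_train = evaluate(strong, feats.values.loc[train_ids].to_numpy(), days_train,
                             model_info={"modality": name, "set": "training"})
        rep_val = evaluate(strong, feats.values.loc[val_ids].to_numpy(), days_val,
                           model_info={"modality": name, "set": "validation"})
        evaluations[name] = {"training": rep_train, "validation": rep_val}
        report_rows.append(
            {
                "model": name,
                "latent_vectors": curves[name].chosen,
                "training_ratio": f"{rep_train.n_correct}/{rep_train.n_total}",
                "training_rate": rep_train.overall_rate,
                "validation_ratio": f"{rep_val.n_correct}/{rep_val.n_total}",
                "validation_rate": rep_val.overall_rate,
            }
        )

    return {
        "seed": cfg.seed,
        "n_samples": len(manifest),
        "n_train": len(train_ids),
        "n_validation": len(val_ids),
        "comparison": report_rows,
        "selection_curves": {
            name: {"candidates": c.candidates, "rates": c.rates, "chosen": c.chosen}
            for name, c in curves.items()
        },
        "fusion_confusion": {
            which: evaluations["fusion"][which].confusion.to_dict()
            for which in ("training", "validation")
        },
        "evaluations": evaluations,
    }


def report_json(report: dict) -> dict:
    """JSON-serializable view of a :func:`run_study` report.

    Evaluation objects are flattened to confusion dictionaries and
    rates; everything else is passed through.
    """
    out = {k: v for k, v in report.items() if k != "evaluations"}
    out["evaluations"] = {
        name: {
            which: {
                "confusion": {str(k): v for k, v in rep.confusion.to_dict().items()},
                "per_class_rate": {str(k): v for k, v in rep.per_class_rate.items()},
                "overall_rate": rep.overall_rate,
                "n_correct": rep.n_correct,
                "n_total": rep.n_total,
            }
            for which, rep in sets.items()
        }
        for name, sets in report["evaluations"].items()
    }
    out["fusion_confusion"] = {
        which: {str(k): v for k, v in conf.items()}
        for which, conf in report["fusion_confusion"].items()
    }
    return out
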