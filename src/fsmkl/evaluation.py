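"""Cross-validated evaluation protocol.

One fold's pipeline is strictly training-derived: the sample order is
shuffled once with the configured seed and cut into contiguous folds; within
each fold the clinical encoding schema, t-test feature ranking, pathway
matching, Gaussian bandwidths, trace constants and numeric standardization
are all computed on the training samples only, the MKL model is fitted (with
optional calibration and one round of ambiguous-label pruning), and the
held-out fold is scored either plainly or cautiously.  Corrupting held-out
rows therefore cannot change the trained fold model — an assertable
no-leakage guarantee.

Accuracy of a cautious run is reported on the predicted subset together with
its coverage; the two numbers are always co-reported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calibration import (calibrate_model, cautious_predict, remove_ambiguous)
from .data_io import (ClinicalTable, LabelVector, OmicsBlock,
                      PathwayCollection, encode_clinical)
from .kernel_bank import KernelBank, assemble_bank, project_bank
from .mkl_core import MklModel, fit_mkl, rank_kernels

__all__ = ["ExperimentConfig", "FoldFit", "CvResult", "fit_pipeline",
           "predict_pipeline", "cross_validate", "compare_configs",
           "aggregate_kernel_report"]


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; hashable for reproducibility stamps."""

    blocks: list[str] | None = None          # None = use every block given
    use_full_block: bool = False
    use_statistical: bool = False
    stat_n_max: int = 15
    use_pathway: bool = True
    within_pathway_top_k: int | None = None
    use_clinical: bool = False
    funcs: tuple[str, ...] = ("linear", "poly2", "poly3")
    clinical_funcs: tuple[str, ...] = ("linear",)
    C: float = 100.0
    mkl_tol: float = 1e-4
    mkl_max_iter: int = 200
    calibrate: bool = True
    smooth_targets: bool = True
    theta_train: float | None = None         # e.g. 0.8 to prune ambiguous labels
    theta_predict: float | None = None       # e.g. 0.95 for cautious prediction
    folds: int = 5
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.seed is None:
            raise ValueError("a seed must be recorded in the config")
        self.funcs = tuple(self.funcs)
        self.clinical_funcs = tuple(self.clinical_funcs)
        if self.blocks is not None:
            self.blocks = list(self.blocks)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["funcs"] = list(self.funcs)
        doc["clinical_funcs"] = list(self.clinical_funcs)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class FoldFit:
    """Everything needed to score held-out samples for one trained fold."""

    model: MklModel
    bank: KernelBank
    train_blocks: dict[str, OmicsBlock]      # includes "CLIN" when encoded
    clin_features: list[str] | None
    train_ids: list[str]


def _select_blocks(blocks: list[OmicsBlock],
                   config: ExperimentConfig) -> list[OmicsBlock]:
    if config.blocks is None:
        return list(blocks)
    by_name = {b.name: b for b in blocks}
    missing = [n for n in config.blocks if n not in by_name]
    if missing:
        raise KeyError(f"no block named {missing[0]!r}")
    return [by_name[n] for n in config.blocks]


def fit_pipeline(blocks: list[OmicsBlock], clinical: ClinicalTable | None,
                 pathways: PathwayCollection | None, labels: LabelVector,
                 config: ExperimentConfig,
                 train_ids: list[str] | None = None) -> FoldFit:
    """Train one model on ``train_ids`` (default: all labeled samples).

    Every data-dependent quantity is derived from the training rows alone.
    Applies, in order: bank construction, MKL fit, sigmoid calibration and —
    when ``theta_train`` is set — a single prune-and-refit round.
    """
    if train_ids is None:
        train_ids = list(labels.samples)
    train_ids = list(train_ids)

    def build(ids: list[str]) -> tuple[MklModel, KernelBank,
                                       dict[str, OmicsBlock], list[str] | None]:
        lab = labels.subset_samples(ids)
        lab.require_both_classes()
        used = [b.subset_samples(ids) for b in _select_blocks(blocks, config)]
        clin_block = None
        if config.use_clinical and clinical is not None:
            clin_block = encode_clinical(clinical.subset_samples(ids))
        bank = assemble_bank(
            used, lab, pathways=pathways, clinical_block=clin_block,
            use_full_block=config.use_full_block,
            use_statistical=config.use_statistical, n_max=config.stat_n_max,
            use_pathway=config.use_pathway,
            within_pathway_top_k=config.within_pathway_top_k,
            funcs=config.funcs, clinical_funcs=config.clinical_funcs)
        model = fit_mkl(bank, lab, C=config.C, tol=config.mkl_tol,
                        max_iter=config.mkl_max_iter)
        if config.calibrate or config.theta_train is not None \
                or config.theta_predict is not None:
            calibrate_model(model, bank, smooth_targets=config.smooth_targets)
        tb = {b.name: b for b in used}
        cf = None
        if clin_block is not None:
            tb["CLIN"] = clin_block
            cf = list(clin_block.features)
        return model, bank, tb, cf

    model, bank, train_blocks, clin_features = build(train_ids)
    if config.theta_train is not None:
        lab = labels.subset_samples(train_ids)
        retained = remove_ambiguous(model, bank, lab,
                                    theta_train=config.theta_train)
        kept_ids = [train_ids[i] for i in retained]
        if len(kept_ids) < len(train_ids):
            model, bank, train_blocks, clin_features = build(kept_ids)
        train_ids = kept_ids
    return FoldFit(model=model, bank=bank, train_blocks=train_blocks,
                   clin_features=clin_features, train_ids=train_ids)


def predict_pipeline(fit: FoldFit, blocks: list[OmicsBlock],
                     clinical: ClinicalTable | None,
                     config: ExperimentConfig, test_ids: list[str],
                     labels: LabelVector | None = None):
    """Score held-out samples with a trained fold.

    Returns a :class:`~fsmkl.calibration.PredictionSet` when the config asks
    for cautious prediction, else a plain (f, predicted) pair wrapped in the
    same structure with full coverage.
    """
    test_ids = list(test_ids)
    by_name = {b.name: b for b in blocks}
    test_blocks = {name: by_name[name].subset_samples(test_ids)
                   for name in fit.train_blocks if name != "CLIN"}
    if "CLIN" in fit.train_blocks:
        test_blocks["CLIN"] = encode_clinical(
            clinical.subset_samples(test_ids), features=fit.clin_features)
    projected = project_bank(fit.bank, fit.train_blocks, test_blocks)
    lab = labels.subset_samples(test_ids) if labels is not None else None
    theta = config.theta_predict if config.theta_predict is not None else 0.5
    return cautious_predict(fit.model, projected, theta_predict=theta,
                            labels=lab, sample_ids=test_ids)


@dataclass
class CvResult:
    """Per-fold accuracies/coverages with their aggregates and kernel
    rankings; every output embeds the config hash and seed."""

    fold_accuracy: list[float]
    fold_coverage: list[float]
    fold_n_predicted: list[int]
    fold_rankings: list[pd.DataFrame] = field(repr=False)
    config_hash: str = ""
    seed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1))

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(self.fold_coverage))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, "accuracy": a, "coverage": c, "n_predicted": m,
                 "config_hash": self.config_hash, "seed": self.seed}
                for i, (a, c, m) in enumerate(zip(
                    self.fold_accuracy, self.fold_coverage,
                    self.fold_n_predicted))]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")


def _fold_split(y: np.ndarray, folds: int, seed: int,
                stratified: bool) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    n = y.size
    perm = rng.permutation(n)
    if stratified:
        # interleave the shuffled classes so each contiguous fold sees both
        pos = perm[y[perm] == 1]
        neg = perm[y[perm] == -1]
        merged: list[int] = []
        ratio = len(pos) / max(len(neg), 1)
        i = j = 0
        while i < len(pos) or j < len(neg):
            if j >= len(neg) or (i < len(pos) and i <= ratio * j):
                merged.append(int(pos[i])); i += 1
            else:
                merged.append(int(neg[j])); j += 1
        perm = np.array(merged)
    return [np.asarray(part, dtype=int) for part in np.array_split(perm, folds)]


def cross_validate(blocks: list[OmicsBlock], clinical: ClinicalTable | None,
                   pathways: PathwayCollection | None, labels: LabelVector,
                   config: ExperimentConfig) -> CvResult:
    """k-fold cross-validation with a prior random reshuffling of the sample
    order (contiguous unstratified folds by default)."""
    y = labels.y
    parts = _fold_split(y, config.folds, config.seed, config.stratified)
    all_ids = labels.samples
    accs, covs, npreds, rankings = [], [], [], []
    for k, test_idx in enumerate(parts):
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"training fold {k} contains a single class; "
                "consider the stratified option")
        train_ids = [all_ids[i] for i in train_idx]
        test_ids = [all_ids[i] for i in test_idx]
        fit = fit_pipeline(blocks, clinical, pathways, labels, config,
                           train_ids=train_ids)
        ps = predict_pipeline(fit, blocks, clinical, config, test_ids,
                              labels=labels)
        accs.append(float("nan") if ps.accuracy is None else ps.accuracy)
        covs.append(ps.coverage)
        npreds.append(int(np.sum(~ps.abstained)))
        rankings.append(rank_kernels(fit.model))
    return CvResult(fold_accuracy=accs, fold_coverage=covs,
                    fold_n_predicted=npreds, fold_rankings=rankings,
                    config_hash=config.config_hash(), seed=config.seed)


def compare_configs(named_configs: dict[str, ExperimentConfig],
                    blocks: list[OmicsBlock],
                    clinical: ClinicalTable | None,
                    pathways: PathwayCollection | None,
                    labels: LabelVector,
                    ) -> tuple[pd.DataFrame, dict[str, CvResult]]:
    """Cross-validate several configs on identical fold splits.

    All configs must share folds and seed (otherwise the comparison is not
    like-for-like and an error is raised).  Returns the comparison table of
    mean +- sd accuracy and coverage, plus the per-config results.
    """
    if len(named_configs) < 1:
        raise ValueError("at least one config required")
    ref = next(iter(named_configs.values()))
    for name, cfg in named_configs.items():
        if cfg.folds != ref.folds or cfg.seed != ref.seed:
            raise ValueError(
                f"config {name!r} uses different folds/seed; comparison invalid")
    results = {name: cross_validate(blocks, clinical, pathways, labels, cfg)
               for name, cfg in named_configs.items()}
    rows = [{"config": name, "mean_accuracy": r.mean, "sd_accuracy": r.sd,
             "mean_coverage": r.mean_coverage, "config_hash": r.config_hash,
             "seed": r.seed}
            for name, r in results.items()]
    return pd.DataFrame(rows), results


def aggregate_kernel_report(result: CvResult) -> pd.DataFrame:
    """Mean weight across folds and selection frequency per kernel identity.

    A kernel absent from a fold counts as weight 0 there.  Kernels never
    selected in any fold are excluded; ties in mean weight break by frequency
    then by first-seen kernel index.
    """
    n_folds = len(result.fold_rankings)
    agg: dict[str, dict] = {}
    for ranking in result.fold_rankings:
        for _, row in ranking.iterrows():
            key = row["detail"]
            rec = agg.setdefault(key, {
                "detail": key, "source": row["source"],
                "selection": row["selection"], "func": row["func"],
                "total_weight": 0.0, "n_selected": 0,
                "first_index": int(row["kernel_index"]),
            })
            rec["total_weight"] += float(row["weight"])
            rec["n_selected"] += 1
    rows = []
    for rec in agg.values():
        rows.append({
            "detail": rec["detail"], "source": rec["source"],
            "selection": rec["selection"], "func": rec["func"],
            "mean_weight": rec["total_weight"] / n_folds,
            "selection_frequency": rec["n_selected"] / n_folds,
            "first_index": rec["first_index"],
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        by=["mean_weight", "selection_frequency", "first_index"],
        ascending=[False, False, True], kind="stable").reset_index(drop=True)
    return df.drop(columns=["first_index"])
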