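"""End-to-end HTW prediction pipeline: split, stage wiring, metrics.

Stage order follows the analysis design: label races from pace profiles,
drop EXCLUDED races, stratified 80/20 split (sex x finish-time bin x age bin
x label), GCV basis selection and smoothing, train-set standardization,
per-variable FPCA with test-set projection, FPC-score collinearity screen,
penalized functional logistic regression with F1 cross-validation, and
test-set metrics.  Every training-derived quantity (basis dimensions,
standardization parameters, FPCA systems, screen, model, lambda) is computed
from training runners only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fpca as fpca_mod
from . import logit as logit_mod
from . import represent, screen
from .basis import BSplineBasis
from .labeling import LabelRule, PaceLabel, classify_race
from .synthetic import FORM_DOMAIN, CohortConfig, CohortTelemetry, generate_cohort


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split specification."""

    train_fraction: float = 0.8
    n_bins: int = 4          # quantile bins for finish time and age
    min_stratum: int = 5     # smaller strata are merged into a neighbour
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")


def _quantile_bins(values: pd.Series, n_bins: int) -> pd.Series:
    codes = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    return codes.fillna(0).astype(int)


def stratified_split(
    metadata: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str]]:
    """Split runner ids 80/20 within sex x finish-time x age x label strata.

    ``metadata`` needs columns runner_id, sex, finish_time_min, age_years,
    label; EXCLUDED races must be removed beforehand.  Strata smaller than
    ``min_stratum`` are merged into the nearest finish-time bin sharing the
    other keys (falling back to label-only strata).  Within each final
    stratum the train count is round(train_fraction * size).
    """
    meta = metadata.reset_index(drop=True).copy()
    if (meta["label"] == PaceLabel.EXCLUDED.value).any():
        raise ValueError("EXCLUDED races must be removed before splitting")
    meta["fbin"] = _quantile_bins(meta["finish_time_min"], spec.n_bins)
    meta["abin"] = _quantile_bins(meta["age_years"], spec.n_bins)
    meta["stratum"] = list(zip(meta["sex"], meta["fbin"], meta["abin"], meta["label"]))

    strata = list(meta["stratum"])
    while True:
        sizes: dict[tuple, int] = {}
        for s in strata:
            sizes[s] = sizes.get(s, 0) + 1
        small = sorted(s for s, n in sizes.items() if n < spec.min_stratum)
        small = [s for s in small if len(sizes) > 1]
        if not small:
            break
        stratum = min(small, key=lambda s: (sizes[s], s))
        sex, fbin, abin, label = stratum
        # nearest finish-time bin sharing sex/age/label, then coarser fallbacks
        candidates = [
            s for s in sizes
            if s != stratum and s[0] == sex and s[2] == abin and s[3] == label
        ]
        if candidates:
            target = min(candidates, key=lambda s: (abs(s[1] - fbin), s[1]))
        else:
            candidates = [s for s in sizes if s != stratum and s[3] == label]
            if not candidates:
                candidates = [s for s in sizes if s != stratum]
            target = max(candidates, key=lambda s: (sizes[s], s))
        strata = [target if s == stratum else s for s in strata]
    meta["stratum"] = strata

    rng = np.random.default_rng(spec.seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for _, group in meta.groupby("stratum", sort=True):
        ids = group["runner_id"].tolist()
        order = rng.permutation(len(ids))
        n_train = int(round(spec.train_fraction * len(ids)))
        n_train = min(max(n_train, 1 if len(ids) > 1 else len(ids)), len(ids))
        train_ids.extend(ids[i] for i in order[:n_train])
        test_ids.extend(ids[i] for i in order[n_train:])
    return sorted(train_ids), sorted(test_ids)


@dataclass
class MetricsReport:
    """Binary confusion counts and the derived headline metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    recall: float
    precision: float
    f1: float
    precision_zero_division: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "f1": self.f1,
            "precision_zero_division": self.precision_zero_division,
        }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Accuracy, recall, precision and F1 with HTW (=1) as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted labels"
        )
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    zero_div = (tp + fp) == 0
    precision = 0.0 if zero_div else tp / (tp + fp)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricsReport(tp, fp, fn, tn, accuracy, recall, precision, f1, zero_div)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rule: LabelRule = field(default_factory=LabelRule)
    split: SplitSpec = field(default_factory=SplitSpec)
    basis_candidates: tuple[int, int] = (8, 30)   # inclusive dimension range
    spline_order: int = 4
    variance_threshold: float = 0.99
    vif_threshold: float = 10.0
    corr_threshold: float = 0.7
    pinned_removal: list[str] | None = None
    lambda_grid: list[float] | None = None
    n_folds: int = 5
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        # one named seed drives cohort draw, split and CV folds
        self.cohort = (
            self.cohort
            if isinstance(self.cohort, CohortConfig)
            else CohortConfig.from_dict(self.cohort)
        )
        self.cohort.seed = self.seed
        self.split = (
            self.split if isinstance(self.split, SplitSpec) else SplitSpec(**self.split)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "rule" in d and isinstance(d["rule"], dict):
            d["rule"] = LabelRule(**d["rule"])
        if "basis_candidates" in d:
            d["basis_candidates"] = tuple(d["basis_candidates"])
        return cls(**d)


@dataclass
class TrainedStages:
    """All training-derived artifacts of the pipeline."""

    n_basis: dict[str, int]
    std_params: dict[str, represent.StandardizationParams]
    fpca_bases: dict[str, fpca_mod.FPCABasis]
    screen_report: screen.ScreenReport
    retained_variables: list[str]
    model: logit_mod.FLRModel
    train_scores: pd.DataFrame


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: CohortTelemetry
    labels: dict[str, str]
    train_ids: list[str]
    test_ids: list[str]
    stages: TrainedStages
    test_scores: pd.DataFrame
    test_prob: np.ndarray
    metrics: MetricsReport
    log: list[str]


def _smooth_all(
    cohort: CohortTelemetry,
    ids: set[str],
    n_basis: dict[str, int],
    order: int,
) -> dict[str, represent.FunctionalDataset]:
    """Smooth every runner in ``ids`` for all variables, merging segment groups."""
    out: dict[str, list[represent.FunctionalDataset]] = {v: [] for v in n_basis}
    for seg, (gids, mids, mats) in cohort.grouped_first_half().items():
        keep = [i for i, g in enumerate(gids) if g in ids]
        if not keep:
            continue
        for var, p in n_basis.items():
            basis = BSplineBasis(n_basis=p, domain=FORM_DOMAIN, order=order)
            ds = represent.smooth_dataset(
                mids, mats[var][keep], basis, [gids[i] for i in keep], var
            )
            out[var].append(ds)
    merged = {}
    for var, parts in out.items():
        merged[var] = represent.FunctionalDataset(
            var,
            [r for p in parts for r in p.runner_ids],
            np.vstack([p.coefficients for p in parts]),
            parts[0].basis,
        )
    return merged


def fit_stages(
    cohort: CohortTelemetry, train_ids: list[str], config: PipelineConfig, log: list[str]
) -> TrainedStages:
    """Run every training-only stage on the given training runners."""
    train_set = set(train_ids)
    grouped = cohort.grouped_first_half()
    min_m = min(len(mids) for _, mids, _ in grouped.values())
    lo, hi = config.basis_candidates
    candidates = list(range(lo, min(hi, min_m - 1) + 1))

    n_basis: dict[str, int] = {}
    for var in cohort.config.variable_names:
        series = [
            (mids, mats[var][i])
            for _, (gids, mids, mats) in grouped.items()
            for i, g in enumerate(gids)
            if g in train_set
        ]
        n_basis[var] = represent.select_basis_dimension(
            series, candidates, domain=FORM_DOMAIN, order=config.spline_order
        )
    log.append(f"GCV basis dimensions: {n_basis}")

    smoothed_train = _smooth_all(cohort, train_set, n_basis, config.spline_order)
    std_params: dict[str, represent.StandardizationParams] = {}
    std_train: dict[str, represent.FunctionalDataset] = {}
    for var, ds in smoothed_train.items():
        std_train[var], std_params[var] = represent.standardize(ds)

    fpca_bases = {
        var: fpca_mod.fit_fpca(std_train[var], config.variance_threshold)
        for var in std_train
    }
    log.append(f"FPCA retained components: {({v: b.K for v, b in fpca_bases.items()})}")

    train_scores = fpca_mod.score_frame(fpca_bases, std_train)
    retained, report = screen.screen_variables(
        train_scores,
        vif_threshold=config.vif_threshold,
        corr_threshold=config.corr_threshold,
        pinned_removal=config.pinned_removal,
    )
    log.extend(report.log_lines())

    kept_cols = [c for c in train_scores.columns if screen.variable_of(c) in set(retained)]
    labels = {r.runner_id: r for r in cohort.runners}
    y_train = np.array(
        [1.0 if classify_race(labels[r].pace_profile(), config.rule) == PaceLabel.HTW else 0.0
         for r in train_scores.index]
    )
    model = logit_mod.fit_flr(
        train_scores[kept_cols],
        y_train,
        lambda_grid=config.lambda_grid,
        n_folds=config.n_folds,
        seed=config.seed,
        threshold=config.decision_threshold,
    )
    log.append(f"FLR lambda = {model.lam:g}")
    return TrainedStages(
        n_basis=n_basis,
        std_params=std_params,
        fpca_bases=fpca_bases,
        screen_report=report,
        retained_variables=retained,
        model=model,
        train_scores=train_scores[kept_cols],
    )


def project_cohort(
    cohort: CohortTelemetry, ids: list[str], stages: TrainedStages, config: PipelineConfig
) -> pd.DataFrame:
    """Smooth, standardize (train params) and project runners to FPC scores."""
    smoothed = _smooth_all(cohort, set(ids), stages.n_basis, config.spline_order)
    std = {
        var: represent.apply_standardization(ds, stages.std_params[var])
        for var, ds in smoothed.items()
    }
    scores = fpca_mod.score_frame(stages.fpca_bases, std)
    return scores[stages.model.columns]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis and optionally write its artifacts."""
    log: list[str] = [f"seed = {config.seed}"]
    cohort = generate_cohort(config.cohort)
    log.append(f"generated cohort: {len(cohort.runners)} runners")

    labels = {
        r.runner_id: classify_race(r.pace_profile(), config.rule).value
        for r in cohort.runners
    }
    counts = pd.Series(list(labels.values())).value_counts().to_dict()
    log.append(f"pace labels: {counts}")

    meta = cohort.metadata_frame()
    meta["label"] = meta["runner_id"].map(labels)
    labeled = meta[meta["label"] != PaceLabel.EXCLUDED.value].reset_index(drop=True)
    split_spec = SplitSpec(
        train_fraction=config.split.train_fraction,
        n_bins=config.split.n_bins,
        min_stratum=config.split.min_stratum,
        seed=config.seed,
    )
    train_ids, test_ids = stratified_split(labeled, split_spec)
    log.append(f"split: {len(train_ids)} train / {len(test_ids)} test")

    stages = fit_stages(cohort, train_ids, config, log)
    test_scores = project_cohort(cohort, test_ids, stages, config)
    prob = logit_mod.predict_prob(stages.model, test_scores)
    y_test = np.array(
        [1 if labels[r] == PaceLabel.HTW.value else 0 for r in test_scores.index]
    )
    metrics = compute_metrics(y_test, (prob >= config.decision_threshold).astype(int))
    log.append(
        f"test metrics: acc={metrics.accuracy:.3f} rec={metrics.recall:.3f} "
        f"prec={metrics.precision:.3f} f1={metrics.f1:.3f}"
    )
    result = PipelineResult(
        config=config,
        cohort=cohort,
        labels=labels,
        train_ids=train_ids,
        test_ids=test_ids,
        stages=stages,
        test_scores=test_scores,
        test_prob=prob,
        metrics=metrics,
        log=log,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def write_artifacts(result: PipelineResult, out: Path) -> None:
    """Write labels, model, metrics, scores and coefficient-function exports."""
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"runner_id": list(result.labels), "label": list(result.labels.values())}
    ).to_csv(out / "labels.csv", index=False)
    result.cohort.metadata_frame().to_csv(out / "metadata.csv", index=False)
    pd.DataFrame({"runner_id": result.train_ids}).assign(split="train").pipe(
        lambda df: pd.concat(
            [df, pd.DataFrame({"runner_id": result.test_ids}).assign(split="test")]
        )
    ).to_csv(out / "split.csv", index=False)
    result.stages.train_scores.to_csv(out / "train_scores.csv")
    result.test_scores.to_csv(out / "test_scores.csv")
    result.stages.screen_report.vif.to_csv(out / "screen_vif.csv")
    with open(out / "model.json", "w") as fh:
        json.dump(result.stages.model.to_dict(), fh, indent=1)
    with open(out / "fpca.json", "w") as fh:
        json.dump(
            {v: b.to_dict() for v, b in result.stages.fpca_bases.items()}, fh
        )
    with open(out / "metrics.json", "w") as fh:
        json.dump(result.metrics.to_dict(), fh, indent=1)
    grid = np.linspace(*FORM_DOMAIN, represent.DEFAULT_GRID)
    rows = []
    for var in result.stages.retained_variables:
        cf = logit_mod.coefficient_function(
            result.stages.model, result.stages.fpca_bases[var], var
        )
        vals = result.stages.fpca_bases[var].basis.evaluate(cf.coefficients, grid)
        rows.append(pd.DataFrame({"variable": var, "t_km": grid, "beta": vals}))
    pd.concat(rows, ignore_index=True).to_csv(out / "coefficient_functions.csv", index=False)
    importance = logit_mod.variable_importance(result.stages.model)
    pd.DataFrame(importance, columns=["variable", "l2_norm"]).to_csv(
        out / "importance.csv", index=False
    )
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
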