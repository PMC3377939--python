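"""Orchestrate the experimental protocol.

The data are split repeatedly (default 100 times) at random into 2:1
training/test sets.  On each training set: precluster (when the mode asks
for it), build the design, tune lambda by 10-fold CVPL, and fit on the
whole training set.  On the test set: compute prognostic indices and the
three evaluation criteria.  Splits are shared across every method x mode
combination so comparisons are paired.  Results aggregate into per-metric
distribution summaries, l1 covariate-selection frequency tables, and
averaged prediction-error curves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gosurv.cox import (
    CoxFit,
    RiskModelInput,
    fit_clinical_only,
    fit_penalized_cox,
    prognostic_index,
    tune_lambda,
)
from gosurv.data import Dataset
from gosurv.design import build_design, project_design
from gosurv.evaluate import (
    PredictionErrorCurve,
    assign_risk_groups,
    breslow_baseline,
    brier_score,
    integrated_brier_score,
    km_censoring,
    logrank_test,
    pi_lrt,
    predict_survival,
    prediction_error_curve,
)
from gosurv.precluster import precluster_all_groups

logger = logging.getLogger(__name__)

METHODS = ("l1", "l2")
MODES = ("genes", "groups", "preclustered", "clinical_only")


@dataclass
class HarnessConfig:
    n_splits: int = 100
    methods: tuple = ("l1", "l2")
    modes: tuple = ("genes", "groups", "preclustered", "clinical_only")
    with_clinical: bool = True
    cv_folds: int = 10
    n_lambda: int = 50
    t_star: float = 10.0
    k_max: int = 20
    master_seed: int = 0
    precluster_full_data: bool = False  # training-only clustering by default


@dataclass
class SplitResult:
    split_id: int
    seed: int
    method: str
    mode: str
    with_clinical: bool
    p_lr: float
    p_pi: float
    ibs: float
    lam: float | None
    n_selected: int
    selected: dict[str, float] = field(default_factory=dict)  # covariate -> coefficient
    curve: PredictionErrorCurve | None = None
    error: str | None = None

    def row(self) -> dict:
        return {
            "split_id": self.split_id,
            "method": self.method,
            "mode": self.mode,
            "with_clinical": self.with_clinical,
            "p_LR": self.p_lr,
            "p_PI": self.p_pi,
            "IBS": self.ibs,
            "lambda": np.nan if self.lam is None else self.lam,
            "n_selected": self.n_selected,
        }


@dataclass
class EvaluationSummary:
    results: list[SplitResult]
    n_splits: int
    n_failed: int
    config: HarnessConfig
    covariate_meta: dict[str, dict] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [r.row() for r in self.results if r.error is None]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        df = self.metrics_frame()
        if df.empty:
            return df
        out = (
            df.groupby(["method", "mode", "with_clinical"])
            .agg(
                n=("split_id", "count"),
                median_p_LR=("p_LR", "median"),
                median_p_PI=("p_PI", "median"),
                median_IBS=("IBS", "median"),
                mean_IBS=("IBS", "mean"),
                median_lambda=("lambda", "median"),
                median_n_selected=("n_selected", "median"),
            )
            .reset_index()
        )
        return out

    def selection_frequency(self, method: str = "l1", mode: str = "preclustered") -> pd.DataFrame:
        """Per covariate: how often l1 selected it, and the majority effect sign."""
        counts: dict[str, int] = {}
        signs: dict[str, list[float]] = {}
        for r in self.results:
            if r.error is not None or r.method != method or r.mode != mode:
                continue
            for cov, coef in r.selected.items():
                counts[cov] = counts.get(cov, 0) + 1
                signs.setdefault(cov, []).append(coef)
        rows = []
        for cov, cnt in counts.items():
            meta = self.covariate_meta.get(cov, {})
            pos = sum(1 for c in signs[cov] if c > 0)
            effect = 1 if pos * 2 >= len(signs[cov]) else -1
            rows.append(
                {
                    "covariate_id": cov,
                    "count": cnt,
                    "effect": effect,
                    "group_id": meta.get("group_id", ""),
                    "medoid": meta.get("medoid", ""),
                    "cluster_size": meta.get("cluster_size", ""),
                }
            )
        df = pd.DataFrame(rows, columns=["covariate_id", "count", "effect", "group_id", "medoid", "cluster_size"])
        return df.sort_values(["count", "covariate_id"], ascending=[False, True]).reset_index(drop=True)

    def mean_curve(self, method: str, mode: str) -> PredictionErrorCurve | None:
        curves = [
            r.curve
            for r in self.results
            if r.error is None and r.method == method and r.mode == mode and r.curve is not None
        ]
        if not curves:
            return None
        return prediction_error_curve(curves)

    def to_dict(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "n_failed": self.n_failed,
            "results": [
                {
                    **r.row(),
                    "lambda": None if r.lam is None else r.lam,
                    "selected": {k: r.selected[k] for k in sorted(r.selected)},
                    "error": r.error,
                }
                for r in self.results
            ],
        }

    def digest(self) -> str:
        """SHA-256 over the canonical JSON form; identical seeds give identical digests."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()


def split_data(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random 2:1 train/test partition: |train| = floor(2n/3)."""
    if n < 3:
        raise ValueError("need at least 3 samples to split 2:1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.floor(2 * n / 3)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class TrainedModel:
    """Training-side artifacts of one split (used for leakage checks too)."""

    design: object | None
    fit: CoxFit
    lam: float | None
    preclustered: object | None


def _train_on_split(
    train_data: Dataset,
    method: str,
    mode: str,
    with_clinical: bool,
    config: HarnessConfig,
    cv_seed: int,
    cluster_source: Dataset | None = None,
) -> TrainedModel:
    Z = train_data.clinical.values if with_clinical else np.empty((train_data.n_samples, 0))
    if mode == "clinical_only":
        if Z.shape[1] == 0:
            raise ValueError("clinical_only mode requires clinical covariates")
        inp = RiskModelInput(np.empty((train_data.n_samples, 0)), Z, train_data.survival)
        fit = fit_clinical_only(inp)
        return TrainedModel(design=None, fit=fit, lam=None, preclustered=None)

    preclustered = None
    if mode == "preclustered":
        preclustered = precluster_all_groups(cluster_source or train_data, k_max=config.k_max)
    design = build_design(train_data, mode, preclustered=preclustered)
    inp = RiskModelInput(design.X, Z, train_data.survival)
    lam, _curve = tune_lambda(
        inp, method, M=config.cv_folds, n_lambda=config.n_lambda, seed=cv_seed
    )
    fit = fit_penalized_cox(inp, method, lam)
    return TrainedModel(design=design, fit=fit, lam=lam, preclustered=preclustered)


def run_single_split(
    dataset: Dataset,
    split: tuple[np.ndarray, np.ndarray],
    method: str,
    mode: str,
    with_clinical: bool = True,
    config: HarnessConfig | None = None,
    split_id: int = 0,
    seed: int = 0,
) -> SplitResult:
    """Train, tune, and evaluate one train/test split for one method x mode."""
    config = config or HarnessConfig()
    train_idx, test_idx = split
    sample_ids = dataset.sample_ids
    train_ids = [sample_ids[i] for i in train_idx]
    test_ids = [sample_ids[i] for i in test_idx]
    train_data = dataset.subset_samples(train_ids)
    test_data = dataset.subset_samples(test_ids)

    cluster_source = dataset if config.precluster_full_data else None

    model = _train_on_split(
        train_data,
        method,
        mode,
        with_clinical,
        config,
        cv_seed=seed * 1000 + 17,
        cluster_source=cluster_source,
    )
    fit = model.fit

    Z_train = train_data.clinical.values if with_clinical else np.empty((train_data.n_samples, 0))
    Z_test = test_data.clinical.values if with_clinical else np.empty((test_data.n_samples, 0))
    if mode == "clinical_only":
        X_train = np.empty((train_data.n_samples, 0))
        X_test = np.empty((test_data.n_samples, 0))
    else:
        X_train = model.design.X
        X_test = project_design(model.design, dataset, test_ids)

    pi_test = prognostic_index(fit, X_test, Z_test)

    labels = assign_risk_groups(pi_test)
    if labels.sum() in (0, len(labels)):
        p_lr = 1.0
    else:
        _, p_lr = logrank_test(labels, test_data.survival)
    try:
        p_pi = pi_lrt(pi_test, test_data.survival)
    except ValueError:
        p_pi = 1.0  # constant PI (e.g. null l1 model): no discrimination

    train_inp = RiskModelInput(X_train, Z_train, train_data.survival)
    baseline = breslow_baseline(fit, train_inp)
    G = km_censoring(test_data.survival)
    t_star = config.t_star
    limit = G.support_limit
    if limit < t_star:
        logger.warning("G(t) hits 0 at %.3g < t*=%.3g; truncating", limit, t_star)
        t_star = limit
    ev = test_data.survival.time[test_data.survival.event == 1]
    grid = np.unique(np.concatenate([[0.0], ev[ev <= t_star], [t_star]]))
    S = predict_survival(fit, baseline, X_test, Z_test, grid)
    bs_vals = np.asarray(
        [brier_score(t, test_data.survival, S[:, j], G) for j, t in enumerate(grid)]
    )
    curve = PredictionErrorCurve(grid, bs_vals)
    ibs = integrated_brier_score(curve, t_star)

    selected = {}
    if mode != "clinical_only" and method == "l1":
        for info, coef in zip(model.design.covariates, fit.beta):
            if coef != 0.0:
                selected[info.covariate_id] = float(coef)

    if mode == "clinical_only":
        n_selected = 0
    elif method == "l1":
        n_selected = int(np.sum(fit.beta != 0))
    else:
        n_selected = len(fit.beta)

    return SplitResult(
        split_id=split_id,
        seed=seed,
        method=method if mode != "clinical_only" else "none",
        mode=mode,
        with_clinical=with_clinical or mode == "clinical_only",
        p_lr=float(p_lr),
        p_pi=float(p_pi),
        ibs=float(ibs),
        lam=model.lam,
        n_selected=n_selected,
        selected=selected,
        curve=curve,
    )


def run_evaluation(
    dataset: Dataset,
    n_splits: int = 100,
    methods: tuple = ("l1", "l2"),
    modes: tuple = ("genes", "groups", "preclustered", "clinical_only"),
    with_clinical: bool = True,
    config: HarnessConfig | None = None,
) -> EvaluationSummary:
    """Shared-split evaluation of every method x mode combination."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    config = config or HarnessConfig()
    config.n_splits = n_splits
    config.methods = tuple(methods)
    config.modes = tuple(modes)
    results: list[SplitResult] = []
    covariate_meta: dict[str, dict] = {}
    n_failed = 0
    n = dataset.n_samples
    for m in range(n_splits):
        seed = config.master_seed + m
        split = split_data(n, seed)
        for mode in modes:
            mode_methods = ("none",) if mode == "clinical_only" else methods
            for method in mode_methods:
                try:
                    res = run_single_split(
                        dataset,
                        split,
                        method if mode != "clinical_only" else "l2",
                        mode,
                        with_clinical=with_clinical,
                        config=config,
                        split_id=m,
                        seed=seed,
                    )
                except Exception as exc:  # noqa: BLE001 - batch robustness
                    logger.warning("split %d %s/%s failed: %s", m, method, mode, exc)
                    results.append(
                        SplitResult(
                            split_id=m,
                            seed=seed,
                            method=method,
                            mode=mode,
                            with_clinical=with_clinical,
                            p_lr=np.nan,
                            p_pi=np.nan,
                            ibs=np.nan,
                            lam=None,
                            n_selected=0,
                            error=str(exc),
                        )
                    )
                    n_failed += 1
                    continue
                results.append(res)
        logger.info("split %d/%d done", m + 1, n_splits)
    if n_failed == len(results):
        raise RuntimeError("every split failed")

    # covariate metadata from a full-data preclustered design, for Table-2-style output
    if any(mode == "preclustered" for mode in modes):
        try:
            pre = precluster_all_groups(dataset, k_max=config.k_max)
            design = build_design(dataset, "preclustered", preclustered=pre)
            for info in design.covariates:
                covariate_meta[info.covariate_id] = {
                    "group_id": info.group_id,
                    "medoid": info.medoid_id,
                    "cluster_size": info.cluster_size,
                }
        except Exception as exc:  # pragma: no cover - metadata is best-effort
            logger.warning("covariate metadata collection failed: %s", exc)

    return EvaluationSummary(
        results=results,
        n_splits=n_splits,
        n_failed=n_failed,
        config=config,
        covariate_meta=covariate_meta,
    )


def report(summary: EvaluationSummary, outdir) -> list[str]:
    """Write metric tables, selection frequencies, curves, and plots."""
    if not summary.results:
        raise ValueError("empty summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    metrics = summary.metrics_frame()
    if metrics.empty:
        raise ValueError("no successful splits to report")
    path = outdir / "metrics.tsv"
    metrics.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(str(path))

    path = outdir / "summary.tsv"
    summary.summary_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(str(path))

    long = metrics.melt(
        id_vars=["split_id", "method", "mode", "with_clinical"],
        value_vars=["p_LR", "p_PI", "IBS"],
        var_name="metric",
        value_name="value",
    )
    path = outdir / "metrics_long.tsv"
    long.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(str(path))

    for method in sorted({r.method for r in summary.results if r.method != "none"}):
        for mode in sorted({r.mode for r in summary.results}):
            if mode == "clinical_only":
                continue
            sel = summary.selection_frequency(method, mode)
            if not sel.empty:
                path = outdir / f"selection_{method}_{mode}.tsv"
                sel.to_csv(path, sep="\t", index=False)
                written.append(str(path))

    curve_rows = []
    for r in summary.results:
        if r.curve is None or r.error is not None:
            continue
        for t, b in zip(r.curve.time, r.curve.bs):
            curve_rows.append(
                {"method": r.method, "mode": r.mode, "split_id": r.split_id, "time": t, "BS": b}
            )
    if curve_rows:
        path = outdir / "curves.tsv"
        pd.DataFrame(curve_rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(str(path))

    written.extend(_plots(summary, outdir))
    return written


def _plots(summary: EvaluationSummary, outdir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    metrics = summary.metrics_frame()
    combos = metrics[["method", "mode"]].drop_duplicates().itertuples(index=False)
    combos = [f"{m}/{d}" for m, d in combos]

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for ax, metric in zip(axes, ["p_PI", "IBS"]):
        data, labels = [], []
        for combo in combos:
            method, mode = combo.split("/")
            vals = metrics[(metrics["method"] == method) & (metrics["mode"] == mode)][metric]
            vals = vals.dropna()
            if metric == "p_PI":
                vals = -np.log10(np.clip(vals, 1e-300, None))
            data.append(vals)
            labels.append(combo)
        ax.boxplot(data, tick_labels=labels)
        ax.set_title("-log10 p (PI)" if metric == "p_PI" else "IBS")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    path = outdir / "boxplots.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(7, 5))
    clinical_curve = summary.mean_curve("none", "clinical_only")
    for combo in combos:
        method, mode = combo.split("/")
        curve = summary.mean_curve(method, mode)
        if curve is None or mode == "clinical_only":
            continue
        ax.step(curve.time, curve.bs, where="post", label=combo)
    if clinical_curve is not None:
        ax.step(clinical_curve.time, clinical_curve.bs, where="post", ls="--", c="k", label="clinical")
    ax.set_xlabel("years")
    ax.set_ylabel("BS(t)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = outdir / "prediction_error_curves.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(str(path))
    return written
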