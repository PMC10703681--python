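"""Imputation-accuracy metrics, bootstrap uncertainty and QC.

Accuracy is measured on withheld (simulated-missing) cells against their true
values. The primary metric is the squared Pearson correlation r^2 — for binary
phenotypes computed between the imputed probability and the 0/1 truth — with
AUPR and AUROC additionally reported for binary phenotypes. Standard errors
and percentile confidence intervals come from bootstrap resampling of the
evaluated cells within each phenotype; method comparisons use a two-tailed
normal test on the bootstrap SEs with a Bonferroni per-phenotype threshold.

For real (non-simulated) data, where no truth is available, the
variance-ratio QC compares the spread of the imputed portion of a phenotype
with its observed portion; over-shrunk imputations score near zero, and
values above 0.2 are the recommended pass level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

from .masking import EvaluationMask
from .phenotype_io import MaskedPhenotypeMatrix, PhenotypeSchema


def pearson_r2(imputed: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation; NaN if either side has zero variance."""
    x = np.asarray(imputed, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.size < 2 or x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def binary_rank_metrics(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUPR, AUROC) for probability scores against 0/1 labels.

    AUROC is the Mann-Whitney concordance probability (ties count half);
    AUPR is the area under the step-wise precision-recall curve. Both are
    NaN when only one class is present.
    """
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        return float("nan"), float("nan")
    aupr = float(average_precision_score(labels, scores))
    auroc = float(roc_auc_score(labels, scores))
    return aupr, auroc


@dataclass
class MetricReport:
    """Per-phenotype and aggregate imputation accuracy.

    ``per_phenotype`` has one row per phenotype with columns: phenotype, kind,
    n_cells, r2 (+ aupr/auroc for binary phenotypes), and, when bootstrapped,
    *_se / *_ci_lo / *_ci_hi columns. Aggregates are unweighted means over
    phenotypes with a defined metric; phenotypes whose metric is undefined
    (zero-variance truth or predictions) are listed in ``undefined``.
    """

    per_phenotype: pd.DataFrame
    aggregates: dict[str, float] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "aggregates": self.aggregates,
            "undefined": self.undefined,
            "per_phenotype": self.per_phenotype.replace({np.nan: None}).to_dict("records"),
        }


def _cells_by_phenotype(
    eval_mask: EvaluationMask, imputed: np.ndarray, schema: PhenotypeSchema
) -> dict[str, tuple[np.ndarray, np.ndarray, str]]:
    """Group (imputed, truth) values of withheld cells by phenotype."""
    pred = np.asarray(imputed, dtype=float)[eval_mask.rows, eval_mask.cols]
    out: dict[str, tuple[np.ndarray, np.ndarray, str]] = {}
    for j in np.unique(eval_mask.cols):
        sel = eval_mask.cols == j
        out[schema.names[j]] = (pred[sel], eval_mask.truth[sel], schema.kinds[j])
    return out


def _aggregate(per: pd.DataFrame) -> dict[str, float]:
    agg: dict[str, float] = {}
    agg["mean_r2"] = float(per["r2"].mean(skipna=True))
    binr = per.loc[per["kind"] == "binary"]
    if len(binr):
        agg["mean_r2_binary"] = float(binr["r2"].mean(skipna=True))
        agg["mean_aupr"] = float(binr["aupr"].mean(skipna=True))
        agg["mean_auroc"] = float(binr["auroc"].mean(skipna=True))
    return agg


def evaluate_imputation(
    eval_mask: EvaluationMask,
    imputed: np.ndarray,
    schema: PhenotypeSchema,
    n_boot_se: int = 50,
    n_boot_ci: int = 100,
    seed: int = 0,
) -> MetricReport:
    """Score an imputed matrix on the withheld cells of an evaluation mask.

    Per-phenotype r^2 (all phenotypes) and AUPR/AUROC (binary phenotypes),
    with bootstrap SEs (``n_boot_se`` replicates, the cells of each phenotype
    resampled with replacement) and percentile 95% CIs (``n_boot_ci``
    replicates). The aggregate mean r^2 carries an SE from per-replicate
    phenotype means sharing a replicate index. Set ``n_boot_se=0`` to skip
    bootstrapping.
    """
    groups = _cells_by_phenotype(eval_mask, imputed, schema)
    rows = []
    undefined: list[str] = []
    for name, (pred, truth, kind) in groups.items():
        r2 = pearson_r2(pred, truth) if len(pred) >= 2 else float("nan")
        row = {"phenotype": name, "kind": kind, "n_cells": len(pred), "r2": r2,
               "aupr": float("nan"), "auroc": float("nan")}
        if kind == "binary":
            row["aupr"], row["auroc"] = binary_rank_metrics(pred, truth)
        if np.isnan(r2):
            undefined.append(name)
        rows.append(row)
    per = pd.DataFrame(rows)
    report = MetricReport(per_phenotype=per, undefined=undefined)
    report.aggregates = _aggregate(per)

    if n_boot_se > 0 and len(per):
        rng = np.random.default_rng(seed)
        n_rep = max(n_boot_se, n_boot_ci)
        # replicate x phenotype matrices of each metric
        boot = {k: np.full((n_rep, len(per)), np.nan) for k in ("r2", "aupr", "auroc")}
        for col, name in enumerate(per["phenotype"]):
            pred, truth, kind = groups[name]
            n = len(pred)
            for b in range(n_rep):
                idx = rng.integers(0, n, size=n)
                boot["r2"][b, col] = pearson_r2(pred[idx], truth[idx])
                if kind == "binary":
                    boot["aupr"][b, col], boot["auroc"][b, col] = binary_rank_metrics(
                        pred[idx], truth[idx]
                    )
        import warnings

        for metric in ("r2", "aupr", "auroc"):
            reps = boot[metric]
            with warnings.catch_warnings():
                # continuous phenotypes have no rank metrics: all-NaN slices expected
                warnings.simplefilter("ignore", RuntimeWarning)
                per[f"{metric}_se"] = np.nanstd(reps[:n_boot_se], axis=0, ddof=1)
                per[f"{metric}_ci_lo"] = np.nanpercentile(reps[:n_boot_ci], 2.5, axis=0)
                per[f"{metric}_ci_hi"] = np.nanpercentile(reps[:n_boot_ci], 97.5, axis=0)
        # a phenotype whose metric is undefined on most resamples is unreliable
        frac_bad = np.mean(np.isnan(boot["r2"][:n_boot_se]), axis=0)
        per["bootstrap_failed"] = frac_bad > 0.5
        agg_reps = np.nanmean(boot["r2"][:n_boot_se], axis=1)
        report.aggregates["mean_r2_se"] = float(np.nanstd(agg_reps, ddof=1))
        ci_reps = np.nanmean(boot["r2"][:n_boot_ci], axis=1)
        report.aggregates["mean_r2_ci_lo"] = float(np.nanpercentile(ci_reps, 2.5))
        report.aggregates["mean_r2_ci_hi"] = float(np.nanpercentile(ci_reps, 97.5))
    return report


def bootstrap_uncertainty(
    metric,
    imputed: np.ndarray,
    truth: np.ndarray,
    n_boot: int = 50,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap SE and percentile 95% CI of an arbitrary cellwise metric.

    ``metric(imputed, truth) -> float`` is re-evaluated on ``n_boot``
    resamples (cells drawn with replacement). Raises if the metric is
    undefined (NaN) on more than half of the resamples.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    imputed = np.asarray(imputed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(truth), size=len(truth))
        vals[b] = metric(imputed[idx], truth[idx])
    if np.mean(np.isnan(vals)) > 0.5:
        raise ValueError("metric undefined on more than half of bootstrap resamples")
    se = float(np.nanstd(vals, ddof=1))
    ci = (float(np.nanpercentile(vals, 2.5)), float(np.nanpercentile(vals, 97.5)))
    return se, ci


def compare_methods(
    report_a: MetricReport,
    report_b: MetricReport,
    alpha: float = 0.05,
    n_tests: int | None = None,
    metric: str = "r2",
) -> pd.DataFrame:
    """Per-phenotype two-tailed comparison of two metric reports.

    z = (m_a - m_b) / sqrt(SE_a^2 + SE_b^2) with a normal two-tailed p-value;
    significance is called at alpha / n_tests (Bonferroni; default n_tests =
    number of phenotypes compared). Reports must have been evaluated on
    identical cells per phenotype.
    """
    a = report_a.per_phenotype.set_index("phenotype")
    b = report_b.per_phenotype.set_index("phenotype")
    if not a.index.equals(b.index) or not a["n_cells"].equals(b["n_cells"]):
        raise ValueError("reports were not evaluated on identical withheld cells")
    se_col = f"{metric}_se"
    if se_col not in a.columns or se_col not in b.columns:
        raise ValueError("reports lack bootstrap SEs; evaluate with n_boot_se > 0")
    if n_tests is None:
        n_tests = len(a)
    diff = a[metric] - b[metric]
    se = np.sqrt(a[se_col] ** 2 + b[se_col] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = diff / se
    z = z.where(se > 0, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "phenotype": a.index,
            f"{metric}_a": a[metric].to_numpy(),
            f"{metric}_b": b[metric].to_numpy(),
            "z": z.to_numpy(),
            "p": p,
            "significant": p < alpha / n_tests,
        }
    ).reset_index(drop=True)
    out.attrs["threshold"] = alpha / n_tests
    out.attrs["n_better"] = int(((out["z"] > 0) & out["significant"]).sum())
    out.attrs["n_worse"] = int(((out["z"] < 0) & out["significant"]).sum())
    return out


def variance_ratio_qc(
    imputed_values: np.ndarray,
    observed_values: np.ndarray,
    threshold: float = 0.2,
) -> tuple[float, bool]:
    """Ratio Var(imputed portion) / Var(observed portion) with a PASS flag.

    Low ratios indicate over-shrunk, low-information imputations; the
    recommended pass level is > 0.2.
    """
    imp = np.asarray(imputed_values, dtype=float)
    obs = np.asarray(observed_values, dtype=float)
    if imp.size < 2 or obs.size < 2:
        raise ValueError("both portions need at least 2 values")
    v_obs = obs.var()
    if v_obs == 0.0:
        raise ValueError("observed portion has zero variance")
    ratio = float(imp.var() / v_obs)
    return ratio, ratio > threshold


def variance_ratio_report(
    data: MaskedPhenotypeMatrix,
    completed: np.ndarray,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Variance-ratio QC per phenotype of a completed matrix."""
    rows = []
    for j, name in enumerate(data.schema.names):
        obs = data.mask[:, j]
        if obs.all() or (~obs).sum() < 2 or obs.sum() < 2:
            rows.append({"phenotype": name, "ratio": float("nan"), "passed": False,
                         "n_observed": int(obs.sum()), "n_imputed": int((~obs).sum())})
            continue
        ratio, ok = variance_ratio_qc(completed[~obs, j], data.values[obs, j], threshold)
        rows.append({"phenotype": name, "ratio": ratio, "passed": ok,
                     "n_observed": int(obs.sum()), "n_imputed": int((~obs).sum())})
    return pd.DataFrame(rows)
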