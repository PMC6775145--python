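"""Per-night agreement metrics and cohort-level subgroup statistics.

Overall agreement between a reference and a predicted hypnogram is scored
on an epoch-per-epoch basis with accuracy and Cohen's kappa; per-stage
performance uses the one-vs-rest 2x2 collapse of the 4x4 confusion matrix.
Cohort summaries report mean +/- SD over nights, Pearson correlations of
performance with age and BMI, and Mann-Whitney U tests between sexes and
between each clinical group and the healthy controls (group comparisons on
a participant level: nights are averaged per participant first).  No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Hypnogram, RecordingMeta, STAGES


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = reference stage, columns = predicted, STAGES order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4) and self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(reference: Hypnogram, predicted: Hypnogram) -> ConfusionMatrix:
    if len(reference) != len(predicted):
        raise ValueError("hypnogram length mismatch")
    cm = np.zeros((4, 4), dtype=np.int64)
    ref = reference.to_indices()
    pred = predicted.to_indices()
    np.add.at(cm, (ref, pred), 1)
    return ConfusionMatrix(cm)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) from the count matrix.

    Degenerate rule: if chance agreement p_e = 1 (both marginals
    concentrated on one class), return 1 for perfect observed agreement and
    0 otherwise.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / (n * n)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _binary_collapse(cm: np.ndarray, stage: int) -> np.ndarray:
    """2x2 one-vs-rest collapse: [[TP, FN], [FP, TN]]."""
    tp = cm[stage, stage]
    fn = cm[stage, :].sum() - tp
    fp = cm[:, stage].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return np.array([[tp, fn], [fp, tn]], dtype=np.int64)


@dataclass
class NightMetrics:
    recording_id: str
    kappa: float
    accuracy_pct: float
    per_stage: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"recording_id": self.recording_id,
                                       "kappa": self.kappa,
                                       "accuracy_pct": self.accuracy_pct}
        for s in STAGES:
            for metric in ("precision", "recall", "accuracy", "kappa"):
                row[f"{s}_{metric}"] = self.per_stage.get(s, {}).get(metric, np.nan)
        return row


def night_metrics(reference: Hypnogram, predicted: Hypnogram,
                  recording_id: str = "") -> NightMetrics:
    """Overall kappa/accuracy plus one-vs-rest per-stage metrics.

    Stages absent from both the reference and the prediction yield missing
    per-stage values.
    """
    cm = confusion(reference, predicted)
    n = cm.total
    kappa = cohen_kappa(cm)
    accuracy = 100.0 * np.trace(cm.counts) / n
    per_stage: dict[str, dict[str, float]] = {}
    for si, stage in enumerate(STAGES):
        b = _binary_collapse(cm.counts, si)
        tp, fn = b[0]
        fp, tn = b[1]
        if tp + fn == 0 and tp + fp == 0:
            per_stage[stage] = {m: np.nan for m in
                                ("precision", "recall", "accuracy", "kappa")}
            continue
        per_stage[stage] = {
            "precision": tp / (tp + fp) if tp + fp > 0 else np.nan,
            "recall": tp / (tp + fn) if tp + fn > 0 else np.nan,
            "accuracy": (tp + tn) / n,
            "kappa": cohen_kappa(ConfusionMatrix(b)),
        }
    return NightMetrics(recording_id, kappa, accuracy, per_stage)


@dataclass
class CohortReport:
    n_nights: int
    summary: pd.DataFrame            # metric -> mean, sd, n
    correlations: pd.DataFrame       # (covariate, metric) -> r, p, n
    group_tests: pd.DataFrame        # comparison -> U, p, n1, n2
    age_split: pd.DataFrame | None = None


def _metric_frame(metrics: list[NightMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_row() for m in metrics])


def cohort_summary(metrics: list[NightMetrics], metas: list[RecordingMeta],
                   age_split_years: float = 50.0) -> CohortReport:
    """Aggregate per-night metrics into the cohort-level report."""
    if len(metrics) != len(metas):
        raise ValueError("metrics and metadata lists must align")
    df = _metric_frame(metrics)
    df["participant_id"] = [m.participant_id for m in metas]
    df["age"] = [m.age for m in metas]
    df["bmi"] = [m.bmi for m in metas]
    df["sex"] = [m.sex for m in metas]
    df["group"] = [m.group for m in metas]

    metric_cols = [c for c in df.columns if c not in
                   ("recording_id", "participant_id", "age", "bmi", "sex", "group")]
    summary = pd.DataFrame({
        "mean": df[metric_cols].mean(),
        "sd": df[metric_cols].std(ddof=1),
        "n": df[metric_cols].notna().sum(),
    })

    corr_rows = []
    for cov in ("age", "bmi"):
        for metric in ("kappa", "accuracy_pct"):
            sub = df[[cov, metric]].dropna()
            if len(sub) < 3 or sub[cov].nunique() < 2 or sub[metric].nunique() < 2:
                corr_rows.append({"covariate": cov, "metric": metric,
                                  "r": np.nan, "p": np.nan, "n": len(sub)})
                continue
            r, p = sps.pearsonr(sub[cov], sub[metric])
            corr_rows.append({"covariate": cov, "metric": metric,
                              "r": float(r), "p": float(p), "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    # participant-level aggregation for the two-sample tests
    per_part = df.groupby("participant_id").agg(
        kappa=("kappa", "mean"), accuracy_pct=("accuracy_pct", "mean"),
        sex=("sex", "first"), group=("group", "first"))
    test_rows = []

    def _mwu(label: str, a: np.ndarray, b: np.ndarray, metric: str) -> None:
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            test_rows.append({"comparison": label, "metric": metric,
                              "U": np.nan, "p": np.nan, "n1": len(a), "n2": len(b)})
            return
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_rows.append({"comparison": label, "metric": metric,
                          "U": float(res.statistic), "p": float(res.pvalue),
                          "n1": len(a), "n2": len(b)})

    for metric in ("kappa", "accuracy_pct"):
        males = per_part.loc[per_part.sex == "M", metric].to_numpy(float)
        females = per_part.loc[per_part.sex == "F", metric].to_numpy(float)
        _mwu("M_vs_F", males, females, metric)
        if per_part.group.notna().any():
            healthy = per_part.loc[per_part.group == "healthy", metric].to_numpy(float)
            for grp in sorted(set(per_part.group.dropna()) - {"healthy"}):
                sel = per_part.loc[per_part.group == grp, metric].to_numpy(float)
                _mwu(f"{grp}_vs_healthy", sel, healthy, metric)
    group_tests = pd.DataFrame(test_rows)

    age_split = None
    if df["age"].notna().any():
        young = df[df.age <= age_split_years]
        old = df[df.age > age_split_years]
        rows = []
        for col in metric_cols:
            a = young[col].to_numpy(float)
            b = old[col].to_numpy(float)
            a = a[~np.isnan(a)]
            b = b[~np.isnan(b)]
            if len(a) and len(b):
                res = sps.mannwhitneyu(a, b, alternative="two-sided")
                rows.append({"metric": col, "young_mean": a.mean(),
                             "old_mean": b.mean(), "U": float(res.statistic),
                             "p": float(res.pvalue), "n_young": len(a),
                             "n_old": len(b)})
        age_split = pd.DataFrame(rows)

    return CohortReport(n_nights=len(metrics), summary=summary,
                        correlations=correlations, group_tests=group_tests,
                        age_split=age_split)


def write_report(report: CohortReport, out_dir) -> None:
    """Serialize the cohort report: CSVs plus a human-readable summary."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(out / "cohort_summary.csv")
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.group_tests.to_csv(out / "group_tests.csv", index=False)
    if report.age_split is not None:
        report.age_split.to_csv(out / "age_split.csv", index=False)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(f"Nights: {report.n_nights}\n\n")
        k = report.summary.loc["kappa"]
        a = report.summary.loc["accuracy_pct"]
        fh.write(f"Cohen's kappa: {k['mean']:.3f} +/- {k['sd']:.3f} (n={int(k['n'])})\n")
        fh.write(f"Accuracy:      {a['mean']:.2f} +/- {a['sd']:.2f} %\n")
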