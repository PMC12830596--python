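"""Benchmarking classifiers against ground truth and against each other.

Per-section Cohen's kappa (method vs ground truth), Fleiss' kappa
(inter-investigator agreement), binary confusion metrics in the
deficient/not-deficient framing, and a fibre-count-weighted section-level
bootstrap producing means with 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionSummary",
    "AgreementStats",
    "cohen_kappa",
    "fleiss_kappa",
    "confusion_metrics",
    "weighted_bootstrap_summary",
    "benchmark_sections",
]


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: ``(p_o - p_e) / (1 - p_e)``.

    ``p_e`` is chance agreement from the two raters' marginal label
    frequencies.  When ``p_e == 1`` (both raters constant) the statistic is
    undefined; by convention this returns 1.0 when the vectors agree and
    ``nan`` otherwise.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    if a.size == 0:
        raise ValueError("label vectors must be non-empty")
    cats = np.union1d(a, b)
    p_o = float((a == b).mean())
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    p_e = float((pa * pb).sum())
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def fleiss_kappa(label_matrix) -> float:
    """Fleiss' kappa for an items x raters label matrix.

    Standard formulation over the categories present: per-item agreement
    ``P_i = (sum_j n_ij^2 - k) / (k (k - 1))``, chance agreement
    ``P_e = sum_j p_j^2``.  Perfect unanimity with >= 2 categories present
    gives 1; with a single category present the statistic is undefined and
    ``nan`` is returned.
    """
    m = np.asarray(label_matrix)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an items x raters matrix with at least 2 raters")
    n_items, k = m.shape
    cats = np.unique(m)
    counts = np.stack([(m == c).sum(axis=1) for c in cats], axis=1)  # items x cats
    p_j = counts.sum(axis=0) / (n_items * k)
    p_i = ((counts ** 2).sum(axis=1) - k) / (k * (k - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0:
        return float("nan")
    return (p_bar - p_e) / (1.0 - p_e)


@dataclass
class ConfusionSummary:
    """Binary deficient-vs-not confusion counts and derived rates.

    Undefined ratios (zero denominator) are ``None``, not 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def fpr(self) -> float | None:
        return self._ratio(self.fp, self.fp + self.tn)

    @property
    def fnr(self) -> float | None:
        return self._ratio(self.fn, self.fn + self.tp)

    @property
    def f1(self) -> float | None:
        p, s = self.ppv, self.sensitivity
        if p is None or s is None or (p + s) == 0:
            return None
        return 2.0 * p * s / (p + s)


def confusion_metrics(predicted_deficient, truth_deficient) -> ConfusionSummary:
    """Confusion summary for boolean deficient calls against boolean truth."""
    pred = np.asarray(predicted_deficient, dtype=bool)
    truth = np.asarray(truth_deficient, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same length")
    if pred.size == 0:
        raise ValueError("empty benchmark set")
    return ConfusionSummary(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


@dataclass
class AgreementStats:
    """Fibre-count-weighted bootstrap summary of per-section statistics."""

    per_section: dict[str, float]
    weights: dict[str, float]
    weighted_mean: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_excluded: int = 0
    excluded_sections: list[str] = field(default_factory=list)


def weighted_bootstrap_summary(
    per_section_stats: dict[str, float],
    weights: dict[str, float],
    n_bootstrap: int = 10_000,
    seed: int | None = 0,
) -> AgreementStats:
    """Resample sections with replacement; weighted mean and 95% CI.

    Each iteration draws sections with replacement and computes the
    fibre-count-weighted mean of their statistics; the CI is the 2.5th-97.5th
    percentile of the bootstrap distribution.  Sections with undefined
    (None/NaN) statistics are excluded and counted.
    """
    keys, stats_, w = [], [], []
    excluded = []
    for k, v in per_section_stats.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            excluded.append(k)
            continue
        if weights[k] <= 0:
            raise ValueError(f"weight for section {k} must be > 0")
        keys.append(k)
        stats_.append(float(v))
        w.append(float(weights[k]))
    if not keys:
        raise ValueError("all per-section statistics are undefined")
    s = np.array(stats_)
    w = np.array(w)
    overall = float((s * w).sum() / w.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, s.size, size=(n_bootstrap, s.size))
    bw = w[idx]
    means = (s[idx] * bw).sum(axis=1) / bw.sum(axis=1)
    ci_low, ci_high = np.quantile(means, [0.025, 0.975])
    return AgreementStats(
        per_section=dict(zip(keys, stats_)),
        weights=dict(zip(keys, w.tolist())),
        weighted_mean=overall,
        ci_low=float(min(ci_low, overall)),
        ci_high=float(max(ci_high, overall)),
        n_bootstrap=n_bootstrap,
        n_excluded=len(excluded),
        excluded_sections=excluded,
    )


def benchmark_sections(
    calls: pd.DataFrame,
    fibres: pd.DataFrame,
    protein: str,
    restrict_to_ground_truth: bool = True,
    three_category: bool = False,
) -> pd.DataFrame:
    """Per-section benchmark of final calls against ground-truth labels.

    ``calls`` must carry ``fibre_id`` and either ``final_call`` or ``label``;
    ``fibres`` supplies ``section``, ``true_<protein>`` and (by default) the
    ``in_ground_truth_region`` restriction, mirroring a study design where
    only a mapped region per section is truth-labelled.

    Returns one row per section: ``kappa, fpr, fnr, ppv, sensitivity, f1,
    n_fibres`` (rates as proportions; undefined values as NaN).  Kappa is
    binary deficient/not-deficient by default; ``three_category`` keeps the
    full -1/0/+1 label set.
    """
    merged = fibres.merge(calls, on="fibre_id", how="inner", validate="one_to_one")
    if restrict_to_ground_truth:
        merged = merged[merged["in_ground_truth_region"]]
    if len(merged) == 0:
        raise ValueError("empty benchmark set")
    if "final_call" in merged.columns:
        pred_label = np.where(merged["final_call"] == "deficient", -1,
                              np.where(merged["final_call"] == "overabundant", 1, 0))
    else:
        pred_label = merged["label"].to_numpy(dtype=int)
    truth_label = merged[f"true_{protein}"].to_numpy(dtype=int)

    rows = []
    for section, grp_idx in merged.groupby("section", sort=True).indices.items():
        p = pred_label[grp_idx]
        t = truth_label[grp_idx]
        if three_category:
            kappa = cohen_kappa(p, t)
        else:
            kappa = cohen_kappa(p == -1, t == -1)
        cm = confusion_metrics(p == -1, t == -1)
        degenerate = np.unique(np.concatenate([p, t])).size == 1
        rows.append({
            "section": section,
            "kappa": kappa,
            "kappa_degenerate": degenerate,
            "fpr": np.nan if cm.fpr is None else cm.fpr,
            "fnr": np.nan if cm.fnr is None else cm.fnr,
            "ppv": np.nan if cm.ppv is None else cm.ppv,
            "sensitivity": np.nan if cm.sensitivity is None else cm.sensitivity,
            "f1": np.nan if cm.f1 is None else cm.f1,
            "n_fibres": len(grp_idx),
        })
    return pd.DataFrame(rows)
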