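"""Anatomically structured paired-difference variability estimation.

Per-section bootstrap distributions of deficient (or overabundant) fibre
proportions are paired under six anatomical strategies of increasing
distance — within a section triplet, across the two segments of an L-split
biopsy, across biopsies within one muscle (pooled, or restricted to QD/TA),
and between muscles — always within one patient, pooled across patients.
Random pairs of values are subtracted over many iterations and the absolute
differences summarised as median, IQR, 2.5th-97.5th percentiles and full
range.  The 97.5th percentile is the variability threshold: only an observed
longitudinal difference strictly exceeding it should be read as
time-dependent change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRATEGIES",
    "SectionProportionDistribution",
    "DifferenceDistribution",
    "VariabilitySummary",
    "bootstrap_section_proportions",
    "enumerate_pairs",
    "sample_abs_differences",
    "summarize_distribution",
    "threshold_report",
    "exceeds_threshold",
]

#: pairing strategies in order of increasing anatomical distance
STRATEGIES = (
    "intra_biopsy",
    "intra_l_split",
    "intra_muscle",
    "intra_QD",
    "intra_TA",
    "inter_muscle",
)


@dataclass
class SectionProportionDistribution:
    """Bootstrap distribution of one section's phenotype proportion.

    Each draw resamples the section's classified fibres with replacement and
    records the proportion carrying the phenotype — distributionally
    Binomial(n, p_hat)/n, which is how the draws are generated.
    """

    section: str
    protein: str
    phenotype: str
    draws: np.ndarray
    n_fibres: int

    @property
    def n_draws(self) -> int:
        return self.draws.size


@dataclass
class DifferenceDistribution:
    """Absolute paired differences for one pairing strategy and metric."""

    strategy: str
    metric: str
    values: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.values.size


@dataclass
class VariabilitySummary:
    """Quantile summary of a difference distribution (metric units)."""

    median: float
    iqr_low: float
    iqr_high: float
    p2_5: float
    p97_5: float
    min: float
    max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "median": self.median, "iqr_low": self.iqr_low, "iqr_high": self.iqr_high,
            "p2_5": self.p2_5, "p97_5": self.p97_5, "min": self.min, "max": self.max,
        }


def bootstrap_section_proportions(
    is_phenotype: Sequence[bool] | np.ndarray,
    section: str = "",
    protein: str = "",
    phenotype: str = "deficient",
    n_draws: int = 10_000,
    seed: int | None = 0,
) -> SectionProportionDistribution:
    """Bootstrap the proportion of phenotype fibres in one section.

    ``is_phenotype`` is one boolean per classified fibre.  Resampling n
    fibres with replacement and taking the phenotype proportion is exactly
    Binomial(n, p_hat)/n, which is drawn directly.
    """
    flags = np.asarray(is_phenotype, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError(f"section {section!r} has no classified fibres")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    p_hat = flags.mean()
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, p_hat, size=n_draws) / n
    return SectionProportionDistribution(
        section=section, protein=protein, phenotype=phenotype,
        draws=draws, n_fibres=n,
    )


def _section_table(meta: pd.DataFrame, unit: str) -> pd.DataFrame:
    required = {"patient", "muscle", "biopsy"} | ({"section"} if unit == "section" else set())
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    cols = ["patient", "muscle", "biopsy"] + (["section"] if unit == "section" else [])
    return meta[cols].drop_duplicates().reset_index(drop=True)


def enumerate_pairs(
    meta: pd.DataFrame,
    strategy: str,
    unit: str = "section",
    l_split_pairs: Sequence[tuple[str, str, float]] = (),
) -> list[tuple[str, str]]:
    """All eligible unordered unit pairs under one pairing strategy.

    ``meta`` is a table with one row per section (or biopsy) carrying
    ``patient, muscle, biopsy`` and, for section-level pairing, ``section``.
    All strategies pair within-patient and pool across patients.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if unit not in ("section", "biopsy"):
        raise ValueError("unit must be 'section' or 'biopsy'")
    tab = _section_table(meta, unit)
    uid = tab["section"] if unit == "section" else tab["biopsy"]
    tab = tab.assign(uid=uid.to_numpy())

    pairs: list[tuple[str, str]] = []

    def cross(a: Sequence[str], b: Sequence[str]):
        pairs.extend((x, y) for x in a for y in b if x != y)

    if strategy == "intra_biopsy":
        if unit != "section":
            raise ValueError("intra_biopsy pairing requires section-level units")
        for _, grp in tab.groupby(["patient", "biopsy"]):
            u = list(grp["uid"])
            pairs.extend((u[i], u[j]) for i in range(len(u)) for j in range(i + 1, len(u)))
    elif strategy == "intra_l_split":
        if not l_split_pairs:
            raise ValueError("intra_l_split pairing requires recorded L-split links")
        by_biopsy = {b: list(g["uid"]) for b, g in tab.groupby("biopsy")}
        for a, b, _dist in l_split_pairs:
            if a not in by_biopsy or b not in by_biopsy:
                raise ValueError(f"L-split pair ({a}, {b}) not present in metadata")
            if unit == "biopsy":
                pairs.append((a, b))
            else:
                cross(by_biopsy[a], by_biopsy[b])
    elif strategy in ("intra_muscle", "intra_QD", "intra_TA"):
        sub = tab
        if strategy != "intra_muscle":
            sub = tab[tab["muscle"] == strategy.split("_")[1]]
        for _, grp in sub.groupby(["patient", "muscle"]):
            by_biopsy = {b: list(g["uid"]) for b, g in grp.groupby("biopsy")}
            bids = sorted(by_biopsy)
            for i in range(len(bids)):
                for j in range(i + 1, len(bids)):
                    if unit == "biopsy":
                        pairs.append((bids[i], bids[j]))
                    else:
                        cross(by_biopsy[bids[i]], by_biopsy[bids[j]])
    elif strategy == "inter_muscle":
        for _, grp in tab.groupby("patient"):
            muscles = sorted(grp["muscle"].unique())
            for i in range(len(muscles)):
                for j in range(i + 1, len(muscles)):
                    a = list(grp.loc[grp["muscle"] == muscles[i], "uid"])
                    b = list(grp.loc[grp["muscle"] == muscles[j], "uid"])
                    pairs.extend((x, y) for x in a for y in b)
    return pairs


def sample_abs_differences(
    distributions: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]],
    n_iterations: int = 1_000_000,
    seed: int | None = 0,
    strategy: str = "",
    metric: str = "",
) -> DifferenceDistribution:
    """Absolute differences from random pair-then-draw sampling.

    Each iteration picks a pair uniformly at random, draws one value from
    each unit's distribution uniformly with replacement and records |a - b|.
    Deterministic given the seed.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    for a, b in pairs:
        for u in (a, b):
            if u not in distributions or len(np.atleast_1d(distributions[u])) == 0:
                raise ValueError(f"unit {u!r} has no distribution values")
    rng = np.random.default_rng(seed)
    counts = np.bincount(rng.integers(0, len(pairs), size=n_iterations), minlength=len(pairs))
    values = np.empty(n_iterations, dtype=float)
    pos = 0
    for (a, b), c in zip(pairs, counts):
        if c == 0:
            continue
        va = np.atleast_1d(np.asarray(distributions[a], dtype=float))
        vb = np.atleast_1d(np.asarray(distributions[b], dtype=float))
        da = va[rng.integers(0, va.size, size=c)]
        db = vb[rng.integers(0, vb.size, size=c)]
        values[pos:pos + c] = np.abs(da - db)
        pos += c
    return DifferenceDistribution(strategy=strategy, metric=metric, values=values)


def summarize_distribution(dist: DifferenceDistribution | np.ndarray) -> VariabilitySummary:
    """Median, IQR, 2.5-97.5 percentiles and full range.

    Quantiles use linear interpolation between order statistics, so printed
    summaries are reproducible bit-for-bit given a seed.
    """
    values = dist.values if isinstance(dist, DifferenceDistribution) else np.asarray(dist, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty distribution")
    q = np.quantile(values, [0.025, 0.25, 0.5, 0.75, 0.975], method="linear")
    return VariabilitySummary(
        median=float(q[2]), iqr_low=float(q[1]), iqr_high=float(q[3]),
        p2_5=float(q[0]), p97_5=float(q[4]),
        min=float(values.min()), max=float(values.max()),
    )


def exceeds_threshold(observed_difference: float, threshold: float) -> bool:
    """Strict rule: a longitudinal difference is flagged as exceeding
    expected variability only when strictly greater than the threshold."""
    return observed_difference > threshold


def threshold_report(
    summaries: Mapping[tuple[str, str], VariabilitySummary],
    strategies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Time-dependent-change thresholds (97.5th percentiles) per metric/strategy.

    ``summaries`` maps ``(metric, strategy)`` to a summary.  Raises when a
    requested strategy is missing for some metric.
    """
    metrics = sorted({m for m, _ in summaries})
    rows = []
    for metric in metrics:
        available = [s for m, s in summaries if m == metric]
        wanted = available if strategies is None else list(strategies)
        wanted = sorted(wanted, key=lambda s: STRATEGIES.index(s) if s in STRATEGIES else 99)
        for strategy in wanted:
            if (metric, strategy) not in summaries:
                raise ValueError(f"missing summary for metric {metric!r}, strategy {strategy!r}")
            s = summaries[(metric, strategy)]
            rows.append({
                "metric": metric, "strategy": strategy,
                "median": s.median, "iqr_low": s.iqr_low, "iqr_high": s.iqr_high,
                "p2_5": s.p2_5, "threshold_p97_5": s.p97_5,
                "min": s.min, "max": s.max,
            })
    return pd.DataFrame(rows)
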