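"""Staged-bootstrap qPCR mtDNA copy number and pyrosequencing heteroplasmy.

mtDNA copy number per nucleus is MT-ND1 copies divided by half the B2M
copies (B2M is diploid-nuclear).  Standard curves (Cq linear in
log10 copies) are bootstrapped by resampling one Cq per dilution with
replacement; curve models are then randomly paired with within-biopsy Cq
replicates to back-calculate copies via ``10^((Cq - intercept) / slope)``,
yielding a combinatorial per-biopsy distribution of MT-ND1/(B2M/2) whose
median is the reported copy number.

Heteroplasmy (% mutated mtDNA) is summarised as the mean of pyrosequencing
triplicates, with a pooled SD across patient groups as the replication-noise
diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mitovar.cohort import PyroseqRecord

__all__ = [
    "StandardCurveFit",
    "CurveSet",
    "McnDistribution",
    "HeteroplasmyEstimate",
    "bootstrap_standard_curves",
    "estimate_mtdnacn",
    "heteroplasmy_mean",
    "pooled_sd",
]


@dataclass
class StandardCurveFit:
    """One fitted standard curve: Cq = intercept + slope * log10(copies)."""

    target: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency diagnostic, ``10^(-1/slope) - 1``."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies(self, cq):
        """Back-calculate template copies from a quantification cycle."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


@dataclass
class CurveSet:
    """Bootstrap ensemble of standard-curve fits for one target."""

    target: str
    slopes: np.ndarray
    intercepts: np.ndarray
    r_squared: np.ndarray

    @property
    def n_models(self) -> int:
        return self.slopes.size

    def __getitem__(self, i: int) -> StandardCurveFit:
        return StandardCurveFit(self.target, float(self.slopes[i]),
                                float(self.intercepts[i]), float(self.r_squared[i]))


@dataclass
class McnDistribution:
    """Per-biopsy combinatorial distribution of mtDNA copies per nucleus."""

    biopsy: str
    values: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.values.size

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def summary(self) -> dict[str, float]:
        q = np.quantile(self.values, [0.025, 0.5, 0.975])
        return {"p2_5": float(q[0]), "median": float(q[1]), "p97_5": float(q[2])}


@dataclass
class HeteroplasmyEstimate:
    """Mean of one biopsy's pyrosequencing triplicate (percent)."""

    biopsy: str
    replicates: list[float]
    mean: float


def bootstrap_standard_curves(
    dilution_series: Sequence[tuple[float, Sequence[float]]],
    target: str = "",
    n_models: int = 100_000,
    seed: int | None = 0,
) -> CurveSet:
    """Bootstrap standard-curve fits by resampling Cq replicates per dilution.

    Each iteration draws one Cq with replacement from every dilution's
    replicates and fits Cq ~ log10(copies) by OLS.  Deterministic given the
    seed.
    """
    if len(dilution_series) < 3:
        raise ValueError("need at least 3 dilutions to fit a standard curve")
    copies = np.array([c for c, _ in dilution_series], dtype=float)
    if (copies <= 0).any():
        raise ValueError("dilution copies must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("all dilution copies are equal; slope is unidentifiable")
    reps = [np.asarray(r, dtype=float) for _, r in dilution_series]
    if any(r.size < 1 for r in reps):
        raise ValueError("every dilution needs at least one Cq replicate")

    rng = np.random.default_rng(seed)
    d = len(reps)
    cq = np.empty((n_models, d))
    for j, r in enumerate(reps):
        cq[:, j] = r[rng.integers(0, r.size, size=n_models)] if r.size > 1 else r[0]

    xm = x.mean()
    ssx = ((x - x.mean()) ** 2).sum()
    ym = cq.mean(axis=1)
    sxy = ((x - xm)[None, :] * (cq - ym[:, None])).sum(axis=1)
    slopes = sxy / ssx
    intercepts = ym - slopes * xm
    ssy = ((cq - ym[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ssy > 0, slopes ** 2 * ssx / ssy, 1.0)
    return CurveSet(target=target, slopes=slopes, intercepts=intercepts, r_squared=r2)


_REDRAW_CAP = 100


def estimate_mtdnacn(
    biopsy_cq: Mapping[str, Sequence[float]],
    curves: Mapping[str, CurveSet],
    biopsy: str = "",
    n_iterations: int = 100_000,
    seed: int | None = 0,
    nd1_target: str = "MT-ND1",
    b2m_target: str = "B2M",
) -> McnDistribution:
    """Combinatorial mtDNAcn distribution for one biopsy.

    Per iteration one curve model and one Cq replicate are drawn
    independently per target; copies are back-calculated and the iteration's
    value is ``ND1 / (B2M / 2)``.  Drawn curves with non-negative slope are
    rejected and redrawn (capped).
    """
    copies = {}
    rng = np.random.default_rng(seed)
    for tgt in (nd1_target, b2m_target):
        cqs = np.asarray(biopsy_cq[tgt], dtype=float)
        if cqs.size < 1:
            raise ValueError(f"{biopsy}: no Cq replicates for {tgt}")
        cs = curves[tgt]
        if cs.n_models < 1:
            raise ValueError(f"empty curve set for {tgt}")
        ci = rng.integers(0, cs.n_models, size=n_iterations)
        for _ in range(_REDRAW_CAP):
            bad = cs.slopes[ci] >= 0
            if not bad.any():
                break
            ci[bad] = rng.integers(0, cs.n_models, size=int(bad.sum()))
        else:
            raise RuntimeError(f"{tgt}: could not draw curves with negative slope")
        qi = rng.integers(0, cqs.size, size=n_iterations)
        copies[tgt] = 10.0 ** ((cqs[qi] - cs.intercepts[ci]) / cs.slopes[ci])
    values = copies[nd1_target] / (copies[b2m_target] / 2.0)
    return McnDistribution(biopsy=biopsy, values=values)


def heteroplasmy_mean(record: PyroseqRecord, allow_partial: bool = False) -> HeteroplasmyEstimate:
    """Per-biopsy heteroplasmy as the arithmetic mean of the triplicate."""
    reps = list(record.replicates)
    if len(reps) != 3:
        if allow_partial and len(reps) >= 2:
            warnings.warn(
                f"{record.biopsy}: {len(reps)} replicates instead of 3", UserWarning,
            )
        else:
            raise ValueError(f"{record.biopsy}: expected 3 replicates, got {len(reps)}")
    if not all(0.0 <= r <= 100.0 for r in reps):
        raise ValueError("heteroplasmy replicates must be in [0, 100]")
    return HeteroplasmyEstimate(biopsy=record.biopsy, replicates=reps, mean=float(np.mean(reps)))


def pooled_sd(groups: Sequence[Sequence[float]]) -> float:
    """Pooled SD: sqrt of the df-weighted average of group variances.

    Groups with fewer than two values carry no degrees of freedom and are
    skipped; at least one group must have >= 2 values.
    """
    num = 0.0
    dof = 0
    for g in groups:
        v = np.asarray(g, dtype=float)
        if v.size < 2:
            continue
        num += (v.size - 1) * v.var(ddof=1)
        dof += v.size - 1
    if dof == 0:
        raise ValueError("pooled SD needs at least one group with >= 2 values")
    return math.sqrt(num / dof)
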