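"""Single-fibre OXPHOS classification.

Two methods, both producing per-fibre certainty scores in [-1, +1] and a
trichotomous final call:

* **Frequentist prediction-interval method** — a linear regression of OXPHOS
  on VDAC1 is fitted to batch-specific control fibres; the 95% prediction
  interval defines the normal range.  Controls are bootstrapped with
  replacement to produce many regression models; each model labels a patient
  fibre -1 (below the band), 0 (inside) or +1 (above), and the certainty
  score is the mean label across models.

* **2D-mitoplot polygon method** — investigators lasso clusters of fibres
  with relatively low (or high) OXPHOS signal on OXPHOS-VDAC1 scatter plots;
  fibres inside a "low" polygon get -1, inside a "high" polygon +1, else 0.
  Inter-investigator labels are bootstrapped (investigators drawn with
  replacement) and the certainty score is the mean over resamples.

Under both methods a fibre is called *deficient* when its mean label is
<= -0.95 (95% of models/resamples concur) and *overabundant* when >= +0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionBand",
    "PolygonAnnotation",
    "fit_control_regression",
    "classify_frequentist",
    "classify_by_polygons",
    "consensus_certainty",
    "small_section_flags",
    "final_call",
    "MIN_FIBRES_PER_SECTION",
]

#: below this fibre count per section, deficiency estimates are flagged as
#: unstable (about 100 fibres are needed for confident classification)
MIN_FIBRES_PER_SECTION = 100

_DEGENERATE_RETRIES = 100


@dataclass
class PredictionBand:
    """OLS fit of OXPHOS on VDAC1 with a t-based prediction interval.

    The band at ``x`` is ``fit(x) +/- t_{1-(1-level)/2, n-2} * s *
    sqrt(1 + 1/n + (x - x_mean)^2 / x_ss)`` where ``s`` is the residual SD.
    """

    slope: float
    intercept: float
    residual_sd: float
    n_control: int
    x_mean: float
    x_ss: float
    level: float = 0.95

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray, level: float = 0.95) -> "PredictionBand":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3:
            raise ValueError("need at least 3 control fibres to fit a prediction band")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("control intensities must be finite")
        x_mean = x.mean()
        x_ss = float(((x - x_mean) ** 2).sum())
        if x_ss <= 0:
            raise ValueError("degenerate predictor: all VDAC1 values are equal")
        slope = float(((x - x_mean) * (y - y.mean())).sum() / x_ss)
        intercept = float(y.mean() - slope * x_mean)
        resid = y - (intercept + slope * x)
        residual_sd = float(np.sqrt((resid ** 2).sum() / (x.size - 2)))
        return cls(slope=slope, intercept=intercept, residual_sd=residual_sd,
                   n_control=int(x.size), x_mean=float(x_mean), x_ss=x_ss, level=level)

    # -- interval --------------------------------------------------------
    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def halfwidth(self, x):
        x = np.asarray(x, dtype=float)
        tcrit = stats.t.ppf(1.0 - (1.0 - self.level) / 2.0, self.n_control - 2)
        return tcrit * self.residual_sd * np.sqrt(
            1.0 + 1.0 / self.n_control + (x - self.x_mean) ** 2 / self.x_ss
        )

    def lower(self, x):
        return self.predict(x) - self.halfwidth(x)

    def upper(self, x):
        return self.predict(x) + self.halfwidth(x)

    def classify(self, x, y):
        """Label observations -1 (below band), 0 (inside) or +1 (above)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lo, hi = self.lower(x), self.upper(x)
        return np.where(y < lo, -1, np.where(y > hi, 1, 0))


@dataclass
class PolygonAnnotation:
    """One investigator's lasso polygon in (VDAC1, OXPHOS) space.

    ``category`` is ``"low"`` (fibres inside are labelled -1) or ``"high"``
    (+1); ``scope`` is the section the polygon applies to.
    """

    investigator: str
    protein: str
    scope: str
    category: str
    vertices: list[tuple[float, float]]

    def validate(self) -> None:
        if self.category not in ("low", "high"):
            raise ValueError(f"unknown polygon category {self.category!r}")
        if len(self.vertices) < 3:
            raise ValueError("polygons need at least 3 vertices")
        from shapely.geometry import Polygon
        if not Polygon(self.vertices).is_simple:
            raise ValueError("polygon is self-intersecting")

    @property
    def label(self) -> int:
        return -1 if self.category == "low" else +1


def fit_control_regression(controls: pd.DataFrame, protein: str,
                           level: float = 0.95, log_scale: bool = False) -> PredictionBand:
    """Fit the control OXPHOS ~ VDAC1 prediction band for one protein.

    ``controls`` needs a ``vdac1`` column and one intensity column named
    after the protein.  With ``log_scale`` both axes are log10-transformed
    before fitting (intensities must then be > 0).
    """
    x = controls["vdac1"].to_numpy(dtype=float)
    y = controls[protein].to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[mask], y[mask]
    if log_scale:
        x, y = np.log10(x), np.log10(y)
    return PredictionBand.fit(x, y, level=level)


def final_call(mean_label: np.ndarray, certainty_threshold: float = 0.95) -> np.ndarray:
    """Map certainty scores to deficient / normal / overabundant calls.

    Calls are non-strict: ``deficient`` iff mean label <= -threshold,
    ``overabundant`` iff >= +threshold, else ``normal``.
    """
    mean_label = np.asarray(mean_label, dtype=float)
    return np.where(mean_label <= -certainty_threshold, "deficient",
                    np.where(mean_label >= certainty_threshold, "overabundant", "normal"))


def _bootstrap_mean_labels(xc, yc, xp, yp, n_models, level, rng, chunk=500):
    """Mean -1/0/+1 label per patient fibre over bootstrapped control fits."""
    n = xc.size
    tcrit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, n - 2)
    acc = np.zeros(xp.size, dtype=float)
    done = 0
    while done < n_models:
        c = min(chunk, n_models - done)
        idx = rng.integers(0, n, size=(c, n))
        for _ in range(_DEGENERATE_RETRIES + 1):
            xs = xc[idx]
            sx = xs.sum(axis=1)
            xm = sx / n
            ssx = (xs * xs).sum(axis=1) - n * xm ** 2
            bad = ssx <= 1e-12
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        ys = yc[idx]
        ym = ys.sum(axis=1) / n
        sxy_c = (xs * ys).sum(axis=1) - n * xm * ym
        syy_c = (ys * ys).sum(axis=1) - n * ym ** 2
        slope = sxy_c / ssx
        intercept = ym - slope * xm
        rss = np.clip(syy_c - slope * sxy_c, 0.0, None)
        resid_sd = np.sqrt(rss / (n - 2))
        pred = intercept[:, None] + slope[:, None] * xp[None, :]
        hw = tcrit * resid_sd[:, None] * np.sqrt(
            1.0 + 1.0 / n + (xp[None, :] - xm[:, None]) ** 2 / ssx[:, None]
        )
        lab = np.where(yp[None, :] < pred - hw, -1, np.where(yp[None, :] > pred + hw, 1, 0))
        acc += lab.sum(axis=0)
        done += c
    return acc / n_models


def classify_frequentist(
    patient_fibres: pd.DataFrame,
    control_fibres: pd.DataFrame,
    protein: str,
    n_models: int = 10_000,
    certainty_threshold: float = 0.95,
    seed: int | None = 0,
    level: float = 0.95,
    log_scale: bool = False,
    batch_col: str | None = None,
) -> pd.DataFrame:
    """Bootstrapped prediction-interval classification of patient fibres.

    Controls are resampled with replacement ``n_models`` times (resample size
    equals the control count); each resample's prediction band labels every
    patient fibre -1/0/+1 and the per-fibre certainty score is the mean label
    across models.  Fits are batch-specific when ``batch_col`` is given (or a
    ``batch`` column is present in both tables).

    Returns a table with ``fibre_id, protein, mean_label, n_resamples,
    final_call``, in the input fibre order.
    """
    if len(patient_fibres) == 0:
        raise ValueError("no patient fibres to classify")
    if batch_col is None and "batch" in patient_fibres.columns and "batch" in control_fibres.columns:
        batch_col = "batch"
    rng = np.random.default_rng(seed)

    if "section" in patient_fibres.columns:
        small = small_section_flags(patient_fibres)
        if small:
            warnings.warn(
                f"{len(small)} section(s) have fewer than {MIN_FIBRES_PER_SECTION} "
                "fibres; deficiency proportions may be unstable", UserWarning,
            )

    def one_batch(pat: pd.DataFrame, ctl: pd.DataFrame) -> np.ndarray:
        xc = ctl["vdac1"].to_numpy(dtype=float)
        yc = ctl[protein].to_numpy(dtype=float)
        mask = np.isfinite(xc) & np.isfinite(yc) & (xc > 0) & (yc > 0)
        xc, yc = xc[mask], yc[mask]
        if xc.size < 3:
            raise ValueError("need at least 3 control fibres per batch")
        if np.ptp(xc) == 0:
            raise ValueError("degenerate predictor: all control VDAC1 values equal")
        xp = pat["vdac1"].to_numpy(dtype=float)
        yp = pat[protein].to_numpy(dtype=float)
        if log_scale:
            xc, yc, xp, yp = np.log10(xc), np.log10(yc), np.log10(xp), np.log10(yp)
        return _bootstrap_mean_labels(xc, yc, xp, yp, n_models, level, rng)

    mean_label = np.empty(len(patient_fibres), dtype=float)
    if batch_col is None:
        mean_label[:] = one_batch(patient_fibres, control_fibres)
    else:
        pos = np.arange(len(patient_fibres))
        for batch, pat in patient_fibres.groupby(batch_col, sort=True):
            ctl = control_fibres[control_fibres[batch_col] == batch]
            if len(ctl) == 0:
                raise ValueError(f"no control fibres for batch {batch!r}")
            mean_label[pos[(patient_fibres[batch_col] == batch).to_numpy()]] = one_batch(pat, ctl)

    return pd.DataFrame({
        "fibre_id": patient_fibres["fibre_id"].to_numpy(),
        "protein": protein,
        "mean_label": mean_label,
        "n_resamples": n_models,
        "final_call": final_call(mean_label, certainty_threshold),
    })


def classify_by_polygons(
    fibres: pd.DataFrame,
    annotations: list[PolygonAnnotation],
    protein: str,
) -> pd.DataFrame:
    """Label fibres by one investigator's polygons (even-odd, boundary-inclusive).

    A fibre inside any "low" polygon of its section gets -1, inside any
    "high" polygon +1, otherwise 0.  A fibre inside both a low and a high
    polygon is a contradictory annotation and raises.
    """
    import shapely
    from shapely.geometry import Polygon

    relevant = [a for a in annotations if a.protein == protein]
    for a in relevant:
        a.validate()
    by_scope: dict[str, dict[str, list[Polygon]]] = {}
    for a in relevant:
        by_scope.setdefault(a.scope, {"low": [], "high": []})[a.category].append(Polygon(a.vertices))

    labels = np.zeros(len(fibres), dtype=int)
    for section, sub in fibres.groupby("section", sort=False):
        polys = by_scope.get(section)
        if polys is None:
            continue
        pts = shapely.points(sub["vdac1"].to_numpy(dtype=float), sub[protein].to_numpy(dtype=float))
        in_low = np.zeros(len(sub), dtype=bool)
        for poly in polys["low"]:
            in_low |= shapely.covers(poly, pts)
        in_high = np.zeros(len(sub), dtype=bool)
        for poly in polys["high"]:
            in_high |= shapely.covers(poly, pts)
        both = in_low & in_high
        if both.any():
            bad = sub["fibre_id"].to_numpy()[both][:3]
            raise ValueError(
                f"contradictory annotation in section {section}: fibre(s) "
                f"{list(bad)} fall inside both a low and a high polygon"
            )
        labels[fibres.index.get_indexer(sub.index)] = in_high.astype(int) - in_low.astype(int)

    return pd.DataFrame({
        "fibre_id": fibres["fibre_id"].to_numpy(),
        "protein": protein,
        "label": labels,
    })


def consensus_certainty(
    label_tables: list[pd.DataFrame],
    n_resamples: int = 10_000,
    certainty_threshold: float = 0.95,
    seed: int | None = 0,
    resample: str = "investigators",
) -> pd.DataFrame:
    """Bootstrapped inter-investigator consensus certainty.

    Each resample draws investigators with replacement (size = number of
    investigators) and averages their -1/0/+1 labels per fibre; the certainty
    score is the mean over resamples — equivalently, a draw-count-weighted
    mean of the investigators' labels.  ``resample="labels"`` instead
    resamples each fibre's label multiset independently (sensitivity mode).
    """
    if len(label_tables) < 1:
        raise ValueError("need at least one investigator label table")
    if resample not in ("investigators", "labels"):
        raise ValueError("resample must be 'investigators' or 'labels'")
    ref = label_tables[0][["fibre_id", "protein"]]
    mats = [label_tables[0]["label"].to_numpy(dtype=float)]
    for t in label_tables[1:]:
        if len(t) != len(ref) or not (
            (t["fibre_id"].to_numpy() == ref["fibre_id"].to_numpy()).all()
            and (t["protein"].to_numpy() == ref["protein"].to_numpy()).all()
        ):
            raise ValueError("investigator label tables cover different fibre sets")
        mats.append(t["label"].to_numpy(dtype=float))
    labels = np.vstack(mats)  # investigators x fibres
    k, m = labels.shape
    rng = np.random.default_rng(seed)

    if resample == "investigators":
        draws = rng.integers(0, k, size=(n_resamples, k))
        weights = np.bincount(draws.ravel(), minlength=k) / (n_resamples * k)
        mean_label = weights @ labels
    else:
        counts = rng.multinomial(n_resamples * k, np.full(k, 1.0 / k), size=m)  # fibres x investigators
        mean_label = (counts * labels.T).sum(axis=1) / (n_resamples * k)

    return pd.DataFrame({
        "fibre_id": ref["fibre_id"].to_numpy(),
        "protein": ref["protein"].to_numpy(),
        "mean_label": mean_label,
        "n_resamples": n_resamples,
        "final_call": final_call(mean_label, certainty_threshold),
    })


def small_section_flags(fibres: pd.DataFrame, min_fibres: int = MIN_FIBRES_PER_SECTION) -> list[str]:
    """Sections with fewer fibres than needed for confident classification."""
    counts = fibres.groupby("section").size()
    return sorted(counts.index[counts < min_fibres])
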