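"""Seeded synthetic cohorts with the hierarchy patient > muscle > biopsy > section.

The generator emulates a multi-biopsy post-mortem study of m.3243A>G
myopathy: per-fibre quadruple-immunofluorescence intensities (VDAC1 plus one
or more OXPHOS proteins) for patients and controls, simulated-investigator
polygon annotations, qPCR plates (standard-curve dilution series plus
per-biopsy Cq replicates for MT-ND1 and B2M) and pyrosequencing heteroplasmy
triplicates.  Every fibre carries a ground-truth OXPHOS label so downstream
classifiers and benchmarks can be tested against exact truth.

Intensity model
---------------
Control fibres follow a linear OXPHOS ~ VDAC1 relationship with Gaussian
residuals.  Patient fibres follow the same line transformed by a systematic
patient-control disparity (multiplicative gain and additive offset) and by
per-section batch perturbations; OXPHOS-deficient fibres are displaced
downward by a fixed multiple of the control residual SD, overabundant fibres
upward symmetrically.

Mosaic deficiency
-----------------
The per-biopsy deficient proportion is ``logistic(patient mean + muscle
offset + W(position))`` where ``W`` is a Gaussian random walk over the
biopsy's position (mm) along the muscle, so deficiency drifts with anatomical
distance.  L-split biopsy pairs are two positions on the same walk separated
by the recorded inter-face distance.  Within a section the deficient count is
assigned deterministically as ``round(p * n)`` by default, so parameter
recovery tests have exact truth; a Bernoulli mode is available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ControlLine",
    "Disparity",
    "DeficiencyModel",
    "CohortDesign",
    "Cohort",
    "QPCRPlate",
    "PyroseqRecord",
    "generate_cohort",
    "generate_annotations",
    "generate_qpcr",
    "generate_pyroseq",
    "study_design",
    "unique_fibre_count",
]


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return math.log(p / (1.0 - p))


@dataclass
class ControlLine:
    """Control OXPHOS ~ VDAC1 relationship for one protein (arbitrary units)."""

    slope: float = 0.8
    intercept: float = 150.0
    residual_sd: float = 40.0


@dataclass
class Disparity:
    """Systematic patient-vs-control signal disparity for one protein.

    Applied as ``y_patient = multiplicative * y_control_line + additive``
    before section batch effects and residual noise.
    """

    additive: float = 0.0
    multiplicative: float = 1.0

    @property
    def is_identity(self) -> bool:
        return self.additive == 0.0 and self.multiplicative == 1.0


@dataclass
class DeficiencyModel:
    """Mosaic-deficiency parameters.

    ``mean_proportion`` maps protein -> mean deficient proportion (scalar, or
    one value per patient).  ``muscle_offset`` maps muscle -> logit offset.
    ``spatial_drift_sd`` is the SD of the logit random-walk increment per
    sqrt(mm) of anatomical distance.
    """

    mean_proportion: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"NDUFB8": 0.30, "MT-CO1": 0.09}
    )
    muscle_offset: Mapping[str, float] = field(
        default_factory=lambda: {"QD": 0.0, "TA": 0.25}
    )
    spatial_drift_sd: float = 0.05

    def patient_mean(self, protein: str, patient_index: int, n_patients: int) -> float:
        value = self.mean_proportion[protein]
        if np.isscalar(value):
            return float(value)
        values = list(value)
        if len(values) != n_patients:
            raise ValueError(
                f"per-patient deficiency proportions for {protein} must have "
                f"length {n_patients}, got {len(values)}"
            )
        return float(values[patient_index])


@dataclass
class CohortDesign:
    """Full specification of one synthetic cohort.

    ``biopsies_per_muscle`` may be a single count or a mapping
    ``(patient, muscle) -> count``.  ``l_split_pairs`` lists biopsy pairs that
    are the two segments of one original biopsy, with the known anatomical
    distance (mm) between their sectioned faces.
    """

    n_patients: int = 4
    muscles: tuple[str, ...] = ("QD", "TA")
    biopsies_per_muscle: int | Mapping[tuple[str, str], int] = 2
    l_split_pairs: Sequence[tuple[str, str, float]] = ()  # (biopsy_a, biopsy_b, mm)
    sections_per_biopsy: int = 3
    fibres_per_section: int = 1300
    proteins: tuple[str, ...] = ("NDUFB8", "MT-CO1")
    control: Mapping[str, ControlLine] = field(
        default_factory=lambda: {"NDUFB8": ControlLine(), "MT-CO1": ControlLine(slope=0.6, intercept=120.0, residual_sd=30.0)}
    )
    control_fibres: int = 2000
    vdac1_mean: float = 1000.0
    vdac1_sd: float = 200.0
    patient_disparity: Mapping[str, Disparity] = field(
        default_factory=lambda: {"NDUFB8": Disparity(multiplicative=0.95), "MT-CO1": Disparity(multiplicative=0.97)}
    )
    section_gain_sd: float = 0.05
    section_offset_sd: float = 15.0
    deficiency: DeficiencyModel = field(default_factory=DeficiencyModel)
    overabundance_rate: float = 0.0003
    deficient_shift: float = 8.0  # in units of control residual SD
    ground_truth_fraction: float = 0.05
    deterministic_assignment: bool = True
    biopsy_spacing_mm: float = 20.0
    seed: int = 0

    # -- validation ------------------------------------------------------
    def biopsies_for(self, patient: str, muscle: str) -> int:
        if isinstance(self.biopsies_per_muscle, Mapping):
            return int(self.biopsies_per_muscle[(patient, muscle)])
        return int(self.biopsies_per_muscle)

    def patient_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    def validate(self) -> None:
        if self.n_patients < 1 or self.sections_per_biopsy < 1 or self.fibres_per_section < 1:
            raise ValueError("all counts must be >= 1")
        if self.control_fibres < 3:
            raise ValueError("need at least 3 control fibres")
        if not (0.0 <= self.ground_truth_fraction <= 1.0):
            raise ValueError("ground_truth_fraction must be in [0, 1]")
        if not (0.0 <= self.overabundance_rate <= 1.0):
            raise ValueError("overabundance_rate must be in [0, 1]")
        biopsy_ids = set()
        for patient in self.patient_ids():
            for muscle in self.muscles:
                n_b = self.biopsies_for(patient, muscle)
                if n_b < 1:
                    raise ValueError("biopsies_per_muscle must be >= 1")
                for b in range(n_b):
                    biopsy_ids.add(f"{patient}_{muscle}_b{b + 1}")
        for a, b, dist in self.l_split_pairs:
            if dist <= 0:
                raise ValueError(f"L-split distance must be > 0, got {dist}")
            if a not in biopsy_ids or b not in biopsy_ids:
                raise ValueError(f"L-split pair ({a}, {b}) references unknown biopsies")
        any_deficiency = False
        for protein in self.proteins:
            if protein not in self.control:
                raise ValueError(f"no control line for protein {protein}")
            if protein not in self.deficiency.mean_proportion:
                raise ValueError(f"no deficiency proportion for protein {protein}")
            for i in range(self.n_patients):
                p = self.deficiency.patient_mean(protein, i, self.n_patients)
                if not (0.0 <= p <= 1.0):
                    raise ValueError("deficiency proportions must be in [0, 1]")
                if p + self.overabundance_rate > 1.0:
                    raise ValueError("deficiency + overabundance rate must be <= 1")
                if p > 0:
                    any_deficiency = True
        if any_deficiency and self.deficient_shift == 0.0:
            raise ValueError(
                "deficient_shift must be non-zero when deficiency proportion > 0 "
                "(the true labels would be unidentifiable from intensities)"
            )


@dataclass
class Cohort:
    """One realisation of a :class:`CohortDesign`.

    ``fibres`` has one row per patient fibre cross-section with columns
    ``fibre_id, patient, muscle, biopsy, section, batch, vdac1``, one
    intensity column per protein, one ``true_<protein>`` label column
    (-1 deficient / 0 normal / +1 overabundant) and
    ``in_ground_truth_region``.  ``controls`` has ``batch, vdac1`` plus
    intensity columns.  ``biopsies`` holds one row per biopsy with its
    position (mm) and true deficient proportions; ``meta`` carries L-split
    links and design echo.
    """

    design: CohortDesign
    fibres: pd.DataFrame
    controls: pd.DataFrame
    biopsies: pd.DataFrame
    meta: dict

    @property
    def sections(self) -> pd.DataFrame:
        cols = ["patient", "muscle", "biopsy", "section"]
        return self.fibres[cols].drop_duplicates().reset_index(drop=True)

    def true_section_proportions(self, protein: str, phenotype: str = "deficient") -> pd.Series:
        target = -1 if phenotype == "deficient" else +1
        lab = self.fibres[f"true_{protein}"] == target
        return lab.groupby(self.fibres["section"]).mean()


@dataclass
class QPCRPlate:
    """Synthetic qPCR plate: dilution series plus per-biopsy Cq replicates."""

    dilution_series: Mapping[str, list[tuple[float, list[float]]]]
    biopsy_cq: Mapping[str, Mapping[str, list[float]]]
    true_curve: Mapping[str, tuple[float, float]]  # target -> (slope, intercept)
    true_mtdnacn: Mapping[str, float]
    cq_noise_sd: float

    def validate(self) -> None:
        for target, series in self.dilution_series.items():
            if any(len(reps) < 1 for _, reps in series):
                raise ValueError(f"{target}: every dilution needs >= 1 replicate")
            copies = [c for c, _ in series]
            if any(b >= a for a, b in zip(copies, copies[1:])):
                raise ValueError(f"{target}: copies must be strictly decreasing")
            for _, reps in series:
                if not all(np.isfinite(r) and r > 0 for r in reps):
                    raise ValueError(f"{target}: Cq values must be finite and > 0")


@dataclass
class PyroseqRecord:
    """Pyrosequencing heteroplasmy triplicate for one biopsy (percent)."""

    biopsy: str
    replicates: list[float]
    true_heteroplasmy: float
    is_standard: bool = False

    def validate(self) -> None:
        if len(self.replicates) != 3:
            raise ValueError("pyrosequencing records carry exactly 3 replicates")
        if not all(0.0 <= r <= 100.0 for r in self.replicates):
            raise ValueError("heteroplasmy replicates must be in [0, 100]")


# ---------------------------------------------------------------------------
# factories


def study_design(fibres_per_section: int = 1300, seed: int = 0, **overrides) -> CohortDesign:
    """Design emulating a 4-patient, 31-biopsy QD/TA post-mortem cohort.

    Biopsy counts per patient and muscle are QD/TA = 5/5, 4/3, 6/5, 1/2;
    four L-split pairs have inter-face distances averaging ~14.4 mm.
    """
    counts = {
        ("P1", "QD"): 5, ("P1", "TA"): 5,
        ("P2", "QD"): 4, ("P2", "TA"): 3,
        ("P3", "QD"): 6, ("P3", "TA"): 5,
        ("P4", "QD"): 1, ("P4", "TA"): 2,
    }
    l_splits = (
        ("P1_QD_b1", "P1_QD_b2", 10.4),
        ("P1_TA_b1", "P1_TA_b2", 13.0),
        ("P3_QD_b1", "P3_QD_b2", 16.0),
        ("P3_TA_b1", "P3_TA_b2", 18.2),
    )
    kwargs = dict(
        n_patients=4,
        biopsies_per_muscle=counts,
        l_split_pairs=l_splits,
        fibres_per_section=fibres_per_section,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def unique_fibre_count(n_cross_sections: int, sections_per_triplet: int = 3) -> int:
    """Unique fibres represented by serial-section cross-section counts.

    Each fibre appears once per serial section, so ``n_cross_sections`` fibre
    segments over triplets of sections correspond to
    ``n_cross_sections / sections_per_triplet`` unique fibres.
    """
    if n_cross_sections % sections_per_triplet:
        raise ValueError("cross-section count is not a multiple of the triplet size")
    return n_cross_sections // sections_per_triplet


# ---------------------------------------------------------------------------
# fibre table generation


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _biopsy_positions(design: CohortDesign, patient: str, muscle: str) -> dict[str, float]:
    """Positions (mm) of a patient-muscle's biopsies along the muscle axis.

    Biopsies are spaced ``biopsy_spacing_mm`` apart; the second member of an
    L-split pair sits at its partner's position plus the recorded distance.
    """
    n_b = design.biopsies_for(patient, muscle)
    ids = [f"{patient}_{muscle}_b{b + 1}" for b in range(n_b)]
    split_of = {b: (a, d) for a, b, d in design.l_split_pairs}
    positions: dict[str, float] = {}
    cursor = 0.0
    for bid in ids:
        if bid in split_of and split_of[bid][0] in positions:
            positions[bid] = positions[split_of[bid][0]] + split_of[bid][1]
        else:
            positions[bid] = cursor
            cursor += design.biopsy_spacing_mm
    return positions


def generate_cohort(design: CohortDesign) -> Cohort:
    """Generate one synthetic cohort; deterministic given ``design.seed``."""
    design.validate()
    rng = np.random.default_rng(design.seed)

    # control fibres, per staining batch (one batch per patient)
    control_rows = []
    for patient in design.patient_ids():
        v = np.clip(rng.normal(design.vdac1_mean, design.vdac1_sd, design.control_fibres), 1.0, None)
        row = {"batch": patient, "vdac1": v}
        for protein in design.proteins:
            line = design.control[protein]
            row[protein] = np.clip(
                line.intercept + line.slope * v + rng.normal(0.0, line.residual_sd, design.control_fibres),
                0.01, None,
            )
        control_rows.append(pd.DataFrame(row))
    controls = pd.concat(control_rows, ignore_index=True)

    # per-biopsy deficient proportions via logit random walk over position
    biopsy_rows = []
    for pi, patient in enumerate(design.patient_ids()):
        for muscle in design.muscles:
            positions = _biopsy_positions(design, patient, muscle)
            ordered = sorted(positions, key=positions.get)
            for protein in design.proteins:
                base = design.deficiency.patient_mean(protein, pi, design.n_patients)
                base_logit = _logit(min(max(base, 1e-6), 1 - 1e-6))
                base_logit += design.deficiency.muscle_offset.get(muscle, 0.0)
                walk = 0.0
                prev_pos = None
                values = {}
                for bid in ordered:
                    pos = positions[bid]
                    if prev_pos is not None and design.deficiency.spatial_drift_sd > 0:
                        step_sd = design.deficiency.spatial_drift_sd * math.sqrt(pos - prev_pos) if pos > prev_pos else 0.0
                        walk += rng.normal(0.0, step_sd) if step_sd > 0 else 0.0
                    values[bid] = float(_logistic(base_logit + walk))
                    prev_pos = pos
                for bid in positions:
                    biopsy_rows.append({
                        "patient": patient, "muscle": muscle, "biopsy": bid,
                        "position_mm": positions[bid], "protein": protein,
                        "true_deficient_prop": values[bid],
                    })
    biopsy_long = pd.DataFrame(biopsy_rows)
    biopsies = biopsy_long.pivot_table(
        index=["patient", "muscle", "biopsy", "position_mm"],
        columns="protein", values="true_deficient_prop",
    ).rename(columns=lambda p: f"true_prop_{p}").reset_index()

    # fibre tables, one section at a time
    n = design.fibres_per_section
    fibre_frames = []
    fibre_counter = 0
    for _, brow in biopsies.iterrows():
        patient, muscle, bid = brow["patient"], brow["muscle"], brow["biopsy"]
        for s in range(design.sections_per_biopsy):
            sid = f"{bid}_s{s + 1}"
            v = np.clip(rng.normal(design.vdac1_mean, design.vdac1_sd, n), 1.0, None)
            gain = 1.0 + (rng.normal(0.0, design.section_gain_sd) if design.section_gain_sd > 0 else 0.0)
            offset = rng.normal(0.0, design.section_offset_sd) if design.section_offset_sd > 0 else 0.0
            rec = {
                "fibre_id": np.array([f"f{fibre_counter + i}" for i in range(n)]),
                "patient": patient, "muscle": muscle, "biopsy": bid,
                "section": sid, "batch": patient, "vdac1": v,
            }
            fibre_counter += n
            for protein in design.proteins:
                line = design.control[protein]
                disp = design.patient_disparity.get(protein, Disparity())
                p_def = float(brow[f"true_prop_{protein}"])
                if design.deterministic_assignment:
                    n_def = _round_half_up(p_def * n)
                    n_over = _round_half_up(design.overabundance_rate * n)
                else:
                    n_def = int(rng.binomial(n, p_def))
                    n_over = int(rng.binomial(n - n_def, design.overabundance_rate))
                labels = np.zeros(n, dtype=int)
                order = rng.permutation(n)
                labels[order[:n_def]] = -1
                labels[order[n_def:n_def + n_over]] = +1
                base = line.intercept + line.slope * v
                y = gain * (disp.multiplicative * base + disp.additive) + offset
                y = y + rng.normal(0.0, line.residual_sd, n)
                shift = design.deficient_shift * line.residual_sd
                y = np.where(labels == -1, y - shift, y)
                y = np.where(labels == +1, y + shift, y)
                rec[protein] = np.clip(y, 0.01, None)
                rec[f"true_{protein}"] = labels
            n_gt = _round_half_up(design.ground_truth_fraction * n)
            gt = np.zeros(n, dtype=bool)
            gt[:n_gt] = True  # index-contiguous block, emulating one mapped region
            rec["in_ground_truth_region"] = gt
            fibre_frames.append(pd.DataFrame(rec))
    fibres = pd.concat(fibre_frames, ignore_index=True)

    meta = {
        "schema": "mitovar-cohort/1",
        "l_split_pairs": [list(p) for p in design.l_split_pairs],
        "muscles": list(design.muscles),
        "proteins": list(design.proteins),
        "seed": design.seed,
    }
    return Cohort(design=design, fibres=fibres, controls=controls, biopsies=biopsies, meta=meta)


# ---------------------------------------------------------------------------
# simulated investigator annotations


def generate_annotations(
    cohort: Cohort,
    n_investigators: int = 3,
    boundary_jitter_sd: float = 0.0,
    seed: int = 0,
    margin_residual_sd: float = 0.5,
):
    """Simulate per-investigator lasso polygons around the true clusters.

    For each investigator, section and protein a "low" polygon is drawn as
    the convex hull of the truly deficient fibres in (VDAC1, OXPHOS) space,
    buffered outward by ``margin_residual_sd`` control residual SDs, with
    vertices perturbed by Gaussian jitter of SD ``boundary_jitter_sd``
    (intensity units).  A "high" polygon is drawn around truly overabundant
    fibres where present.  With zero jitter the polygons classify exactly the
    true labels.

    Returns a list of :class:`mitovar.classify.PolygonAnnotation`.
    """
    from shapely.geometry import MultiPoint
    from mitovar.classify import PolygonAnnotation

    if n_investigators < 1:
        raise ValueError("need at least one investigator")
    rng = np.random.default_rng(seed)
    annotations = []
    grouped = cohort.fibres.groupby("section", sort=True)
    for section, sub in grouped:
        if len(sub) == 0:
            raise ValueError(f"section {section} has no fibres")
        for protein in cohort.design.proteins:
            margin = margin_residual_sd * cohort.design.control[protein].residual_sd
            for category, target in (("low", -1), ("high", +1)):
                pts = sub.loc[sub[f"true_{protein}"] == target, ["vdac1", protein]].to_numpy()
                if len(pts) == 0:
                    continue
                hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(margin, quad_segs=4)
                base_vertices = np.asarray(hull.exterior.coords)[:-1]
                for inv in range(n_investigators):
                    verts = base_vertices
                    if boundary_jitter_sd > 0:
                        jittered = verts + rng.normal(0.0, boundary_jitter_sd, verts.shape)
                        # re-hull so the jittered outline stays a simple polygon
                        jhull = MultiPoint([tuple(p) for p in jittered]).convex_hull
                        if jhull.geom_type != "Polygon":
                            jhull = jhull.buffer(1e-6)
                        verts = np.asarray(jhull.exterior.coords)[:-1]
                    annotations.append(PolygonAnnotation(
                        investigator=f"I{inv + 1}",
                        protein=protein,
                        scope=section,
                        category=category,
                        vertices=[(float(x), float(y)) for x, y in verts],
                    ))
    return annotations


# ---------------------------------------------------------------------------
# qPCR and pyrosequencing generators


DEFAULT_DILUTION_COPIES = (1e7, 1e6, 1e5, 1e4, 1e3, 1e2)


def generate_qpcr(
    biopsies: Sequence[str],
    true_mtdnacn: Mapping[str, float],
    curve: Mapping[str, tuple[float, float]] | None = None,
    cq_noise_sd: float = 0.2,
    seed: int = 0,
    b2m_copies_per_reaction: float = 2000.0,
    dilution_copies: Sequence[float] = DEFAULT_DILUTION_COPIES,
    replicates_per_dilution: int = 6,
    replicates_per_biopsy: int = 6,
) -> QPCRPlate:
    """Simulate a qPCR plate consistent with per-biopsy true mtDNAcn.

    ``curve`` maps target -> (slope, intercept) of Cq vs log10(copies); the
    default slope -3.3219 corresponds to 100% amplification efficiency.
    MT-ND1 copies per reaction are ``mtDNAcn * (B2M / 2)`` so back-calculated
    copy numbers recover the truth exactly at zero noise.
    """
    if curve is None:
        curve = {"MT-ND1": (-3.3219, 38.0), "B2M": (-3.3219, 38.0)}
    for target, (slope, intercept) in curve.items():
        if not (np.isfinite(slope) and np.isfinite(intercept)):
            raise ValueError(f"{target}: curve parameters must be finite")
        if slope == 0:
            raise ValueError(f"{target}: slope must be non-zero")
    for b in biopsies:
        if not true_mtdnacn[b] > 0:
            raise ValueError(f"true mtDNAcn for {b} must be > 0")
    rng = np.random.default_rng(seed)

    def cq_of(target: str, copies: float, size: int) -> list[float]:
        slope, intercept = curve[target]
        mean = intercept + slope * math.log10(copies)
        noise = rng.normal(0.0, cq_noise_sd, size) if cq_noise_sd > 0 else np.zeros(size)
        return [float(c) for c in mean + noise]

    dilution_series = {
        target: [(float(c), cq_of(target, c, replicates_per_dilution)) for c in dilution_copies]
        for target in curve
    }
    biopsy_cq = {}
    for b in biopsies:
        nd1 = true_mtdnacn[b] * (b2m_copies_per_reaction / 2.0)
        biopsy_cq[b] = {
            "MT-ND1": cq_of("MT-ND1", nd1, replicates_per_biopsy),
            "B2M": cq_of("B2M", b2m_copies_per_reaction, replicates_per_biopsy),
        }
    plate = QPCRPlate(
        dilution_series=dilution_series,
        biopsy_cq=biopsy_cq,
        true_curve=dict(curve),
        true_mtdnacn={b: float(true_mtdnacn[b]) for b in biopsies},
        cq_noise_sd=cq_noise_sd,
    )
    plate.validate()
    return plate


DEFAULT_PYROSEQ_STANDARDS = (0.0, 16.0, 52.0, 92.0)


def generate_pyroseq(
    biopsies: pd.DataFrame,
    muscle_mean_het: Mapping[tuple[str, str], float] | Mapping[str, float],
    between_biopsy_sd: float = 2.9,
    replicate_sd: float = 1.0,
    seed: int = 0,
    standards: Sequence[float] = DEFAULT_PYROSEQ_STANDARDS,
) -> list[PyroseqRecord]:
    """Simulate pyrosequencing triplicates per biopsy plus assay standards.

    ``muscle_mean_het`` maps either ``(patient, muscle)`` or ``muscle`` to a
    mean heteroplasmy percentage; per-biopsy truth is drawn around it with SD
    ``between_biopsy_sd`` and replicates around the truth with SD
    ``replicate_sd``, all clipped to [0, 100].
    """
    rng = np.random.default_rng(seed)

    def mean_for(patient: str, muscle: str) -> float:
        if (patient, muscle) in muscle_mean_het:
            m = muscle_mean_het[(patient, muscle)]
        else:
            m = muscle_mean_het[muscle]
        if not (0.0 <= m <= 100.0):
            raise ValueError("heteroplasmy means must be in [0, 100]")
        return float(m)

    records = []
    seen = set()
    for _, row in biopsies.iterrows():
        bid = row["biopsy"]
        if bid in seen:
            continue
        seen.add(bid)
        mean = mean_for(row["patient"], row["muscle"])
        truth = float(np.clip(mean + (rng.normal(0.0, between_biopsy_sd) if between_biopsy_sd > 0 else 0.0), 0.0, 100.0))
        reps = np.clip(truth + (rng.normal(0.0, replicate_sd, 3) if replicate_sd > 0 else np.zeros(3)), 0.0, 100.0)
        records.append(PyroseqRecord(biopsy=bid, replicates=[float(r) for r in reps], true_heteroplasmy=truth))
    for level in standards:
        reps = np.clip(level + (rng.normal(0.0, replicate_sd, 3) if replicate_sd > 0 else np.zeros(3)), 0.0, 100.0)
        records.append(PyroseqRecord(
            biopsy=f"STD_{level:g}", replicates=[float(r) for r in reps],
            true_heteroplasmy=float(level), is_standard=True,
        ))
    for rec in records:
        rec.validate()
    return records
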