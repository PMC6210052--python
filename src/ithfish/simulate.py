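"""Synthetic IFISH cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
each (patient, timepoint) sample is a mixture of subclones; every subclone
has a phenotype (intensity location parameters on the 12-bit scale), a
*HER2* copy-number genotype (probe pixel-area band) and a spatial-pattern
propensity.  Cells are drawn i.i.d. from the patient's mixture —
log-normal intensities clipped to [0, 4095], truncated-normal pixel areas,
categorical spatial labels, Poisson centromere-17 counts — and survival
times come from an exponential baseline hazard scaled by each patient's
planted hazard multiplier, with administrative censoring.

Every planted quantity (subclone fractions per timepoint, the exact
Kullback-Leibler divergence between them, hazard multipliers, archetype
labels) is recorded in ``CohortTable.truth`` so downstream estimates can be
checked against the truth.

Named scenarios (see :func:`scenario_presets`):

* ``homogeneous_amp`` — one HER2+/ER+ *HER2*-amplified subclone; every
  sample is single-class, Shannon index 0, no clonal shift.
* ``three_archetypes`` — three planted composition archetypes (a
  HER2+/ER+-dominated, a HER2+/ER−-dominated, and an evenly mixed group),
  for clustering-recovery tests.
* ``kl_contrast`` — half the patients undergo a large pre→post clonal shift
  (≈1 bit), half a negligible one (≈0.05 bit); the low-shift patients carry
  a 3× hazard, mirroring the association between static clonal composition
  under therapy and poor outcome.
* ``null_no_shift`` — pre and post compositions identical; all true K-L
  divergences are exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ithfish.cohort import CELL_COLUMNS, CohortTable
from ithfish.diversity import kl_divergence_vectors

__all__ = ["SubcloneSpec", "PatientSpec", "scenario_presets", "generate_cohort", "simulate_nucleus_spots"]

#: pixel-area band centres/spreads per genotype; spreads put each band edge
#: ~3.3 sd from the centre, so threshold crossings occur (a few cells per
#: thousand, exercising boundary handling downstream) but are rare enough
#: that classified compositions converge to the planted subclone fractions.
_AREA_PARAMS = {"norm": (30.0, 10.0), "gain": (130.0, 21.0), "amp": (400.0, 60.0)}

#: spatial-pattern propensities per genotype: amplified subclones tend to
#: tight signal clusters, normal-CN subclones to scattered single signals.
_SPATIAL_PROBS = {
    "norm": (0.10, 0.80, 0.10),
    "gain": (0.25, 0.40, 0.35),
    "amp": (0.75, 0.10, 0.15),
}

#: log-normal intensity locations (12-bit scale) per marker state; the
#: log-scale sigma of 0.5 puts ~0.2-0.4% of cells across the classification
#: threshold, so misclassification is rare but non-zero.
_INTENSITY_MEANS = {("her2", True): 1200.0, ("her2", False): 80.0, ("er", True): 400.0, ("er", False): 12.0}
_LOG_SIGMA = 0.5

INTENSITY_MAX = 4095.0


@dataclass(frozen=True)
class SubcloneSpec:
    """Generative parameters of one subclone.

    Intensity means are locations of the log-normal draws (clipped to the
    12-bit range); ``area_mean``/``area_sd`` parameterize a normal truncated
    at zero; ``spatial_probs`` is the (cluster, scatter, mix) propensity.
    """

    phenotype: str
    genotype: str
    er_mean: float
    her2_mean: float
    er_sd: float = _LOG_SIGMA
    her2_sd: float = _LOG_SIGMA
    area_mean: float = 0.0
    area_sd: float = 0.0
    spatial_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if not (0 <= self.er_mean <= INTENSITY_MAX and 0 <= self.her2_mean <= INTENSITY_MAX):
            raise ValueError("intensity means must lie within the 12-bit range")
        if abs(sum(self.spatial_probs) - 1.0) > 1e-9:
            raise ValueError(f"spatial_probs must sum to 1, got {self.spatial_probs}")


def make_subclone(phenotype: str, genotype: str) -> SubcloneSpec:
    """Standard subclone for a (phenotype, genotype) pair."""
    her2_state = phenotype.startswith("HER2+")
    er_state = "/ER+" in phenotype
    am, asd = _AREA_PARAMS[genotype]
    return SubcloneSpec(
        phenotype=phenotype,
        genotype=genotype,
        er_mean=_INTENSITY_MEANS[("er", er_state)],
        her2_mean=_INTENSITY_MEANS[("her2", her2_state)],
        area_mean=am,
        area_sd=asd,
        spatial_probs=_SPATIAL_PROBS[genotype],
    )


@dataclass(frozen=True)
class PatientSpec:
    """Planted per-patient truth: mixtures, shift, hazard, response."""

    patient_id: str
    pre_fractions: np.ndarray
    post_fractions: np.ndarray
    target_kl: float
    hazard_multiplier: float
    pcr: bool
    archetype: int | None = None

    def __post_init__(self):
        for name in ("pre_fractions", "post_fractions"):
            f = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, f)
            if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")
        if self.hazard_multiplier <= 0:
            raise ValueError("hazard_multiplier must be positive")


@dataclass(frozen=True)
class Scenario:
    """A fully parameterized cohort recipe."""

    name: str
    description: str
    subclones: tuple[SubcloneSpec, ...]
    n_patients: int
    #: builder(rng, n_patients) -> list[PatientSpec]
    build_patients: object = field(repr=False, compare=False, default=None)


def _solve_post_fractions(pre: np.ndarray, direction: np.ndarray, target_kl: float) -> np.ndarray:
    """Post mixture on the segment pre → direction with KL(pre||post) = target.

    The divergence grows monotonically along the segment, so a scalar root
    find recovers the planted value to machine precision.
    """
    if target_kl == 0:
        return pre.copy()
    kl_end = kl_divergence_vectors(pre, direction, epsilon=0)
    if target_kl > kl_end:
        raise ValueError(f"target_kl={target_kl} exceeds the reachable maximum {kl_end:.3f}")

    def f(t: float) -> float:
        q = (1 - t) * pre + t * direction
        return kl_divergence_vectors(pre, q, epsilon=0) - target_kl

    t = brentq(f, 0.0, 1.0, xtol=1e-15)
    return (1 - t) * pre + t * direction


def _dirichlet_positive(rng: np.random.Generator, centroid: np.ndarray, conc: float, floor: float = 0.01) -> np.ndarray:
    """Dirichlet draw around a centroid, floored away from the simplex boundary."""
    f = rng.dirichlet(conc * centroid)
    f = np.maximum(f, floor)
    return f / f.sum()


def _build_homogeneous_amp(rng: np.random.Generator, n: int) -> list[PatientSpec]:
    one = np.array([1.0])
    return [
        PatientSpec(f"P{i:03d}", one, one, 0.0, 1.0, pcr=False) for i in range(n)
    ]


_ARCHETYPE_CENTROIDS = np.array(
    [
        [0.85, 0.05, 0.05, 0.05],  # dominated by HER2+/ER+
        [0.05, 0.85, 0.05, 0.05],  # dominated by HER2+/ER-
        [0.25, 0.25, 0.25, 0.25],  # evenly mixed -> highest Shannon index
    ]
)


def _build_three_archetypes(rng: np.random.Generator, n: int) -> list[PatientSpec]:
    specs = []
    for i in range(n):
        arch = i % 3
        f = _dirichlet_positive(rng, _ARCHETYPE_CENTROIDS[arch], conc=150.0)
        specs.append(PatientSpec(f"P{i:03d}", f, f.copy(), 0.0, 1.0, pcr=False, archetype=arch + 1))
    return specs


_KL_PRE_CENTROID = np.array([0.5, 0.3, 0.2])
#: amp-takeover directions, mildest first.  The moderate direction keeps all
#: post-treatment masses away from the simplex boundary (small-count
#: categories dominate the variance of the estimated divergence); the
#: sharper fallbacks guarantee the planted divergence stays reachable for
#: every Dirichlet draw of pre-treatment fractions.
_KL_SHIFT_DIRECTIONS = (
    np.array([0.05, 0.15, 0.80]),
    np.array([0.02, 0.08, 0.90]),
    np.array([0.01, 0.01, 0.98]),
)
KL_HIGH_TARGET = 1.0  # bits
KL_LOW_TARGET = 0.05  # bits
LOW_SHIFT_HAZARD = 3.0


def _build_kl_contrast(rng: np.random.Generator, n: int) -> list[PatientSpec]:
    specs = []
    for i in range(n):
        high = i < n // 2
        pre = _dirichlet_positive(rng, _KL_PRE_CENTROID, conc=60.0, floor=0.02)
        target = KL_HIGH_TARGET if high else KL_LOW_TARGET
        post = None
        for direction in _KL_SHIFT_DIRECTIONS:
            if kl_divergence_vectors(pre, direction, epsilon=0) > 1.05 * target:
                post = _solve_post_fractions(pre, direction, target)
                break
        if post is None:  # pragma: no cover - unreachable with preset directions
            post = _solve_post_fractions(pre, _KL_SHIFT_DIRECTIONS[-1], target)
        specs.append(
            PatientSpec(
                f"P{i:03d}",
                pre,
                post,
                target_kl=kl_divergence_vectors(pre, post, epsilon=0),
                hazard_multiplier=1.0 if high else LOW_SHIFT_HAZARD,
                pcr=False,
            )
        )
    return specs


def _build_null_no_shift(rng: np.random.Generator, n: int) -> list[PatientSpec]:
    specs = []
    for i in range(n):
        f = _dirichlet_positive(rng, np.array([0.4, 0.35, 0.25]), conc=80.0, floor=0.02)
        specs.append(PatientSpec(f"P{i:03d}", f, f.copy(), 0.0, 1.0, pcr=False))
    return specs


def scenario_presets() -> dict[str, Scenario]:
    """Catalogue of the named, fully parameterized cohort scenarios."""
    pheno4 = (
        make_subclone("HER2+/ER+", "amp"),
        make_subclone("HER2+/ER-", "amp"),
        make_subclone("HER2-/ER+", "norm"),
        make_subclone("HER2-/ER-", "norm"),
    )
    geno3 = (
        make_subclone("HER2+/ER-", "norm"),
        make_subclone("HER2+/ER-", "gain"),
        make_subclone("HER2+/ER-", "amp"),
    )
    return {
        "homogeneous_amp": Scenario(
            "homogeneous_amp",
            "single HER2+/ER+ amplified subclone; zero heterogeneity and zero shift",
            (make_subclone("HER2+/ER+", "amp"),),
            n_patients=10,
            build_patients=_build_homogeneous_amp,
        ),
        "three_archetypes": Scenario(
            "three_archetypes",
            "three well-separated phenotype-composition archetypes for clustering recovery",
            pheno4,
            n_patients=36,
            build_patients=_build_three_archetypes,
        ),
        "kl_contrast": Scenario(
            "kl_contrast",
            "half the cohort shifts ~1 bit pre->post, half ~0.05 bit; low shift carries 3x hazard",
            geno3,
            n_patients=40,
            build_patients=_build_kl_contrast,
        ),
        "null_no_shift": Scenario(
            "null_no_shift",
            "pre and post compositions identical for every patient; true K-L = 0",
            geno3,
            n_patients=20,
            build_patients=_build_null_no_shift,
        ),
    }


def _draw_intensities(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    """Log-normal intensities with median ``mean``, clipped to the 12-bit range."""
    x = np.exp(rng.normal(np.log(mean), sigma, size=n)) if mean > 0 else np.zeros(n)
    return np.clip(x, 0.0, INTENSITY_MAX)


def _draw_areas(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Pixel areas from a normal truncated at zero."""
    a = -mean / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


_SPATIAL_NAMES = np.array(["cluster", "scatter", "mix"])
BASELINE_MEAN_DFS = 60.0  # months under hazard multiplier 1
BASELINE_MEAN_OS = 90.0
CENSOR_FRACTION = 0.30  # administrative-censoring target at baseline hazard


def _sample_cells(
    rng: np.random.Generator,
    subclones: tuple[SubcloneSpec, ...],
    fractions: np.ndarray,
    n_cells: int,
    patient_id: str,
    timepoint: str,
    cent17_missing: float = 0.05,
) -> pd.DataFrame:
    idx = rng.choice(len(subclones), size=n_cells, p=fractions)
    er = np.empty(n_cells)
    her2 = np.empty(n_cells)
    area = np.empty(n_cells)
    spatial = np.empty(n_cells, dtype=object)
    for j, sc in enumerate(subclones):
        m = idx == j
        k = int(m.sum())
        if k == 0:
            continue
        er[m] = _draw_intensities(rng, sc.er_mean, sc.er_sd, k)
        her2[m] = _draw_intensities(rng, sc.her2_mean, sc.her2_sd, k)
        area[m] = _draw_areas(rng, sc.area_mean, sc.area_sd, k)
        spatial[m] = _SPATIAL_NAMES[rng.choice(3, size=k, p=np.asarray(sc.spatial_probs))]
    cent = rng.poisson(2.0, size=n_cells).astype(float)
    cent[rng.random(n_cells) < cent17_missing] = np.nan
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "timepoint": timepoint,
            "image_id": "sim0",
            "er_intensity": er,
            "her2_intensity": her2,
            "her2_area_px": area,
            "cent17_count": cent,
            "spatial_label": spatial,
        },
        columns=list(CELL_COLUMNS),
    )


def _survival_row(rng: np.random.Generator, spec: PatientSpec) -> dict:
    censor_dfs = -BASELINE_MEAN_DFS * np.log(CENSOR_FRACTION)
    censor_os = -BASELINE_MEAN_OS * np.log(CENSOR_FRACTION)
    t_dfs = rng.exponential(BASELINE_MEAN_DFS / spec.hazard_multiplier)
    t_os = rng.exponential(BASELINE_MEAN_OS / spec.hazard_multiplier)
    return {
        "patient_id": spec.patient_id,
        "pcr": spec.pcr,
        "relapse": bool(t_dfs <= censor_dfs),
        "death_bc": bool(t_os <= censor_os),
        "time_dfs": float(min(t_dfs, censor_dfs)),
        "time_os": float(min(t_os, censor_os)),
        "er_status_ihc": "",
        "grade": int(rng.integers(2, 4)),
        "her2_ihc": "3+",
    }


def generate_cohort(
    n_patients: int | None = None,
    cells_per_sample: int = 300,
    scenario: str = "three_archetypes",
    seed: int = 0,
    timepoints: tuple[str, ...] = ("pre", "post"),
    sparse_sample: tuple[str, str, int] | None = None,
) -> CohortTable:
    """Generate a synthetic cohort with planted ground truth.

    Parameters
    ----------
    n_patients
        Cohort size (default: the scenario's preset size; must be >= 2).
    cells_per_sample
        Cells per (patient, timepoint) sample (>= 10).
    scenario
        A preset name from :func:`scenario_presets`.
    seed
        Seeds all randomness; identical seeds give byte-identical cohorts.
    timepoints
        Which timepoints to emit; pre uses ``pre_fractions``, any later
        timepoint uses ``post_fractions``.
    sparse_sample
        Optional ``(patient_id, timepoint, n_cells)`` override forcing one
        deliberately sparse sample, for exclusion-filter tests.

    Returns
    -------
    CohortTable
        Cells + clinical covariates; ``truth`` holds the scenario name, the
        subclone specs and every :class:`PatientSpec`.
    """
    presets = scenario_presets()
    if scenario not in presets:
        raise ValueError(f"unknown scenario {scenario!r}; available: {sorted(presets)}")
    sc = presets[scenario]
    n = sc.n_patients if n_patients is None else int(n_patients)
    if n < 2:
        raise ValueError("n_patients must be >= 2")
    if cells_per_sample < 10:
        raise ValueError("cells_per_sample must be >= 10")
    rng = np.random.default_rng(seed)
    patients = sc.build_patients(rng, n)

    frames = []
    for spec in patients:
        for tp in timepoints:
            frac = spec.pre_fractions if tp == "pre" else spec.post_fractions
            n_cells = cells_per_sample
            if sparse_sample is not None and sparse_sample[:2] == (spec.patient_id, tp):
                n_cells = int(sparse_sample[2])
            frames.append(_sample_cells(rng, sc.subclones, frac, n_cells, spec.patient_id, tp))
    cells = pd.concat(frames, ignore_index=True)
    clinical = pd.DataFrame([_survival_row(rng, spec) for spec in patients])

    truth = {
        "scenario": scenario,
        "seed": seed,
        "subclones": sc.subclones,
        "patients": {spec.patient_id: spec for spec in patients},
    }
    return CohortTable(
        cells=cells,
        clinical=clinical,
        provenance={
            "generator": "ithfish.simulate",
            "scenario": scenario,
            "seed": seed,
            "n_patients": n,
            "cells_per_sample": cells_per_sample,
            "intensities_adjusted": True,
        },
        truth=truth,
    )


def simulate_nucleus_spots(
    pattern: str, rng: np.random.Generator, nucleus_radius: float = 10.0
) -> np.ndarray:
    """Spot centroids for one synthetic nucleus with a known spatial pattern.

    Synthetic geometry (units of one spot diameter): ``cluster`` packs
    10-20 spots in a disc of radius 0.5; ``scatter`` places 3-6 spots
    pairwise more than 3 apart; ``mix`` combines a 4-8 spot aggregate with
    enough distant singletons to break an 80% majority.
    """

    def disc(center: np.ndarray, radius: float, k: int) -> np.ndarray:
        r = radius * np.sqrt(rng.random(k))
        th = 2 * np.pi * rng.random(k)
        return center + np.c_[r * np.cos(th), r * np.sin(th)]

    def far_points(k: int, min_dist: float = 3.0, avoid: np.ndarray | None = None) -> np.ndarray:
        pts: list[np.ndarray] = []
        while len(pts) < k:
            cand = (rng.random(2) * 2 - 1) * nucleus_radius
            others = pts + ([avoid] if avoid is not None else [])
            if all(np.linalg.norm(cand - o) > min_dist for o in others):
                pts.append(cand)
        return np.array(pts)

    if pattern == "cluster":
        center = (rng.random(2) * 2 - 1) * nucleus_radius * 0.5
        return disc(center, 0.5, int(rng.integers(10, 21)))
    if pattern == "scatter":
        return far_points(int(rng.integers(3, 7)))
    if pattern == "mix":
        k_cluster = int(rng.integers(4, 9))
        k_single = max(2, int(np.ceil(k_cluster / 3)))
        center = (rng.random(2) * 2 - 1) * nucleus_radius * 0.3
        agg = disc(center, 0.5, k_cluster)
        singles = far_points(k_single, min_dist=3.0, avoid=center)
        return np.vstack([agg, singles])
    raise ValueError(f"unknown pattern {pattern!r}")
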