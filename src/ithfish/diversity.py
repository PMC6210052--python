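"""Composition-based heterogeneity: Shannon index and Kullback-Leibler shift.

A *sample composition* is the vector of cell-class fractions of one
(patient, timepoint) sample over a fixed category system: the four
phenotypes, the three *HER2* copy-number genotypes, the 12 combined classes,
or the three intranuclear spatial patterns.

Heterogeneity within a sample is the Shannon index (entropy in bits)

    SI = -sum_i f_i log2 f_i,

zero for a single-class tumor and log2(M) for a uniform mixture over M
classes.  The treatment-induced clonal shift of a patient is the
Kullback-Leibler divergence between the pre-treatment composition P and the
post-treatment composition Q,

    K-L = sum_i P_i log2(P_i / Q_i),

in bits; zero iff the compositions are identical.  Both indices use base-2
logarithms.  Cohorts are split at the median K-L into KL_high / KL_low
groups for outcome comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ithfish.classify import SYSTEMS

__all__ = [
    "SampleComposition",
    "ClonalShiftResult",
    "composition",
    "shannon_index",
    "mean_shannon_by_group",
    "kl_divergence",
    "kl_divergence_vectors",
    "median_split",
    "DegenerateSplitWarning",
]

_SYSTEM_COLUMN = {
    "phenotype4": "phenotype",
    "genotype3": "genotype",
    "combined12": "combined",
    "spatial3": "spatial_label",
}


class InfiniteDivergenceError(ValueError):
    """Q has zero mass where P does not, and no smoothing was requested."""


class DegenerateSplitWarning(UserWarning):
    """All K-L values identical; the median split carries no information."""


@dataclass(frozen=True)
class SampleComposition:
    """Cell-class fractions of one sample over a named category system."""

    patient_id: str
    timepoint: str
    system: str
    fractions: np.ndarray
    n_cells: int

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}; expected one of {sorted(SYSTEMS)}")
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        m = len(SYSTEMS[self.system])
        if fr.shape != (m,):
            raise ValueError(f"system {self.system} needs {m} fractions, got shape {fr.shape}")
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must be >= 0 and sum to 1 (sum={fr.sum()!r})")

    @property
    def categories(self) -> tuple[str, ...]:
        return SYSTEMS[self.system]

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(self.categories), name=(self.patient_id, self.timepoint))


@dataclass(frozen=True)
class ClonalShiftResult:
    """Per-patient clonal-shift summary between pre and post compositions.

    ``deltas`` are per-category fraction changes Q_i - P_i on the raw
    (unsmoothed) fractions and sum to zero; ``group`` is filled in by
    :func:`median_split`.
    """

    patient_id: str
    system: str
    kl_bits: float
    deltas: np.ndarray
    group: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.kl_bits < 0:
            raise ValueError(f"kl_bits={self.kl_bits} is negative")
        d = np.asarray(self.deltas, dtype=float)
        object.__setattr__(self, "deltas", d)
        if abs(d.sum()) > 1e-9:
            raise ValueError(f"deltas must sum to 0, got {d.sum()!r}")


def composition(cells: pd.DataFrame, system: str) -> SampleComposition:
    """Fraction of each category among the classified cells of one sample.

    ``cells`` must contain the class column for ``system`` (``phenotype``,
    ``genotype``, ``combined`` or ``spatial_label``) and belong to a single
    (patient, timepoint); categories absent from the sample get fraction 0.
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}")
    col = _SYSTEM_COLUMN[system]
    if col not in cells.columns:
        raise ValueError(f"cells lack the {col!r} column; classify them first")
    labels = cells[col].dropna()
    if len(labels) == 0:
        raise ValueError("composition of an empty sample is undefined")
    pids = cells["patient_id"].unique()
    tps = cells["timepoint"].unique()
    if len(pids) > 1 or len(tps) > 1:
        raise ValueError("composition expects cells of a single (patient, timepoint) sample")
    cats = SYSTEMS[system]
    counts = labels.value_counts()
    frac = np.array([counts.get(c, 0) for c in cats], dtype=float)
    frac /= frac.sum()
    return SampleComposition(
        patient_id=str(pids[0]), timepoint=str(tps[0]), system=system,
        fractions=frac, n_cells=int(len(labels)),
    )


def cohort_compositions(cells: pd.DataFrame, system: str) -> list[SampleComposition]:
    """Compositions for every (patient, timepoint) sample in a classified table."""
    return [
        composition(grp, system)
        for _, grp in cells.groupby(["patient_id", "timepoint"], sort=True)
    ]


def shannon_index(comp: SampleComposition | np.ndarray) -> float:
    """Shannon index in bits, with the convention 0 * log 0 = 0."""
    f = comp.fractions if isinstance(comp, SampleComposition) else np.asarray(comp, dtype=float)
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def mean_shannon_by_group(si: pd.Series, groups: pd.Series) -> pd.Series:
    """Arithmetic mean Shannon index per group label.

    ``si`` and ``groups`` are aligned by index (sample id); every sample must
    carry a label.
    """
    si, groups = si.align(groups, join="inner")
    if len(si) == 0:
        raise ValueError("no samples shared between SI values and group labels")
    if groups.isna().any():
        raise ValueError("every sample must be labeled")
    return si.groupby(groups).mean()


def _smooth(p: np.ndarray, epsilon: float) -> np.ndarray:
    """Additive-epsilon smoothing then renormalization (applied when any mass is zero)."""
    if epsilon > 0 and (p == 0).any():
        p = p + epsilon
        p = p / p.sum()
    return p


def kl_divergence_vectors(p: np.ndarray, q: np.ndarray, epsilon: float = 1e-6) -> float:
    """K-L divergence D(P || Q) in bits between two fraction vectors.

    Zero-mass categories receive an additive ``epsilon`` pseudo-fraction
    (then renormalization) before the divergence is evaluated; with
    ``epsilon=0`` a category with Q_i = 0 < P_i raises
    :class:`InfiniteDivergenceError`.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    ps = _smooth(p, epsilon)
    qs = _smooth(q, epsilon)
    if ((qs == 0) & (ps > 0)).any():
        raise InfiniteDivergenceError(
            "Q assigns zero mass to a category P occupies; the divergence is "
            "infinite — pass epsilon > 0 to smooth empty categories"
        )
    mask = ps > 0
    return float((ps[mask] * np.log2(ps[mask] / qs[mask])).sum())


def kl_divergence(
    pre: SampleComposition, post: SampleComposition, epsilon: float = 1e-6
) -> ClonalShiftResult:
    """Clonal-shift index of one patient: D(pre || post) in bits plus deltas.

    Both compositions must use the same category system.  ``deltas`` are
    computed on the raw fractions (no smoothing), so they always sum to zero.
    """
    if pre.system != post.system:
        raise ValueError(f"system mismatch: {pre.system} vs {post.system}")
    if pre.patient_id != post.patient_id:
        raise ValueError(f"patient mismatch: {pre.patient_id} vs {post.patient_id}")
    kl = kl_divergence_vectors(pre.fractions, post.fractions, epsilon=epsilon)
    return ClonalShiftResult(
        patient_id=pre.patient_id,
        system=pre.system,
        kl_bits=kl,
        deltas=post.fractions - pre.fractions,
    )


def median_split(shifts: list[ClonalShiftResult]) -> list[ClonalShiftResult]:
    """Split a cohort into KL_high / KL_low at the median K-L index.

    Values strictly above the median go to ``KL_high``; values at or below it
    to ``KL_low`` (ties at the median are low, deterministically).  For an
    even number of distinct values this yields two equal-sized groups.  When
    every value is identical the split is degenerate: a
    :class:`DegenerateSplitWarning` is issued and all patients are KL_low.
    """
    if len(shifts) < 2:
        raise ValueError("median_split needs at least 2 patients")
    vals = np.array([s.kl_bits for s in shifts], dtype=float)
    med = float(np.median(vals))
    if np.all(vals == vals[0]):
        warnings.warn(
            f"all {len(vals)} K-L values identical ({vals[0]:.4g}); split is degenerate",
            DegenerateSplitWarning,
            stacklevel=2,
        )
    from dataclasses import replace

    return [
        replace(s, group="KL_high" if s.kl_bits > med else "KL_low") for s in shifts
    ]


def shift_table(shifts: list[ClonalShiftResult]) -> pd.DataFrame:
    """Tabulate shift results, one row per patient, sorted by decreasing K-L."""
    cats = SYSTEMS[shifts[0].system] if shifts else ()
    rows = []
    for s in shifts:
        row = {"patient_id": s.patient_id, "system": s.system, "kl_bits": s.kl_bits, "group": s.group}
        row.update({f"delta_{c}": d for c, d in zip(cats, s.deltas)})
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("kl_bits", ascending=False).reset_index(drop=True)
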