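"""Cell phenotype/genotype classification and patient-level ER status.

Every tumor cell is assigned to

* one of four **phenotype** classes HER2+/ER+, HER2+/ER-, HER2-/ER+,
  HER2-/ER- by thresholding the adjusted membrane HER2 and nuclear ER
  fluorescence intensities (defaults 300 and 50 on the 12-bit scale);
* one of three **genotype** classes by total *HER2* probe pixel area within
  the nucleus -- norm (<= 63 px, up to ~3 gene copies), gain (64-200 px,
  ~3-6 copies), amp (> 200 px, > 6 copies);
* the **combined** 12-way class, the phenotype x genotype pair.

Positivity is strictly greater than the threshold, so a cell at exactly the
cutoff is negative; the genotype bands use inclusive upper bounds on the
lower side, matching the published pixel ranges.

Patient ER status follows the clinical convention: a tumor is ER+ when at
least 1% of its pre-treatment cells are ER-positive, and patients are further
stratified into negative (< 1%), low (1-10%), intermediate (10-50%] and
high (> 50%) ER strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: category orders are fixed so composition vectors are comparable everywhere
PHENOTYPES = ("HER2+/ER+", "HER2+/ER-", "HER2-/ER+", "HER2-/ER-")
GENOTYPES = ("norm", "gain", "amp")
COMBINED = tuple(f"{p} {g}" for p in PHENOTYPES for g in GENOTYPES)
ER_STRATA = ("negative", "low", "intermediate", "high")

SYSTEMS: dict[str, tuple[str, ...]] = {
    "phenotype4": PHENOTYPES,
    "genotype3": GENOTYPES,
    "combined12": COMBINED,
    "spatial3": ("cluster", "scatter", "mix"),
}


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs on the 12-bit intensity scale and pixel areas.

    A cell is marker-positive when its intensity is *strictly above* the
    cutoff; genotype bands are ``area <= area_norm_max`` (norm),
    ``area_norm_max < area <= area_gain_max`` (gain), else amp.
    """

    her2_pos: float = 300.0
    er_pos: float = 50.0
    area_norm_max: float = 63.0
    area_gain_max: float = 200.0

    def __post_init__(self):
        if not 0 < self.er_pos < 4095:
            raise ValueError(f"er_pos={self.er_pos} outside (0, 4095)")
        if not 0 < self.her2_pos < 4095:
            raise ValueError(f"her2_pos={self.her2_pos} outside (0, 4095)")
        if not 0 < self.area_norm_max < self.area_gain_max:
            raise ValueError(
                f"need 0 < area_norm_max < area_gain_max, got {self.area_norm_max}, {self.area_gain_max}"
            )


@dataclass(frozen=True)
class CellClassification:
    """Class labels of a single cell; ``combined`` is the (phenotype, genotype) pair."""

    phenotype: str
    genotype: str

    @property
    def combined(self) -> str:
        return f"{self.phenotype} {self.genotype}"


def classify_cell(
    er_intensity: float, her2_intensity: float, her2_area_px: float, t: Thresholds | None = None
) -> CellClassification:
    """Classify a single cell; see the module docstring for the conventions."""
    t = t or Thresholds()
    her2 = "HER2+" if her2_intensity > t.her2_pos else "HER2-"
    er = "ER+" if er_intensity > t.er_pos else "ER-"
    if her2_area_px <= t.area_norm_max:
        geno = "norm"
    elif her2_area_px <= t.area_gain_max:
        geno = "gain"
    else:
        geno = "amp"
    return CellClassification(phenotype=f"{her2}/{er}", genotype=geno)


def classify_cells(cells: pd.DataFrame, t: Thresholds | None = None) -> pd.DataFrame:
    """Vectorized classification of a cell table.

    Returns a copy of ``cells`` with ``phenotype``, ``genotype`` and
    ``combined`` columns added.  The classification is a total function of
    the three measurements, so it is invariant to row order and to how cells
    are grouped into images.
    """
    t = t or Thresholds()
    out = cells.copy()
    her2pos = out["her2_intensity"].to_numpy(float) > t.her2_pos
    erpos = out["er_intensity"].to_numpy(float) > t.er_pos
    out["phenotype"] = np.where(
        her2pos,
        np.where(erpos, "HER2+/ER+", "HER2+/ER-"),
        np.where(erpos, "HER2-/ER+", "HER2-/ER-"),
    )
    area = out["her2_area_px"].to_numpy(float)
    out["genotype"] = np.select(
        [area <= t.area_norm_max, area <= t.area_gain_max], ["norm", "gain"], default="amp"
    )
    out["combined"] = out["phenotype"] + " " + out["genotype"]
    return out


def patient_er_status(
    cells: pd.DataFrame, t: Thresholds | None = None
) -> tuple[str, float]:
    """Patient-level ER status from all pre-treatment cells of one patient.

    Returns ``("ER+" | "ER-", percent_positive)`` with the percentage rounded
    to 0.1%.  The tumor is ER+ when >= 1% of cells exceed the ER intensity
    cutoff (the negative class is defined as < 1% positive cells).
    """
    t = t or Thresholds()
    if len(cells) == 0:
        raise ValueError("patient_er_status requires at least one cell")
    frac = float((cells["er_intensity"].to_numpy(float) > t.er_pos).mean())
    pct = round(100.0 * frac, 1)
    return ("ER+" if 100.0 * frac >= 1.0 else "ER-"), pct


def er_stratum(percent_positive: float) -> str:
    """Four-level ER stratum from the percentage of ER-positive cells.

    negative < 1%; low 1-10% (inclusive); intermediate (10-50%]; high > 50%.
    """
    p = float(percent_positive)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent_positive={p} outside [0, 100]")
    if p < 1.0:
        return "negative"
    if p <= 10.0:
        return "low"
    if p <= 50.0:
        return "intermediate"
    return "high"


def patient_er_table(cohort_cells: pd.DataFrame, t: Thresholds | None = None) -> pd.DataFrame:
    """Per-patient ER status and stratum from pre-treatment cells.

    Returns a DataFrame with columns ``patient_id, er_status, pct_er_pos,
    er_stratum``; patients without pre-treatment cells are omitted.
    """
    pre = cohort_cells[cohort_cells["timepoint"] == "pre"]
    rows = []
    for pid, grp in pre.groupby("patient_id", sort=True):
        status, pct = patient_er_status(grp, t)
        rows.append({"patient_id": pid, "er_status": status, "pct_er_pos": pct, "er_stratum": er_stratum(pct)})
    return pd.DataFrame(rows, columns=["patient_id", "er_status", "pct_er_pos", "er_stratum"])
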