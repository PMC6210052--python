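"""End-to-end orchestration: classify -> compose -> diversity -> cluster ->
spatial -> clonal shift -> outcome statistics.

:func:`run_pipeline` takes one run configuration (a plain dict, typically
loaded from YAML), executes every stage that its inputs support, writes CSV
tables, a machine-readable JSON summary and (optionally) figures into the
output directory, and returns the result bundle in memory.  Runs are
deterministic given config + seed, and every threshold and convention in
force is echoed into the summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ithfish import cluster as _cluster
from ithfish import spatial as _spatial
from ithfish import stats as _stats
from ithfish.classify import SYSTEMS, Thresholds, classify_cells, patient_er_table
from ithfish.cohort import CohortTable, filter_samples, read_cells, read_clinical
from ithfish.diversity import (
    ClonalShiftResult,
    cohort_compositions,
    kl_divergence,
    median_split,
    shannon_index,
    shift_table,
)
from ithfish.simulate import generate_cohort

__all__ = ["run_pipeline", "PipelineResult", "scatter_cell_plot", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "min_cells": 50,
    "thresholds": {},  # Thresholds(**...) defaults
    "systems": ["phenotype4", "genotype3", "combined12"],
    "kl": {"system": "genotype3", "epsilon": 1e-6},
    "cluster": {"k": 3, "method": "ward", "metric": "euclidean", "use_clr": False},
    "spatial": {"cutoff": 0.70},
    "survival": {"endpoint": "os"},
    "figures": False,
}


@dataclass
class PipelineResult:
    """Everything one run produced, keyed the way it is written to disk."""

    config: dict[str, Any]
    cohort: CohortTable
    cells: pd.DataFrame  # classified cell table
    composition_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    si_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    cluster_assignments: dict[str, _cluster.ClusterAssignment] = field(default_factory=dict)
    cluster_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    er_table: pd.DataFrame | None = None
    spatial_profiles: list[_spatial.SpatialProfile] = field(default_factory=list)
    shifts: list[ClonalShiftResult] = field(default_factory=list)
    shift_df: pd.DataFrame | None = None
    survival: _stats.SurvivalResult | None = None
    cox: _stats.SurvivalResult | None = None
    summary: dict[str, Any] = field(default_factory=dict)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration, merged over the defaults."""
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _validate_config(cfg: dict[str, Any]) -> list[str]:
    problems = []
    if "scenario" not in cfg and "input" not in cfg:
        problems.append("config: one of 'scenario' or 'input' is required")
    if "input" in cfg and "cells" not in cfg.get("input", {}):
        problems.append("input.cells: path to the cell table is required")
    for sys_name in cfg.get("systems", []):
        if sys_name not in SYSTEMS:
            problems.append(f"systems: unknown category system {sys_name!r}")
    if cfg.get("kl", {}).get("system") not in SYSTEMS:
        problems.append(f"kl.system: unknown category system {cfg.get('kl', {}).get('system')!r}")
    k = cfg.get("cluster", {}).get("k", 3)
    if not isinstance(k, int) or k < 1:
        problems.append(f"cluster.k: must be a positive integer, got {k!r}")
    return problems


def _acquire_cohort(cfg: dict[str, Any]) -> CohortTable:
    if "scenario" in cfg:
        sc = cfg["scenario"]
        if isinstance(sc, str):
            sc = {"name": sc}
        return generate_cohort(
            n_patients=sc.get("n_patients"),
            cells_per_sample=sc.get("cells_per_sample", 300),
            scenario=sc["name"],
            seed=cfg.get("seed", 0),
        )
    inp = cfg["input"]
    cohort = read_cells(inp["cells"], schema=inp.get("schema"))
    if "clinical" in inp:
        cohort.clinical = read_clinical(inp["clinical"])
        cohort = CohortTable(cohort.cells, cohort.clinical, cohort.provenance)
    return cohort


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Stages that lack their inputs are skipped with a note in the summary
    (e.g. no post-treatment samples -> no clonal-shift stage; no clinical
    table -> no survival stage).
    """
    cfg = json.loads(json.dumps({**DEFAULT_CONFIG, **config}, default=str))
    problems = _validate_config(cfg)
    if problems:
        raise ValueError("invalid run configuration:\n  " + "\n  ".join(problems))

    thresholds = Thresholds(**cfg.get("thresholds", {}))
    cohort = _acquire_cohort(cfg)
    cohort, exclusions = filter_samples(cohort, min_cells=int(cfg["min_cells"]))
    cells = classify_cells(cohort.cells, thresholds)

    res = PipelineResult(config=cfg, cohort=cohort, cells=cells)
    summary: dict[str, Any] = {
        "config": _jsonable(cfg),
        "thresholds": asdict(thresholds),
        "conventions": {
            "positivity": "strictly greater than threshold",
            "genotype_bands_px": "norm <= 63 < gain <= 200 < amp",
            "er_positive_cutoff_percent": 1.0,
            "log_base": 2,
            "kl_direction": "D(pre || post)",
            "median_ties": "ties at the median assigned KL_low",
            "spatial_majority_cutoff": cfg["spatial"]["cutoff"],
        },
        "n_patients": int(cells["patient_id"].nunique()),
        "n_cells": int(len(cells)),
        "excluded_samples": [list(e) for e in exclusions.excluded],
    }

    # per-system compositions, Shannon indices, clustering
    for sys_name in cfg["systems"]:
        comps = cohort_compositions(cells, sys_name)
        comp_df = pd.DataFrame(
            [
                {"patient_id": c.patient_id, "timepoint": c.timepoint, "n_cells": c.n_cells,
                 **dict(zip(c.categories, c.fractions))}
                for c in comps
            ]
        )
        si_df = comp_df[["patient_id", "timepoint"]].copy()
        si_df["shannon_bits"] = [shannon_index(c) for c in comps]
        res.composition_tables[sys_name] = comp_df
        res.si_tables[sys_name] = si_df

        pre_comps = [c for c in comps if c.timepoint == "pre"]
        k = int(cfg["cluster"]["k"])
        if len(pre_comps) >= k:
            assign = _cluster.cluster_compositions(
                pre_comps, k=k, method=cfg["cluster"]["method"],
                metric=cfg["cluster"]["metric"], use_clr=bool(cfg["cluster"]["use_clr"]),
            )
            si_pre = pd.Series(
                [shannon_index(c) for c in pre_comps],
                index=pd.MultiIndex.from_tuples(
                    [(c.patient_id, c.timepoint) for c in pre_comps],
                    names=["patient_id", "timepoint"],
                ),
            )
            res.cluster_assignments[sys_name] = assign
            res.cluster_summaries[sys_name] = _cluster.characterize_clusters(assign, pre_comps, si_pre)
        summary.setdefault("mean_shannon_bits", {})[sys_name] = float(si_df["shannon_bits"].mean())

    # patient ER status (pre-treatment cells)
    if (cells["timepoint"] == "pre").any():
        res.er_table = patient_er_table(cells, thresholds)
        summary["er_strata_counts"] = res.er_table["er_stratum"].value_counts().to_dict()

    # spatial profiles
    res.spatial_profiles = _spatial.cohort_spatial_profiles(cells, cutoff=float(cfg["spatial"]["cutoff"]))
    if res.spatial_profiles:
        summary["spatial_class_counts"] = (
            pd.Series([p.sample_class for p in res.spatial_profiles]).value_counts().to_dict()
        )

    # clonal shift: patients with both pre and post samples
    kl_sys = cfg["kl"]["system"]
    eps = float(cfg["kl"]["epsilon"])
    comps_kl = {(c.patient_id, c.timepoint): c for c in cohort_compositions(cells, kl_sys)}
    paired = sorted({p for (p, t) in comps_kl if t == "pre"} & {p for (p, t) in comps_kl if t == "post"})
    if len(paired) >= 2:
        shifts = [kl_divergence(comps_kl[(p, "pre")], comps_kl[(p, "post")], epsilon=eps) for p in paired]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            shifts = median_split(shifts)
        res.shifts = shifts
        res.shift_df = shift_table(shifts)
        kl_vals = np.array([s.kl_bits for s in shifts])
        summary["clonal_shift"] = {
            "system": kl_sys,
            "n_paired_patients": len(paired),
            "kl_median_bits": float(np.median(kl_vals)),
            "kl_max_bits": float(kl_vals.max()),
            "n_high": int(sum(s.group == "KL_high" for s in shifts)),
            "n_low": int(sum(s.group == "KL_low" for s in shifts)),
            "degenerate_split": any("degenerate" in str(w.message) for w in caught),
        }

        # survival between KL groups
        if cohort.clinical is not None and len(cohort.clinical):
            endpoint = cfg["survival"]["endpoint"]
            tcol, ecol = ("time_os", "death_bc") if endpoint == "os" else ("time_dfs", "relapse")
            clin = cohort.clinical.set_index("patient_id").loc[paired]
            groups = np.array([s.group for s in shifts])
            try:
                res.survival = _stats.km_logrank(
                    clin[tcol].to_numpy(), clin[ecol].to_numpy(bool), groups
                )
                summary["survival"] = {
                    "endpoint": endpoint,
                    "logrank_stat": res.survival.logrank_stat,
                    "logrank_p": res.survival.logrank_p,
                }
            except ValueError as e:
                summary["survival"] = {"endpoint": endpoint, "skipped": str(e)}
            try:
                res.cox = _stats.cox_univariate(
                    clin[tcol].to_numpy(), clin[ecol].to_numpy(bool), kl_vals
                )
                summary["cox_kl_continuous"] = {
                    "hr": res.cox.cox_hr, "ci": [res.cox.cox_ci_low, res.cox.cox_ci_high], "p": res.cox.cox_p,
                }
            except _stats.NonIdentifiableError as e:
                summary["cox_kl_continuous"] = {"skipped": str(e)}

    res.summary = summary
    if out_dir is not None:
        _write_outputs(res, Path(out_dir))
    return res


def _write_outputs(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res.cells.to_csv(out / "cells_classified.csv", index=False)
    for sys_name, df in res.composition_tables.items():
        df.to_csv(out / f"composition_{sys_name}.csv", index=False)
        res.si_tables[sys_name].to_csv(out / f"shannon_{sys_name}.csv", index=False)
    for sys_name, assign in res.cluster_assignments.items():
        lab = assign.labels.reset_index()
        lab.to_csv(out / f"clusters_{sys_name}.csv", index=False)
        np.savetxt(out / f"linkage_{sys_name}.tsv", assign.linkage_matrix, delimiter="\t")
        res.cluster_summaries[sys_name].to_csv(out / f"cluster_summary_{sys_name}.csv", index=False)
    if res.er_table is not None:
        res.er_table.to_csv(out / "er_status.csv", index=False)
    if res.spatial_profiles:
        pd.DataFrame(
            [
                {"patient_id": p.patient_id, "timepoint": p.timepoint, "n_scored": p.n_scored,
                 "f_cluster": p.freqs[0], "f_scatter": p.freqs[1], "f_mix": p.freqs[2],
                 "sample_class": p.sample_class, "ternary_x": p.ternary_xy[0], "ternary_y": p.ternary_xy[1]}
                for p in res.spatial_profiles
            ]
        ).to_csv(out / "spatial_profiles.csv", index=False)
    if res.shift_df is not None:
        res.shift_df.to_csv(out / "clonal_shift.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(res.summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_report(res, out / "report.txt")
    if res.config.get("figures"):
        _write_figures(res, out)


def _write_report(res: PipelineResult, path: Path) -> None:
    s = res.summary
    lines = [
        "ithfish run report",
        "==================",
        f"patients: {s['n_patients']}   cells: {s['n_cells']}",
        f"excluded samples: {s['excluded_samples'] or 'none'}",
        "",
        "conventions in force:",
    ]
    lines += [f"  {k}: {v}" for k, v in s["conventions"].items()]
    lines += ["", "thresholds:"] + [f"  {k}: {v}" for k, v in s["thresholds"].items()]
    if "mean_shannon_bits" in s:
        lines += ["", "mean Shannon index (bits) by system:"]
        lines += [f"  {k}: {v:.3f}" for k, v in s["mean_shannon_bits"].items()]
    if "clonal_shift" in s:
        cs = s["clonal_shift"]
        lines += ["", f"clonal shift ({cs['system']}): {cs['n_paired_patients']} paired patients, "
                      f"median K-L {cs['kl_median_bits']:.3f} bits, split {cs['n_high']}/{cs['n_low']}"]
    if "survival" in s and "logrank_p" in s.get("survival", {}):
        lines += [f"log-rank ({s['survival']['endpoint']}): p = {s['survival']['logrank_p']:.4g}"]
    path.write_text("\n".join(lines) + "\n")


def _write_figures(res: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if res.shift_df is not None and len(res.shift_df):
        delta_cols = [c for c in res.shift_df.columns if c.startswith("delta_")]
        fig, ax = plt.subplots(figsize=(8, 4))
        bottom_pos = np.zeros(len(res.shift_df))
        bottom_neg = np.zeros(len(res.shift_df))
        x = np.arange(len(res.shift_df))
        for c in delta_cols:
            v = res.shift_df[c].to_numpy()
            base = np.where(v >= 0, bottom_pos, bottom_neg)
            ax.bar(x, v, bottom=base, label=c.removeprefix("delta_"))
            bottom_pos += np.maximum(v, 0)
            bottom_neg += np.minimum(v, 0)
        ax.set_xticks(x, res.shift_df["patient_id"], rotation=90, fontsize=6)
        ax.set_ylabel("fraction change (post - pre)")
        ax.set_title("per-patient category shifts, sorted by decreasing K-L")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "clonal_shift_deltas.png", dpi=150)
        plt.close(fig)

    if res.spatial_profiles:
        from ithfish.spatial import _CORNERS

        fig, ax = plt.subplots(figsize=(5, 5))
        tri = np.vstack([_CORNERS, _CORNERS[0]])
        ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1)
        xs = [p.ternary_xy[0] for p in res.spatial_profiles]
        ys = [p.ternary_xy[1] for p in res.spatial_profiles]
        ax.scatter(xs, ys, s=25, alpha=0.8)
        for corner, name in zip(_CORNERS, ("cluster", "scatter", "mix")):
            ax.annotate(name, corner, fontsize=9, ha="center", va="top")
        ax.set_aspect("equal")
        ax.axis("off")
        fig.savefig(out / "spatial_ternary.png", dpi=150)
        plt.close(fig)

    if res.survival is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, curve in res.survival.km_curves.items():
            ax.step(curve.index, curve["survival"], where="post", label=str(lab))
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        ax.set_title(f"log-rank p = {res.survival.logrank_p:.3g}")
        fig.tight_layout()
        fig.savefig(out / "km_kl_groups.png", dpi=150)
        plt.close(fig)


def scatter_cell_plot(cells: pd.DataFrame, patient_id: str) -> dict[str, pd.DataFrame]:
    """Plot-ready single-cell scatter data for one patient, per timepoint.

    Returns ``{timepoint: frame}`` with ER intensity as x, HER2 intensity as
    y, phenotype as color class and a point size proportional to the *HER2*
    probe area (copy-number proxy).  Timepoints without cells are omitted
    with a warning.
    """
    sub = cells[cells["patient_id"] == patient_id]
    if len(sub) == 0:
        raise ValueError(f"no cells for patient {patient_id!r}")
    if "phenotype" not in sub.columns:
        raise ValueError("cells must be classified first")
    panels = {}
    for tp in ("pre", "post", "metastasis"):
        part = sub[sub["timepoint"] == tp]
        if len(part) == 0:
            if tp in ("pre", "post"):
                warnings.warn(f"patient {patient_id}: no {tp} cells; panel omitted", stacklevel=2)
            continue
        area = part["her2_area_px"].to_numpy(float)
        panels[tp] = pd.DataFrame(
            {
                "x_er": part["er_intensity"].to_numpy(float),
                "y_her2": part["her2_intensity"].to_numpy(float),
                "color": part["phenotype"].to_numpy(),
                "size": 10.0 + 40.0 * area / max(area.max(), 1.0),
            }
        )
    return panels
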