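"""End-to-end orchestration: simulate/ingest -> censor -> clean -> connectomes
-> group contrast -> PLSC, with deterministic tabular outputs.

Every stage writes TSV into the output directory; ``manifest.json`` records
the configuration hash, seed, package versions and per-stage counts (subjects
retained, volumes censored, edges tested), so a run is reproducible
bit-for-bit from its config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import region_table
from .connectome import AccordanceConnectivity, delta_nodal_strength, nodal_strength
from .contrast import (
    P_REPORT,
    Z_THRESHOLD,
    fuse_group_contrasts,
    paired_edge_tests,
    significant_edges,
)
from .plsc import PLSCorrelation, loocv_scores
from .preprocess import (
    BAND_HZ,
    DVARS_THRESH_PCT,
    FD_THRESH_MM,
    MIN_RETAINED,
    bandpass,
    censor_volumes,
    clean_regional_series,
)
from .simulate import CohortSpec, cohort_manifest, generate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Serializable description of one full analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    fd_thresh: float = FD_THRESH_MM
    dvars_thresh: float = DVARS_THRESH_PCT
    min_retained: float = MIN_RETAINED
    band: tuple[float, float] = BAND_HZ
    q_low: float = 0.158
    q_high: float = 0.842
    p_report: float = P_REPORT
    z_threshold: float = Z_THRESHOLD
    n_permutations: int = 5000
    n_bootstrap: int = 200
    run_plsc: bool = True
    seed: int | None = None
    out_dir: str = "neoconn_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        cohort = d["cohort"]
        if cohort.get("dose") is not None:
            cohort["dose"] = list(np.asarray(cohort["dose"]).tolist())
        cohort["planted_edges"] = {
            g: [list(e) for e in edges] for g, edges in cohort["planted_edges"].items()
        }
        cohort["dose_effect_nodes"] = [list(s) for s in cohort["dose_effect_nodes"]]
        d["band"] = list(d["band"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    if spec.n_regions == 90:
        names = region_table().set_index("label")["name"]
    else:  # non-atlas configurations get positional labels
        names = pd.Series(
            [f"region_{k}" for k in range(1, spec.n_regions + 1)],
            index=np.arange(1, spec.n_regions + 1),
        )

    cohort = generate_cohort(spec)
    _write_tsv(cohort_manifest(cohort), out / "cohort.tsv")

    # --- censoring + cleaning + connectomes ------------------------------
    conn = AccordanceConnectivity(q_low=config.q_low, q_high=config.q_high)
    per_group: dict[str, dict] = {}
    counts = {"subjects_total": len(cohort), "subjects_excluded": 0, "volumes_censored": 0}
    excluded = []
    for sub in cohort:
        mats = {}
        censored = 0
        ok = True
        for run_id, run, motion in (("run1", sub.run1, sub.motion1), ("run2", sub.run2, sub.motion2)):
            cres = censor_volumes(
                motion,
                fd_thresh=config.fd_thresh,
                dvars_thresh=config.dvars_thresh,
                min_retained=config.min_retained,
            )
            censored += int((~cres.keep_mask).sum())
            if not cres.include_subject:
                ok = False
                break
            nuisance = np.column_stack([motion.fd, motion.dvars])
            cleaned = clean_regional_series(run, nuisance=nuisance, censor=cres)
            filtered = bandpass(cleaned, *config.band)
            mats[run_id] = conn.fit(
                [filtered.signals]).transform([filtered.signals])[0]
        counts["volumes_censored"] += censored
        if not ok:
            counts["subjects_excluded"] += 1
            excluded.append(sub.subject_id)
            logger.warning("subject %s excluded: <%.0f%% volumes retained",
                           sub.subject_id, 100 * config.min_retained)
            continue
        per_group.setdefault(sub.group, {"subjects": [], "run1": [], "run2": [], "dose": []})
        per_group[sub.group]["subjects"].append(sub.subject_id)
        per_group[sub.group]["run1"].append(mats["run1"])
        per_group[sub.group]["run2"].append(mats["run2"])
        per_group[sub.group]["dose"].append(sub.dose)

    # --- per-group edge contrasts ----------------------------------------
    group_stats = {}
    for grp, data in sorted(per_group.items()):
        stats_df = paired_edge_tests(np.stack(data["run1"]), np.stack(data["run2"]))
        group_stats[grp] = stats_df
        _write_tsv(stats_df, out / f"edge_stats_{grp}.tsv")
        report = stats_df[(~stats_df["degenerate"]) & (stats_df["p"] < config.p_report)]
        _write_tsv(
            _name_edges(report[["region_a", "region_b", "p", "d"]], names),
            out / f"table_{grp}.tsv",
        )
    counts["edges_tested"] = 0 if not group_stats else int(
        next(iter(group_stats.values())).shape[0]
    )

    # --- PM vs PC fusion --------------------------------------------------
    manifest_extra: dict = {}
    if {"PM", "PC"} <= group_stats.keys():
        fused = fuse_group_contrasts(group_stats["PM"], group_stats["PC"])
        _write_tsv(fused, out / "fused_contrast.tsv")
        hits = significant_edges(fused, threshold=config.z_threshold)
        _write_tsv(
            _name_edges(hits[["region_a", "region_b", "z_diff"]], names),
            out / "table_fused.tsv",
        )
        manifest_extra["n_fused_significant"] = int(hits.shape[0])

    # --- PLSC dose-response ----------------------------------------------
    if config.run_plsc and "PM" in per_group and all(
        d is not None for d in per_group["PM"]["dose"]
    ):
        pm = per_group["PM"]
        X = np.stack(
            [delta_nodal_strength(r1, r2) for r1, r2 in zip(pm["run1"], pm["run2"])]
        )
        y = np.asarray(pm["dose"], dtype=float)
        model = PLSCorrelation(
            n_permutations=config.n_permutations,
            n_bootstrap=config.n_bootstrap,
            random_state=config.seed,
        ).fit(X, y)
        cv = loocv_scores(X, y, subject_ids=pm["subjects"])
        sal = pd.DataFrame(
            {
                "region": names.to_numpy(),
                "salience": model.x_saliences_,
                "boot_mean": model.boot_mean_,
                "boot_p5": model.boot_low_,
                "boot_p95": model.boot_high_,
                "robust": model.robust_mask_,
            }
        )
        _write_tsv(sal, out / "plsc_saliences.tsv")
        _write_tsv(cv.scores, out / "plsc_scores.tsv")
        delta_df = pd.DataFrame(X, columns=names.to_numpy())
        delta_df.insert(0, "dose", y)
        delta_df.insert(0, "subject", pm["subjects"])
        _write_tsv(delta_df, out / "plsc_design.tsv")
        manifest_extra["plsc"] = {
            "singular_value": float(model.singular_value_),
            "p_value": float(model.p_value_),
            "n_robust": int(model.robust_mask_.sum()),
            "loocv_r_brain": cv.r_brain,
            "loocv_r_outcome": cv.r_outcome,
        }
    elif config.run_plsc:
        logger.info("PLSC stage skipped: no PM dose covariate available")
        manifest_extra["plsc"] = "skipped (no PM dose covariate)"

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "counts": counts,
        "excluded_subjects": excluded,
        **manifest_extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _name_edges(df: pd.DataFrame, names: pd.Series) -> pd.DataFrame:
    out = df.copy()
    out["region_a"] = out["region_a"].map(names)
    out["region_b"] = out["region_b"].map(names)
    return out


def render_tables(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Re-read a completed run's publication-style tables, keyed by name."""
    out = Path(out_dir)
    tables = {}
    for path in sorted(out.glob("table_*.tsv")):
        tables[path.stem] = pd.read_csv(path, sep="\t")
    for name in ("plsc_saliences", "plsc_scores"):
        path = out / f"{name}.tsv"
        if path.exists():
            tables[name] = pd.read_csv(path, sep="\t")
    return tables
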