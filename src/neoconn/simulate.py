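"""Synthetic neonatal resting-state cohorts.

Emulates the data structure of a two-run music-listening study in newborns:
three groups (full-term controls FT, preterm controls PC, preterm-music PM;
16/15/15 subjects), two 300-volume runs at TR 1.6 s, 90 atlas regions, and a
per-PM-subject "dose" covariate — the number of music-intervention sessions
during hospitalisation, drawn to match a 25 +/- 8.92 (range 7-35) profile.

Signal model: stationary Gaussian AR(1) (lag coefficient 0.3) whose
innovation covariance is a unit-diagonal region covariance with mild block
structure. Run-2 effects are planted by adding coupling increments to chosen
off-diagonal entries before sampling. Dose effects add, for PM subjects,
clique increments among designated "positive" and "negative" node sets whose
per-subject magnitude moves up (positive set) or down (negative set) with a
latent variable correlated with the standardized dose at a controlled
generating correlation, so the true delta-nodal-strength/dose correlation is
known. Motion spikes inject spatially heterogeneous intensity jumps plus an
FD exceedance at the same volume, so FD- and DVARS-based censoring can be
exercised jointly.

Not modelled (deliberately): hemodynamic forward models, physiological noise,
scanner artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MotionTrace, RegionalRun, compute_dvars

GROUPS = ("FT", "PC", "PM")
DOSE_MEAN, DOSE_SD, DOSE_RANGE = 25.0, 8.92, (7, 35)


@dataclass
class CohortSpec:
    """Generative description of one synthetic cohort.

    The defaults restate the emulated study design; effect-size fields default
    to a null cohort (nothing planted).

    Parameters
    ----------
    n_per_group : dict
        Subjects per group; default FT 16, PC 15, PM 15.
    planted_edges : dict
        group -> list of ``(region_i, region_j, delta_coupling)``: run-2
        coupling increments shared by all subjects of the group.
    dose : array or None
        Session counts for the PM subjects; drawn from the study's profile
        (normal 25 +/- 8.92, clipped to [7, 35], rounded) when None.
    dose_effect_nodes : (tuple, tuple)
        (positive node set, negative node set): regions whose run-2 clique
        increments scale up / down with dose.
    dose_effect_r : float
        Generating correlation between dose and the per-subject increment.
    dose_base_delta, dose_slope : float
        Increment = ``base * (1 +/- slope * t)`` (clipped to keep the
        covariance valid), ``t`` the dose-linked latent variable.
    noise_sd : float
        Fluctuation SD in signal units about ``baseline_mean`` (1% of 1000,
        a typical resting BOLD fluctuation scale; accordance is invariant to
        this scale, which only sets the baseline DVARS level ~1.2%).
    spike_rate : float
        Per-volume probability of a motion spike; 0.03 reproduces the ~10-15%
        frame loss the emulated study reports.
    """

    n_per_group: dict = field(default_factory=lambda: {"FT": 16, "PC": 15, "PM": 15})
    n_regions: int = 90
    n_volumes: int = 300
    tr: float = 1.6
    planted_edges: dict = field(default_factory=dict)
    dose: np.ndarray | None = None
    dose_effect_nodes: tuple = ((), ())
    dose_effect_r: float = 0.9
    dose_base_delta: float = 0.4
    dose_slope: float = 0.8
    max_delta: float = 0.85
    ar_coef: float = 0.3
    block_size: int = 15
    block_corr: float = 0.1
    baseline_mean: float = 1000.0
    noise_sd: float = 10.0
    spike_rate: float = 0.03
    spike_amp: float = 8.0
    seed: int | None = None

    def validate(self) -> None:
        if set(self.n_per_group) - set(GROUPS):
            raise ValueError(f"groups must be among {GROUPS}")
        for grp, edges in self.planted_edges.items():
            if grp not in GROUPS:
                raise ValueError(f"unknown group {grp!r} in planted_edges")
            for i, j, _ in edges:
                if i == j:
                    raise ValueError(f"planted edge ({i},{j}) is a self-loop")
                if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                    raise ValueError(f"planted edge ({i},{j}) outside region range")
        for nodes in self.dose_effect_nodes:
            for u in nodes:
                if not 0 <= u < self.n_regions:
                    raise ValueError(f"dose-effect node {u} outside region range")
        if self.dose is not None and len(self.dose) != self.n_per_group.get("PM", 0):
            raise ValueError("dose length must equal the PM group size")
        if not 0 <= self.spike_rate < 1:
            raise ValueError("spike_rate must be a probability")
        if not -1 <= self.dose_effect_r <= 1:
            raise ValueError("dose_effect_r must be a correlation")


@dataclass
class SyntheticSubject:
    """One simulated subject: two runs, two motion traces, planted truth."""

    subject_id: str
    group: str
    run1: RegionalRun
    run2: RegionalRun
    motion1: MotionTrace
    motion2: MotionTrace
    dose: int | None
    ground_truth: dict  # {"edges": [(i, j, delta)], "nodal_delta": array}


def _clique_edges(nodes: tuple) -> list[tuple[int, int]]:
    nodes = tuple(nodes)
    return [(nodes[a], nodes[b]) for a in range(len(nodes)) for b in range(a + 1, len(nodes))]


def _base_covariance(spec: CohortSpec) -> np.ndarray:
    """Unit-diagonal covariance with mild contiguous-block correlation."""
    n = spec.n_regions
    cov = np.eye(n)
    if spec.block_corr:
        for start in range(0, n, spec.block_size):
            stop = min(start + spec.block_size, n)
            cov[start:stop, start:stop] = spec.block_corr
        np.fill_diagonal(cov, 1.0)
    return cov


def _planted_covariance(base: np.ndarray, edges: list[tuple[int, int, float]]) -> np.ndarray:
    cov = base.copy()
    for i, j, delta in edges:
        cov[i, j] += delta
        cov[j, i] += delta
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "planted covariance is not positive-definite; lower delta_coupling"
        ) from None
    return cov


def _sample_ar1(cov: np.ndarray, n_volumes: int, phi: float, rng) -> np.ndarray:
    """Stationary AR(1) with stationary covariance ``cov``; (n_regions, n_volumes)."""
    chol = np.linalg.cholesky(cov)
    n = cov.shape[0]
    innov = chol @ rng.standard_normal((n, n_volumes))
    x = np.empty((n, n_volumes))
    x[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n_volumes):
        x[:, t] = phi * x[:, t - 1] + scale * innov[:, t]
    return x


def _make_run(spec: CohortSpec, cov: np.ndarray, rng) -> tuple[RegionalRun, MotionTrace]:
    x = _sample_ar1(cov, spec.n_volumes, spec.ar_coef, rng)
    signals = spec.baseline_mean + spec.noise_sd * x

    fd = np.abs(rng.normal(0.1, 0.08, size=spec.n_volumes)).clip(max=0.45)
    fd[0] = 0.0
    spikes = np.flatnonzero(rng.random(spec.n_volumes) < spec.spike_rate)
    spikes = spikes[spikes > 0]  # volume 0 has FD/DVARS defined as 0
    for t in spikes:
        signals[:, t] += spec.noise_sd * spec.spike_amp * rng.standard_normal(spec.n_regions)
        fd[t] = 0.6 + rng.exponential(0.3)
    dvars = compute_dvars(signals)
    run = RegionalRun(signals=signals, tr=spec.tr)
    return run, MotionTrace(fd=fd, dvars=dvars)


def _dose_latents(dose: np.ndarray, r: float, rng) -> np.ndarray:
    """Latent per-subject variable with corr(dose, t) = r in population."""
    z = (dose - dose.mean()) / dose.std(ddof=1)
    eta = rng.standard_normal(dose.size)
    return r * z + np.sqrt(max(0.0, 1 - r**2)) * eta


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Simulate the full three-group cohort described by ``spec``.

    Run 1 is always drawn from the baseline covariance; run 2 from the
    baseline plus the group's planted edge increments plus, for PM subjects,
    the dose-scaled clique increments on the dose-effect node sets. A planted
    covariance that is not positive-definite raises with a diagnostic.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = _base_covariance(spec)

    n_pm = spec.n_per_group.get("PM", 0)
    if spec.dose is not None:
        dose = np.asarray(spec.dose, dtype=float)
    else:
        dose = np.round(
            rng.normal(DOSE_MEAN, DOSE_SD, size=n_pm).clip(*DOSE_RANGE)
        )
    pos_nodes, neg_nodes = spec.dose_effect_nodes
    has_dose_effect = (len(pos_nodes) + len(neg_nodes)) > 0 and n_pm > 0
    latents = _dose_latents(dose, spec.dose_effect_r, rng) if has_dose_effect else None

    cohort: list[SyntheticSubject] = []
    for group in GROUPS:
        n_sub = spec.n_per_group.get(group, 0)
        group_edges = [tuple(e) for e in spec.planted_edges.get(group, [])]
        for k in range(n_sub):
            dose_edges = []
            if group == "PM" and has_dose_effect:
                t = latents[k]
                for sign, nodes in ((+1, pos_nodes), (-1, neg_nodes)):
                    delta = spec.dose_base_delta * (1 + sign * spec.dose_slope * t)
                    delta = float(np.clip(delta, 0.0, spec.max_delta))
                    dose_edges += [(i, j, delta) for i, j in _clique_edges(nodes)]
            edges = list(group_edges) + dose_edges
            cov2 = _planted_covariance(base, edges) if edges else base
            run1, motion1 = _make_run(spec, base, rng)
            run2, motion2 = _make_run(spec, cov2, rng)
            nodal = np.zeros(spec.n_regions)
            for i, j, delta in edges:
                nodal[i] += delta
                nodal[j] += delta
            cohort.append(
                SyntheticSubject(
                    subject_id=f"{group}{k + 1:02d}",
                    group=group,
                    run1=run1,
                    run2=run2,
                    motion1=motion1,
                    motion2=motion2,
                    dose=int(dose[k]) if group == "PM" and n_pm else None,
                    ground_truth={
                        "edges": edges,
                        "group_edges": group_edges,
                        "dose_edges": dose_edges,
                        "nodal_delta": nodal,
                    },
                )
            )
    return cohort


def ground_truth_report(cohort: list[SyntheticSubject]) -> dict:
    """Planted effects of a cohort, for parameter-recovery tests.

    Returns ``{"edges": DataFrame, "nodal": DataFrame}``: the group-level
    planted edge deltas (group, region_a, region_b, delta; one row per planted
    edge) and, for PM subjects, per-region true nodal deltas alongside the
    dose (these include the per-subject dose-scaled clique increments).
    """
    edge_rows, nodal_rows = [], []
    seen_groups = set()
    for sub in cohort:
        if sub.group not in seen_groups:  # group edges are uniform within a group
            seen_groups.add(sub.group)
            for i, j, delta in sub.ground_truth["group_edges"]:
                a, b = (i, j) if i < j else (j, i)
                edge_rows.append(
                    {"group": sub.group, "region_a": a, "region_b": b, "delta": delta}
                )
        if sub.group == "PM":
            nodal = sub.ground_truth["nodal_delta"]
            for region in np.flatnonzero(nodal):
                nodal_rows.append(
                    {
                        "subject": sub.subject_id,
                        "dose": sub.dose,
                        "region": int(region),
                        "nodal_delta": nodal[region],
                    }
                )
    return {
        "edges": pd.DataFrame(
            edge_rows, columns=["group", "region_a", "region_b", "delta"]
        ),
        "nodal": pd.DataFrame(
            nodal_rows, columns=["subject", "dose", "region", "nodal_delta"]
        ),
    }


def cohort_manifest(cohort: list[SyntheticSubject]) -> pd.DataFrame:
    """Tabular cohort summary (subject, group, dose, volumes per run)."""
    return pd.DataFrame(
        {
            "subject": [s.subject_id for s in cohort],
            "group": [s.group for s in cohort],
            "dose": [s.dose if s.dose is not None else "" for s in cohort],
            "n_volumes_run1": [s.run1.n_volumes for s in cohort],
            "n_volumes_run2": [s.run2.n_volumes for s in cohort],
        }
    )
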