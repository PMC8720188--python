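"""Edge-wise pre/post inference and the between-group z-fusion contrast.

Per group, each upper-triangle edge of the connectome gets a one-sided paired
t-test for increased coupling in run 2 (after the stimulus) versus run 1,
plus a paired Cohen's d (mean of differences over SD of differences). To
contrast the music-exposed preterm group (PM) against preterm controls (PC),
the per-edge one-sided p-values are mapped to z-scores with the normal
quantile function and fused as

    z_diff = (z_PM - z_PC) / sqrt(2)

which is standard normal per edge under the joint null with independent
groups (the raw difference has variance 2 by the variance sum law). Edges
with z_diff >= 2.58 (p = .005 one-sided) form the reported significant set.

No multiplicity correction is applied, by design: the study design this
mirrors reports uncorrected p-values (small samples) with effect sizes
alongside.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z_THRESHOLD = 2.58  # one-sided p = .005 on the fused scale
P_REPORT = 0.001  # default per-group reporting filter


def upper_triangle_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices (a < b) of the upper-triangle edges, fixed order."""
    return np.triu_indices(n_regions, k=1)


def edge_vector(conn: np.ndarray) -> np.ndarray:
    """Flatten a symmetric connectome to its upper-triangle edge vector."""
    conn = np.asarray(conn)
    ia, ib = upper_triangle_index(conn.shape[0])
    return conn[ia, ib]


def paired_edge_tests(
    conn_run1: np.ndarray, conn_run2: np.ndarray, region_ids: np.ndarray | None = None
) -> pd.DataFrame:
    """One-sided paired t-tests per edge, run 2 > run 1.

    Parameters
    ----------
    conn_run1, conn_run2 : array, (n_subjects, n_regions, n_regions)
        Per-subject connectomes, paired by position.

    Returns
    -------
    DataFrame with columns ``region_a``, ``region_b`` (labels, a < b), ``t``,
    ``p`` (one-sided), ``d`` (paired Cohen's d), ``n``, ``degenerate``.
    Zero-variance edges are flagged degenerate (t, p, d = NaN) and logged;
    they are excluded from any downstream fusion.
    """
    c1 = np.asarray(conn_run1, dtype=float)
    c2 = np.asarray(conn_run2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 3:
        raise ValueError("expected matching (n_subjects, n_regions, n_regions) stacks")
    n_sub, n_reg, _ = c1.shape
    if n_sub < 3:
        raise ValueError("need at least 3 paired subjects")
    ia, ib = upper_triangle_index(n_reg)
    diff = c2[:, ia, ib] - c1[:, ia, ib]  # (n_subjects, n_edges)

    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    degenerate = sd == 0
    t = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    d = np.full(mean.shape, np.nan)
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n_sub))
    p[ok] = stats.t.sf(t[ok], df=n_sub - 1)
    d[ok] = mean[ok] / sd[ok]
    if degenerate.any():
        logger.warning(
            "%d degenerate (zero-variance) edges excluded from edge tests",
            int(degenerate.sum()),
        )
    if region_ids is None:
        region_ids = np.arange(1, n_reg + 1)
    region_ids = np.asarray(region_ids)
    return pd.DataFrame(
        {
            "region_a": region_ids[ia],
            "region_b": region_ids[ib],
            "t": t,
            "p": p,
            "d": d,
            "n": n_sub,
            "degenerate": degenerate,
        }
    )


def p_to_z(p: np.ndarray | float) -> np.ndarray | float:
    """Map one-sided p-values to z-scores via the normal quantile function.

    z = Phi^-1(1 - p): small p (strong run-2 increase) maps to large positive
    z. p exactly 0 or 1 is clamped to the nearest representable value with a
    warning.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    eps = np.finfo(float).eps
    if np.any(arr <= 0) or np.any(arr >= 1):
        warnings.warn("p-values at {0, 1} clamped to representable range", stacklevel=2)
        arr = np.clip(arr, tiny, 1 - eps)
    z = stats.norm.isf(arr)
    return z if np.ndim(p) else float(z)


def z_fusion(z_pm: np.ndarray, z_pc: np.ndarray) -> np.ndarray:
    """Fuse two independent per-edge z maps: (z_PM - z_PC) / sqrt(2)."""
    z_pm = np.asarray(z_pm, dtype=float)
    z_pc = np.asarray(z_pc, dtype=float)
    if z_pm.shape != z_pc.shape:
        raise ValueError("z maps must align edge-for-edge")
    return (z_pm - z_pc) / np.sqrt(2.0)


def fuse_group_contrasts(
    stats_pm: pd.DataFrame, stats_pc: pd.DataFrame
) -> pd.DataFrame:
    """Build the fused z_diff table from two groups' edge-test tables.

    Edges degenerate in either group are dropped. Returns region_a, region_b,
    z_pm, z_pc, z_diff.
    """
    keys = ["region_a", "region_b"]
    merged = stats_pm.merge(stats_pc, on=keys, suffixes=("_pm", "_pc"))
    merged = merged[~(merged["degenerate_pm"] | merged["degenerate_pc"])]
    z_pm = p_to_z(merged["p_pm"].to_numpy())
    z_pc = p_to_z(merged["p_pc"].to_numpy())
    out = merged[keys].copy()
    out["z_pm"] = z_pm
    out["z_pc"] = z_pc
    out["z_diff"] = z_fusion(z_pm, z_pc)
    return out.reset_index(drop=True)


def significant_edges(
    fused: pd.DataFrame, threshold: float = Z_THRESHOLD
) -> pd.DataFrame:
    """Edges whose fused z_diff meets the threshold, sorted descending."""
    hits = fused[fused["z_diff"] >= threshold]
    return hits.sort_values("z_diff", ascending=False).reset_index(drop=True)
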