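"""Volume censoring and regional-signal cleaning.

The path from a raw run to analysable regional time series:

1. motion-based frame censoring (framewise displacement / DVARS thresholds with
   a scrubbing window, and a 50% retention rule for subject inclusion),
2. gray-matter masking of an atlas label image against tissue-probability maps,
3. joint nuisance regression + linear detrending, with optional voxel-to-region
   averaging,
4. zero-phase Butterworth band-pass filtering.

Censored volumes are dropped and the retained series concatenated; no
interpolation is attempted. All signal arrays are ``(n_series, n_volumes)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

logger = logging.getLogger(__name__)

#: default censoring configuration (thresholds in mm / percent, window in volumes)
FD_THRESH_MM = 0.5
DVARS_THRESH_PCT = 3.0
SCRUB_BEFORE = 1
SCRUB_AFTER = 2
MIN_RETAINED = 0.5
BAND_HZ = (0.01, 0.1)


@dataclass
class MotionTrace:
    """Per-volume motion summaries for one run.

    Parameters
    ----------
    fd : array
        Framewise displacement in mm (Power convention); element 0 is 0.
    dvars : array
        Rate of global BOLD change, percent of run-mean intensity; element 0
        is 0.
    """

    fd: np.ndarray
    dvars: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.fd.ndim != 1 or self.dvars.ndim != 1:
            raise ValueError("fd and dvars must be 1-D")
        if self.fd.shape != self.dvars.shape:
            raise ValueError(
                f"fd and dvars lengths differ: {self.fd.size} vs {self.dvars.size}"
            )
        if self.fd.size == 0:
            raise ValueError("empty motion trace")
        if np.any(self.fd < 0) or np.any(self.dvars < 0):
            raise ValueError("fd and dvars must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.fd.size


@dataclass
class CensorResult:
    """Outcome of frame censoring for one run."""

    keep_mask: np.ndarray
    retained_fraction: float
    include_subject: bool


@dataclass
class RegionalRun:
    """One run's regional signal matrix.

    ``signals`` is ``(n_regions, n_volumes)``; ``keep_mask`` records which of
    the original volumes the columns correspond to (None means all volumes).
    """

    signals: np.ndarray
    tr: float
    region_ids: np.ndarray = field(default=None)
    keep_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (n_regions, n_volumes)")
        if self.region_ids is None:
            self.region_ids = np.arange(1, self.signals.shape[0] + 1)
        self.region_ids = np.asarray(self.region_ids)

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[1]


def censor_volumes(
    motion: MotionTrace,
    fd_thresh: float = FD_THRESH_MM,
    dvars_thresh: float = DVARS_THRESH_PCT,
    scrub_before: int = SCRUB_BEFORE,
    scrub_after: int = SCRUB_AFTER,
    min_retained: float = MIN_RETAINED,
) -> CensorResult:
    """Scrub motion-corrupted volumes.

    A volume whose FD exceeds ``fd_thresh`` (mm) or whose DVARS exceeds
    ``dvars_thresh`` (percent) is removed together with the ``scrub_before``
    preceding and ``scrub_after`` following volumes; windows from multiple
    triggers union and are clipped at run boundaries. The subject is flagged
    for inclusion when at least ``min_retained`` of the volumes survive.
    """
    n = motion.n_volumes
    bad = (motion.fd > fd_thresh) | (motion.dvars > dvars_thresh)
    keep = np.ones(n, dtype=bool)
    for t in np.flatnonzero(bad):
        lo = max(0, t - scrub_before)
        hi = min(n, t + scrub_after + 1)
        keep[lo:hi] = False
    retained = float(keep.mean())
    return CensorResult(
        keep_mask=keep,
        retained_fraction=retained,
        include_subject=retained >= min_retained,
    )


def compute_dvars(volumes: np.ndarray, brain_mask: np.ndarray | None = None) -> np.ndarray:
    """DVARS: spatial SD of successive difference frames, as percent.

    ``volumes`` is an intensity array whose *last* axis is time (a 4-D scan or
    a 2-D voxels-by-volumes matrix). The result is expressed as a percent of
    the run-mean within-mask intensity; element 0 is 0 by convention.
    """
    vols = np.asarray(volumes, dtype=float)
    if vols.shape[-1] < 2:
        raise ValueError("need at least 2 volumes")
    flat = vols.reshape(-1, vols.shape[-1])
    if brain_mask is not None:
        m = np.asarray(brain_mask, dtype=bool).reshape(-1)
        flat = flat[m]
    if flat.shape[0] == 0:
        raise ValueError("empty brain mask")
    diffs = np.diff(flat, axis=1)
    sd = diffs.std(axis=0)  # spatial SD of each difference frame
    ref = flat.mean()
    if ref == 0:
        raise ValueError("zero mean intensity; cannot express DVARS as percent")
    out = np.zeros(flat.shape[1])
    out[1:] = 100.0 * sd / abs(ref)
    return out


def framewise_displacement(params: np.ndarray, radius_mm: float = 50.0) -> np.ndarray:
    """FD from 6 rigid-body parameters (3 translations mm, 3 rotations rad).

    Power's formulation: sum of absolute backward differences, rotations
    converted to arc length on a sphere of ``radius_mm``. Element 0 is 0.
    """
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("params must be (n_volumes, 6)")
    d = np.abs(np.diff(p, axis=0))
    d[:, 3:] *= radius_mm
    return np.concatenate([[0.0], d.sum(axis=1)])


def mask_atlas_by_gm(
    p_gm: np.ndarray, p_wm: np.ndarray, p_csf: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Restrict an atlas label image to gray-matter voxels.

    A voxel keeps its label iff P(GM) >= P(WM) and P(GM) >= P(CSF); ties keep
    the voxel (removal requires a strict deficit). Others become background 0.
    """
    p_gm, p_wm, p_csf = (np.asarray(a, dtype=float) for a in (p_gm, p_wm, p_csf))
    labels = np.asarray(labels)
    if not (p_gm.shape == p_wm.shape == p_csf.shape == labels.shape):
        raise ValueError("tissue maps and labels must share a shape")
    for name, a in (("p_gm", p_gm), ("p_wm", p_wm), ("p_csf", p_csf)):
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError(f"{name} outside [0, 1]")
    is_gm = (p_gm >= p_wm) & (p_gm >= p_csf)
    return np.where(is_gm, labels, 0)


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each row of ``y`` against ``design`` columns."""
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return y - (design @ beta).T


def clean_regional_series(
    run: RegionalRun,
    nuisance: np.ndarray | None = None,
    censor: CensorResult | None = None,
    labels: np.ndarray | None = None,
) -> RegionalRun:
    """Censor, residualize against nuisance + trend, and (optionally) average to regions.

    Censored volumes are dropped first; the retained series is residualized in
    one design matrix containing an intercept, a linear trend, and any
    ``nuisance`` regressors (rows = volumes, full-length or already-censored).
    When ``labels`` gives a per-series atlas label (0 = background), series are
    averaged within labels after residualization; a label with no contributing
    series yields a NaN row and a logged warning.
    """
    sig = run.signals
    keep = None
    if censor is not None:
        keep = np.asarray(censor.keep_mask, dtype=bool)
        if keep.size != sig.shape[1]:
            raise ValueError("censor mask length does not match volumes")
        sig = sig[:, keep]
    n_kept = sig.shape[1]
    design_cols = [np.ones(n_kept), np.linspace(-1.0, 1.0, n_kept)]
    if nuisance is not None:
        nui = np.asarray(nuisance, dtype=float)
        if nui.ndim == 1:
            nui = nui[:, None]
        if nui.ndim != 2:
            raise ValueError("nuisance must be (n_volumes, n_regressors)")
        if keep is not None and nui.shape[0] == keep.size:
            nui = nui[keep]
        if nui.shape[0] != n_kept:
            raise ValueError(
                f"nuisance rows ({nui.shape[0]}) do not align with retained volumes ({n_kept})"
            )
        design_cols.extend(nui.T)
    design = np.column_stack(design_cols)
    resid = _residualize(sig, design)

    if labels is not None:
        labels = np.asarray(labels)
        if labels.size != resid.shape[0]:
            raise ValueError("labels length must equal number of series")
        region_ids = np.unique(labels[labels != 0])
        out = np.full((region_ids.size, n_kept), np.nan)
        for k, lab in enumerate(region_ids):
            rows = resid[labels == lab]
            if rows.shape[0] == 0:  # pragma: no cover - unique() precludes this
                logger.warning("region %s has no retained voxels; set to missing", lab)
                continue
            out[k] = rows.mean(axis=0)
        resid, ids = out, region_ids
    else:
        ids = run.region_ids
    return RegionalRun(signals=resid, tr=run.tr, region_ids=ids, keep_mask=keep)


def bandpass(
    run: RegionalRun,
    low: float = BAND_HZ[0],
    high: float = BAND_HZ[1],
    order: int = 4,
) -> RegionalRun:
    """Zero-phase Butterworth band-pass over the retained series.

    Pass-band gain is ~1 and the stop band strongly attenuated; applied
    forward-backward (``filtfilt``) so no phase is introduced. The band must
    lie inside (0, Nyquist) for the run's TR.
    """
    nyq = 0.5 / run.tr
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq:.4g}) Hz")
    b, a = sp_signal.butter(order, [low / nyq, high / nyq], btype="bandpass")
    filtered = sp_signal.filtfilt(b, a, run.signals, axis=1)
    return RegionalRun(
        signals=filtered, tr=run.tr, region_ids=run.region_ids, keep_mask=run.keep_mask
    )
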