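"""Scalar readouts for the population-level assays.

Swelling fraction from A540 decay with an alamethicin end point, Ca2+
retention capacity from a Calcium Green pulse train, mitochondrial-stress-
test OCR summaries, calcein/TMRM ROI-timecourse quantification, and the
475/410 ratiometric Ca2+ readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .simulate import AbsorbanceSeries, FluorescenceSeries, OcrSeries, RoiTimecourseSet
from .stats import TestResult, group_compare

__all__ = [
    "SwellingResult",
    "CrcResult",
    "OcrSummary",
    "TimecourseSummary",
    "swollen_fraction",
    "crc",
    "ocr_summary",
    "summarize_timecourse",
    "compare_timecourses",
    "gcamp_ratio",
    "READOUT_DELAY_S",
]

#: Scalar timecourse readouts are taken this long after the addition (8 min).
READOUT_DELAY_S = 480.0

#: Default evaluation delay for the swelling fraction (~9 min after Ca2+).
SWELLING_EVAL_DELAY_S = 540.0


@dataclass(frozen=True)
class SwellingResult:
    """Fraction of swollen mitochondria, normalized to the alamethicin floor."""

    fraction: float
    t_eval: float
    a_baseline: float
    a_eval: float
    a_ala: float

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValidationError("fraction must be clamped to [0, 1]")


@dataclass(frozen=True)
class CrcResult:
    """Calcium retention capacity of a suspension."""

    retained_pulses: int
    crc_nmol_per_mg: float
    release_time: float | None


@dataclass(frozen=True)
class OcrSummary:
    """Protein-normalized, non-mitochondrial-corrected OCR summaries."""

    basal: float            # per ug protein
    oligo_sensitive: float  # per ug protein
    nonmito: float          # per ug protein (the subtracted floor)


@dataclass(frozen=True, eq=False)
class TimecourseSummary:
    """Normalized population traces and the 8-min scalar readout."""

    times: np.ndarray
    calcein_mean: np.ndarray
    calcein_sem: np.ndarray
    tmrm_mean: np.ndarray
    tmrm_sem: np.ndarray
    readout_time: float
    calcein_readout: float
    calcein_readout_sem: float
    tmrm_readout: float
    tmrm_readout_sem: float
    n_rois: int
    condition: str


def _plateau_mean(values: np.ndarray, n: int = 3) -> float:
    """Mean of the last `n` samples — the plateau convention used before
    each injection/event (robust to injection transients)."""
    if values.size < n:
        raise ValidationError(f"need at least {n} samples for a plateau mean")
    return float(values[-n:].mean())


def swollen_fraction(series: AbsorbanceSeries,
                     t_eval_offset: float = SWELLING_EVAL_DELAY_S) -> SwellingResult:
    """Fraction of swollen mitochondria at ca_time + t_eval_offset.

    fraction = (A_baseline - A_eval) / (A_baseline - A_ala), where
    A_baseline is the pre-Ca2+ mean, A_eval the absorbance at the
    evaluation time (linear interpolation), and A_ala the post-alamethicin
    plateau (maximal swelling).  Clamped to [0, 1].
    """
    t, a = series.times, series.a540
    if series.ca_time is None:
        raise ValidationError("series has no Ca2+ addition time to anchor the readout")
    post_ala = a[t > series.ala_time]
    if post_ala.size < 3:
        raise ValidationError("need >= 3 points after alamethicin for the plateau")
    a_ala = _plateau_mean(post_ala)
    pre = a[t < series.ca_time]
    if pre.size == 0:
        raise ValidationError("no pre-Ca2+ baseline samples")
    a_base = float(pre.mean())
    if a_base - a_ala <= 1e-9 * max(1.0, abs(a_base)):
        raise ValidationError(
            "degenerate assay: baseline absorbance does not exceed the "
            "alamethicin floor"
        )
    t_eval = series.ca_time + t_eval_offset
    if t_eval > series.ala_time:
        raise ValidationError("evaluation time falls after alamethicin addition")
    a_eval = float(np.interp(t_eval, t, a))
    frac = (a_base - a_eval) / (a_base - a_ala)
    return SwellingResult(
        fraction=float(np.clip(frac, 0.0, 1.0)),
        t_eval=t_eval, a_baseline=a_base, a_eval=a_eval, a_ala=a_ala,
    )


def crc(series: FluorescenceSeries, pulse_size: float | None = None,
        protein: float | None = None, noise_tolerance_sigmas: float = 3.0) -> CrcResult:
    """Ca2+ retention capacity from a pulse-train fluorescence series.

    A pulse counts as retained when the indicator returns below its
    pre-pulse baseline plus a noise tolerance (3x the pre-assay sd) before
    the next pulse.  CRC = retained x pulse_size / protein in nmol Ca2+ per
    mg protein (uM * ml/mg = nmol/mg).  release_time is the first time the
    signal exceeds the tolerance band and never comes back.
    """
    if series.pulse_times.size < 1:
        raise ValidationError("need at least one pulse")
    pulse_size = series.pulse_size if pulse_size is None else pulse_size
    protein = series.protein if protein is None else protein
    if protein <= 0 or pulse_size <= 0:
        raise ValidationError("pulse_size and protein must be > 0")
    t, f = series.times, series.fluorescence
    pre = f[t < series.pulse_times[0]]
    if pre.size < 3:
        raise ValidationError("need pre-assay samples to estimate noise")
    tol = noise_tolerance_sigmas * float(pre.std(ddof=1)) if pre.size > 1 else 0.0

    retained = 0
    release_time = None
    n = series.pulse_times.size
    for k in range(n):
        p = series.pulse_times[k]
        nxt = series.pulse_times[k + 1] if k + 1 < n else t[-1] + 1.0
        base = float(f[t < p][-3:].mean())
        between = (t > p) & (t < nxt)
        if not between.any():
            break
        if np.any(f[between] <= base + tol):
            retained += 1
        else:
            # uptake failed: the release phase starts here
            exceed = np.flatnonzero((t >= p) & (f > base + tol))
            release_time = float(t[exceed[0]]) if exceed.size else float(p)
            break
    return CrcResult(
        retained_pulses=retained,
        crc_nmol_per_mg=retained * pulse_size / protein,
        release_time=release_time,
    )


def ocr_summary(series: OcrSeries) -> OcrSummary:
    """Basal and oligomycin-sensitive OCR, non-mito corrected, per protein.

    nonmito is the post-rotenone/antimycin plateau; basal is the
    pre-oligomycin plateau minus nonmito; oligo_sensitive is basal minus
    the corrected post-oligomycin plateau.  Everything is divided by the
    protein content, so adding a constant to the raw series cancels out of
    basal and oligo_sensitive.
    """
    t, y = series.times, series.ocr
    inj = dict(series.injections)
    t_oligo, t_fccp = inj["oligomycin"], inj["FCCP"]
    t_aa = inj["antimycin A"]
    post_aa = y[t > t_aa]
    if post_aa.size < 3:
        raise ValidationError("missing rotenone/antimycin plateau")
    nonmito_raw = _plateau_mean(post_aa)
    basal_raw = _plateau_mean(y[t < t_oligo])
    post_oligo_raw = _plateau_mean(y[(t > t_oligo) & (t < t_fccp)])
    basal = (basal_raw - nonmito_raw) / series.protein
    oligo_sensitive = basal - (post_oligo_raw - nonmito_raw) / series.protein
    return OcrSummary(basal=basal, oligo_sensitive=oligo_sensitive,
                      nonmito=nonmito_raw / series.protein)


def _normalize(set_: RoiTimecourseSet, channel: np.ndarray, background: float,
               baseline: str) -> np.ndarray:
    pre = set_.times < set_.addition_time
    if not pre.any():
        raise ValidationError("no pre-addition samples to normalize against")
    sig = channel - background
    if baseline == "pre_mean":
        ref = sig[:, pre].mean(axis=1, keepdims=True)
    elif baseline == "first_frame":
        ref = sig[:, :1]
    else:
        raise ValidationError(f"unknown baseline mode {baseline!r}")
    return sig / ref


def summarize_timecourse(set_: RoiTimecourseSet,
                         baseline: str = "pre_mean") -> TimecourseSummary:
    """Background-subtract, normalize and average an ROI ensemble.

    Each ROI is normalized to its pre-addition baseline (or first frame);
    the population trace is mean +/- SEM across ROIs, with SEM counted over
    ROIs pooled across experiments, matching the reporting convention of
    the imaging panels.  The scalar readout is the normalized value 8 min
    after the addition.
    """
    if set_.n_rois < 2:
        raise ValidationError("need at least 2 ROIs")
    cal = _normalize(set_, set_.calcein, set_.background_calcein, baseline)
    tm = _normalize(set_, set_.tmrm, set_.background_tmrm, baseline)
    n = set_.n_rois
    t_read = set_.addition_time + READOUT_DELAY_S
    if t_read > set_.times[-1]:
        raise ValidationError("recording ends before the 8-min readout")

    def at_readout(mat):
        vals = np.array([np.interp(t_read, set_.times, row) for row in mat])
        return vals

    cal_r = at_readout(cal)
    tm_r = at_readout(tm)
    sem = lambda m: m.std(axis=0, ddof=1) / np.sqrt(n)  # noqa: E731
    return TimecourseSummary(
        times=set_.times,
        calcein_mean=cal.mean(axis=0), calcein_sem=sem(cal),
        tmrm_mean=tm.mean(axis=0), tmrm_sem=sem(tm),
        readout_time=t_read,
        calcein_readout=float(cal_r.mean()),
        calcein_readout_sem=float(cal_r.std(ddof=1) / np.sqrt(n)),
        tmrm_readout=float(tm_r.mean()),
        tmrm_readout_sem=float(tm_r.std(ddof=1) / np.sqrt(n)),
        n_rois=n, condition=set_.condition,
    )


def compare_timecourses(a: RoiTimecourseSet, b: RoiTimecourseSet,
                        channel: str = "calcein",
                        baseline: str = "pre_mean") -> TestResult:
    """Two-sample t-test on per-ROI 8-min readouts of two conditions."""
    vals = []
    for s in (a, b):
        mat = _normalize(s, getattr(s, channel),
                         getattr(s, f"background_{channel}"), baseline)
        t_read = s.addition_time + READOUT_DELAY_S
        vals.append(np.array([np.interp(t_read, s.times, row) for row in mat]))
    return group_compare(vals[0], vals[1])


def gcamp_ratio(f475: np.ndarray, f410: np.ndarray,
                bg475: float = 0.0, bg410: float = 0.0) -> np.ndarray:
    """Ratiometric Ca2+ signal R = (F475 - bg475) / (F410 - bg410).

    Points where the denominator is not positive after background
    subtraction are masked to NaN with a warning.
    """
    f475 = np.asarray(f475, dtype=float)
    f410 = np.asarray(f410, dtype=float)
    if f475.shape != f410.shape:
        raise ValidationError("channel series must have equal length")
    num = f475 - bg475
    den = f410 - bg410
    bad = den <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} ratio points masked (background exceeds signal)",
            RuntimeWarning, stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return r
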