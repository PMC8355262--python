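"""Per-experiment channel statistics and group comparisons.

Implements the three headline single-channel statistics:

* G_max — the largest conductance jump between two stable states completed
  in under 10 ms,
* G_mean — the offset-corrected mean conductance during channel activity in
  the 30 s preceding blocker addition,
* Q_4s — the net charge through the channel over the contiguous 4-s window
  of maximal activity,

together with the inclusion rule (only traces with events outside the noise
range enter the G_mean analysis) and the paired / two-sample t-tests used
for blocker-effect and group comparisons.  Absent statistics are explicit
``None`` markers, never zeros: "no current activity" must stay
distinguishable from a measured zero conductance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sps

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import (
    DegenerateVarianceError,
    PairingError,
    ValidationError,
)
from .idealize import (
    ConductanceLevels,
    Idealization,
    MixtureFit,
    TransitionEvent,
    extract_levels,
    idealize,
)
from .simulate import Trace

__all__ = [
    "ConductanceStats",
    "TestResult",
    "has_events",
    "compute_gmax",
    "compute_gmean",
    "compute_q4s",
    "blocker_effect",
    "group_compare",
]


@dataclass(frozen=True)
class ConductanceStats:
    """Per-experiment channel statistics; None marks an absent value."""

    gmax: float | None           # pS
    gmean: float | None          # pS
    q4s: float | None            # pC
    included: bool
    gmean_window: tuple[float, float] | None = None
    q_window: tuple[float, float] | None = None
    gmean_window_truncated: bool = False

    def __post_init__(self) -> None:
        if not self.included and self.gmean is not None:
            raise ValidationError("excluded traces cannot carry a G_mean")
        if self.q4s is not None and self.q4s < 0:
            raise ValidationError("Q_4s must be >= 0")


@dataclass(frozen=True)
class TestResult:
    """A t-test outcome."""

    statistic: float
    df: float
    p_value: float
    paired: bool
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value must lie in [0, 1]")


def has_events(trace: Trace, fit: MixtureFit,
               config: AnalysisConfig = DEFAULT_CONFIG,
               ideal: Idealization | None = None,
               levels: ConductanceLevels | None = None,
               span: tuple[float, float] | None = None) -> bool:
    """Inclusion rule: does the trace show events outside the noise range?

    True iff at least one non-baseline level survives the
    event-threshold merge rule and at least one dwell on such a level lasts
    min_stable_dwell_ms or longer (within `span`, if given).  A precomputed
    idealization/levels pair may be passed to avoid refitting.
    """
    if levels is None:
        levels = extract_levels(fit, trace.protocol, config)
    if levels.n_levels < 2:
        return False
    if ideal is None:
        ideal = idealize(trace, levels, config)
    seg = ideal.segments
    fs = ideal.sampling_rate
    if span is not None:
        i0, i1 = int(round(span[0] * fs)), int(round(span[1] * fs))
        keep = (seg[:, 1] > i0) & (seg[:, 0] < i1)
        seg = seg[keep]
    min_samples = int(round(config.min_stable_dwell_ms / 1000.0 * fs))
    open_seg = seg[seg[:, 2] > 0]
    return bool(np.any(open_seg[:, 1] - open_seg[:, 0] >= min_samples)) if len(open_seg) else False


def compute_gmax(events: list[TransitionEvent],
                 config: AnalysisConfig = DEFAULT_CONFIG) -> float | None:
    """Largest |delta_g| among events faster than the duration cutoff.

    Returns None (reported downstream as "no current activity") when no
    qualifying event exists.
    """
    fast = [abs(e.delta_g) for e in events
            if e.duration_ms < config.max_transition_duration_ms]
    return max(fast) if fast else None


def compute_gmean(trace: Trace, ideal: Idealization, levels: ConductanceLevels,
                  blocker_time: float,
                  config: AnalysisConfig = DEFAULT_CONFIG,
                  current: np.ndarray | None = None):
    """Mean conductance during activity in the window before the blocker.

    Averages the offset-corrected current over all samples idealized to a
    non-baseline level within [blocker_time - gmean_window_s, blocker_time),
    divided by V_h.  Returns (gmean_pS_or_None, (t0, t1), truncated_flag);
    gmean is None when the window holds no activity.  Pass the
    baseline-corrected signal as `current`.
    """
    fs = trace.protocol.sampling_rate
    vh = trace.protocol.holding_potential
    t0 = blocker_time - config.gmean_window_s
    truncated = t0 < 0
    t0 = max(0.0, t0)
    i0, i1 = int(round(t0 * fs)), int(round(blocker_time * fs))
    if i1 <= i0:
        raise ValidationError("empty G_mean window")
    x = np.asarray(current if current is not None else trace.current, float)
    labels = ideal.labels()[i0:i1]
    if config.include_closed_in_gmean:
        mask = np.ones(labels.size, dtype=bool)
    else:
        mask = labels > 0
    if not mask.any():
        return None, (t0, blocker_time), truncated
    gmean = float(x[i0:i1][mask].mean() / vh * 1000.0)
    return gmean, (t0, blocker_time), truncated


def compute_q4s(trace: Trace, ideal: Idealization, levels: ConductanceLevels,
                config: AnalysisConfig = DEFAULT_CONFIG,
                current: np.ndarray | None = None,
                span: tuple[float, float] | None = None):
    """Net charge over the best contiguous 4-s window (pC).

    Slides a q_interval_s window across `span` (default: whole trace) and
    returns (max trapezoidal integral of the offset-corrected current, the
    winning window).  pA integrated over s gives pC directly.
    """
    fs = trace.protocol.sampling_rate
    x = np.asarray(current if current is not None else trace.current, float)
    if span is not None:
        i0, i1 = int(round(span[0] * fs)), int(round(span[1] * fs))
        x = x[i0:i1]
        offset_t = span[0]
    else:
        offset_t = 0.0
    w = int(round(config.q_interval_s * fs))
    if x.size < w:
        raise ValidationError(
            f"trace span shorter than the {config.q_interval_s} s charge window"
        )
    ct = integrate.cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    q = ct[w:] - ct[:-w]
    i = int(np.argmax(q))
    window = (offset_t + i / fs, offset_t + (i + w) / fs)
    return float(q[i]), window


def _check_groups(*groups):
    for g in groups:
        if len(g) < 2:
            raise ValidationError("each group needs at least 2 observations")


def blocker_effect(pre, post) -> TestResult:
    """Two-sided paired t-test on per-experiment (pre - post) statistics.

    Mirrors the before/after-blocker comparison of G_max across
    experiments.  All-zero differences give t = 0, p = 1; zero-variance
    nonzero differences raise DegenerateVarianceError.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise PairingError("pre and post must pair one value per experiment")
    _check_groups(pre)
    n = pre.size
    d = pre - post
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return TestResult(0.0, n - 1, 1.0, paired=True, n=(n,))
        raise DegenerateVarianceError(
            "paired differences have zero variance but nonzero mean"
        )
    t, p = sps.ttest_rel(pre, post)
    return TestResult(float(t), n - 1, float(p), paired=True, n=(n,))


def group_compare(a, b, welch: bool = False) -> TestResult:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    Set welch=True for the unequal-variance variant.  Identical constant
    groups give t = 0, p = 1; zero-variance groups with different means
    raise DegenerateVarianceError.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_groups(a, b)
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TestResult(0.0, df, 1.0, paired=False, n=(a.size, b.size))
        raise DegenerateVarianceError(
            "both groups have zero variance and different means"
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else (
        a.size + b.size - 2 if not welch else float("nan"))
    return TestResult(float(res.statistic), df, float(res.pvalue),
                      paired=False, n=(a.size, b.size))
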