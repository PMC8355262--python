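"""End-to-end per-trace analysis and preset round-trip batches.

`analyze_trace` chains the full current-analysis procedure: mixture fit,
level extraction, idealization, piecewise-linear offset correction over
closed dwells, a second fit/idealization pass on the corrected signal,
transition detection, inclusion test and the G_max / G_mean / Q_4s
statistics over the pre-blocker span.  `preset_batch` runs it over a batch
of jittered preset simulations and summarizes mean +/- SEM per statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .idealize import (
    ConductanceLevels,
    Idealization,
    MixtureFit,
    TransitionEvent,
    detect_transitions,
    extract_levels,
    fit_mixture,
    idealize,
    piecewise_linear_baseline,
)
from .presets import DEFAULT_BLOCKER_TIME, DEFAULT_DURATION, JITTER_CV, simulate_preset
from .simulate import Trace
from .stats import (
    ConductanceStats,
    compute_gmax,
    compute_gmean,
    compute_q4s,
    has_events,
)

__all__ = ["TraceAnalysis", "analyze_trace", "preset_batch",
           "summarize_batch", "truth_gmax"]


@dataclass(eq=False)
class TraceAnalysis:
    """Everything the pipeline derived from one trace."""

    trace: Trace
    fit: MixtureFit
    levels: ConductanceLevels
    ideal: Idealization
    events: list[TransitionEvent]
    corrected: np.ndarray
    stats: ConductanceStats
    blocker_time: float | None
    gmax_post: float | None  # G_max over the post-blocker span, if any


def analyze_trace(trace: Trace, config: AnalysisConfig = DEFAULT_CONFIG,
                  blocker_time: float | None = None) -> TraceAnalysis:
    """Run the full single-channel analysis on one trace.

    blocker_time defaults to the first intervention timestamp; statistics
    are computed over the pre-blocker span (the whole trace if there is no
    blocker).  Offset correction: a first fit/idealization pass locates
    closed dwells, a piecewise-linear baseline through their means is
    subtracted, and the final fit/idealization runs on the corrected
    signal.
    """
    if blocker_time is None and trace.interventions:
        blocker_time = trace.interventions[0].time
    duration = trace.protocol.duration
    t_end = blocker_time if blocker_time is not None else duration

    # pass 1: locate closed dwells for the offset correction
    fit1 = fit_mixture(trace.current, config=config)
    levels1 = extract_levels(fit1, trace.protocol, config)
    ideal1 = idealize(trace, levels1, config)
    baseline = piecewise_linear_baseline(trace, ideal1)
    corrected = trace.current - baseline

    # pass 2: final fit and idealization on the offset-corrected signal
    fit2 = fit_mixture(corrected, config=config)
    levels2 = extract_levels(fit2, trace.protocol, config)
    ideal2 = idealize(trace, levels2, config, current=corrected)
    events = detect_transitions(ideal2, trace, current=corrected)

    included = has_events(trace, fit2, config, ideal=ideal2, levels=levels2,
                          span=(0.0, t_end))
    pre_events = [e for e in events if e.time < t_end]
    gmax = compute_gmax(pre_events, config)
    gmax_post = None
    if blocker_time is not None and blocker_time < duration:
        # skip the settling window so the block's own closing transient is
        # not scored as post-blocker activity
        t_post = blocker_time + config.post_blocker_settle_s
        post_events = [e for e in events if e.time >= t_post]
        gmax_post = compute_gmax(post_events, config)

    if included:
        gmean, gwin, truncated = compute_gmean(
            trace, ideal2, levels2, t_end, config, current=corrected
        )
        q4s, qwin = compute_q4s(trace, ideal2, levels2, config,
                                current=corrected, span=(0.0, t_end))
    else:
        gmean, gwin, truncated = None, None, False
        q4s, qwin = None, None
    stats = ConductanceStats(
        gmax=gmax, gmean=gmean, q4s=q4s, included=included,
        gmean_window=gwin, q_window=qwin, gmean_window_truncated=truncated,
    )
    return TraceAnalysis(
        trace=trace, fit=fit2, levels=levels2, ideal=ideal2, events=events,
        corrected=corrected, stats=stats, blocker_time=blocker_time,
        gmax_post=gmax_post,
    )


def preset_batch(name: str, n: int = 20, seed: int = 0,
                 config: AnalysisConfig = DEFAULT_CONFIG,
                 duration: float = DEFAULT_DURATION,
                 blocker_time: float = DEFAULT_BLOCKER_TIME,
                 jitter_cv: float = JITTER_CV) -> pd.DataFrame:
    """Simulate and analyze n preset traces; one row per experiment.

    Child seeds are spawned from `seed`, so the batch is reproducible and
    traces are mutually independent.
    """
    rows = []
    children = np.random.SeedSequence(seed).spawn(n)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        trace = simulate_preset(name, seed=rng, duration=duration,
                                blocker_time=blocker_time, jitter_cv=jitter_cv)
        res = analyze_trace(trace, config)
        s = res.stats
        rows.append({
            "experiment": i,
            "preset": name,
            "included": s.included,
            "gmax_pS": s.gmax,
            "gmean_pS": s.gmean,
            "q4s_pC": s.q4s,
            "gmax_post_pS": res.gmax_post,
        })
    return pd.DataFrame(rows)


def summarize_batch(df: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Mean, SEM and n for each statistic of a preset batch (absent values
    are dropped, as in per-experiment reporting)."""
    out = {}
    for col in ("gmax_pS", "gmean_pS", "q4s_pC"):
        vals = df[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            out[col] = {"mean": float("nan"), "sem": float("nan"), "n": 0}
            continue
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        out[col] = {"mean": float(vals.mean()), "sem": sem, "n": int(vals.size)}
    return out


def truth_gmax(trace: Trace, window: tuple[float, float],
               config: AnalysisConfig = DEFAULT_CONFIG) -> float | None:
    """G_max from the simulator's true segmentation (oracle estimator).

    Uses the exact state path to segment the measured current, estimates
    each state's level current as the empirical mean over its dwell samples
    (excluding samples within two filter rise times of any jump), and
    scores the usual fast-transition maximum between stable dwells inside
    `window`.  This keeps the measurement noise of a real analysis while
    bypassing the mixture fit; it exists for statistical-engine calibration
    checks, not as the production path.
    """
    truth = trace.truth
    if truth is None:
        raise ValueError("trace carries no ground-truth path")
    fs = trace.protocol.sampling_rate
    vh = trace.protocol.holding_potential
    x = trace.current
    t = np.arange(x.size) / fs
    guard = 2.0 * 0.34 / trace.protocol.filter_cutoff  # two 10-90% rise times

    jumps = np.append(truth.jump_times, trace.protocol.duration)
    states = truth.states
    # empirical level current per state over guarded dwell cores, using only
    # samples inside the window so disjoint windows give independent estimates
    sums = np.zeros(truth.conductances_pS.size)
    counts = np.zeros(truth.conductances_pS.size)
    dwell_list = []
    for k in range(states.size):
        dwell_list.append((jumps[k], jumps[k + 1], states[k]))
        a = max(jumps[k] + guard, window[0])
        b = min(jumps[k + 1] - guard, window[1])
        if b <= a:
            continue
        i0, i1 = int(np.ceil(a * fs)), int(np.floor(b * fs))
        if i1 <= i0:
            continue
        sums[states[k]] += x[i0:i1].sum()
        counts[states[k]] += i1 - i0
    if counts[counts > 0].size < 2:
        return None
    level_current = np.full(counts.size, np.nan)
    np.divide(sums, counts, out=level_current, where=counts > 0)

    min_dwell = config.min_stable_dwell_ms / 1000.0
    best = None
    prev = None
    for a, b, s in dwell_list:
        if b - a < min_dwell or np.isnan(level_current[s]):
            prev = None
            continue
        if prev is not None and window[0] <= a < window[1]:
            dg = abs(level_current[s] - level_current[prev]) / vh * 1000.0
            best = dg if best is None or dg > best else best
        prev = s
    return best
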