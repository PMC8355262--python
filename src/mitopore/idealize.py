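"""Trace idealization: amplitude histogram, Gaussian-mixture level fitting,
piecewise-constant level assignment and transition-event detection.

The chain mirrors the study's current-analysis procedure: conductance
levels are identified by multi-Gaussian fitting of the current amplitude
histogram (weighted EM over bins with BIC model selection; a raw-sample EM
is exposed as a cross-check), the trace is assigned
to the nearest level with hysteresis, dwells shorter than a stability
threshold are merged away, and each surviving boundary becomes a transition
event whose duration is the 10-90% crossing time on the filtered current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from sklearn.mixture import GaussianMixture

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import FittingError, ValidationError
from .simulate import RecordingProtocol, Trace

__all__ = [
    "AmplitudeHistogram",
    "MixtureFit",
    "ConductanceLevels",
    "Idealization",
    "TransitionEvent",
    "build_histogram",
    "fit_mixture",
    "extract_levels",
    "idealize",
    "detect_transitions",
    "piecewise_linear_baseline",
]


@dataclass(frozen=True, eq=False)
class AmplitudeHistogram:
    """Binned current amplitudes; counts conserve the window sample count."""

    bin_edges: np.ndarray  # pA, strictly increasing, len = len(counts)+1
    counts: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_samples:
            raise ValidationError("histogram counts must sum to the sample count")


@dataclass(frozen=True)
class MixtureFit:
    """Gaussian mixture fitted to current amplitudes.

    components are (weight, mean_pA, sd_pA), sorted by mean ascending.
    score is the model-selection criterion (BIC; lower is better).
    """

    components: tuple[tuple[float, float, float], ...]
    k: int
    log_likelihood: float
    score: float
    n_fit_samples: int

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        means = [c[1] for c in self.components]
        if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValidationError("weights must be positive and sum to 1")
        if any(c[2] <= 0 for c in self.components):
            raise ValidationError("component sds must be > 0")
        if sorted(means) != means:
            raise ValidationError("components must be sorted by mean")


@dataclass(frozen=True, eq=False)
class ConductanceLevels:
    """Discrete conductance levels extracted from a mixture fit.

    Level 0 is the baseline (closed peak); conductances are strictly
    increasing, in pS: g_i = (mu_i - mu_baseline) / V_h * 1000.
    """

    baseline_current: float       # pA
    baseline_sd: float            # pA
    level_currents: np.ndarray    # pA, ascending, level 0 = baseline
    conductances: np.ndarray      # pS, conductances[0] == 0

    def __post_init__(self) -> None:
        if self.conductances[0] != 0:
            raise ValidationError("level 0 must be the zero-conductance baseline")
        if np.any(np.diff(self.conductances) <= 0):
            raise ValidationError("conductances must be strictly increasing")
        if (self.conductances < 0).any():
            raise ValidationError("conductances must be non-negative")

    @property
    def n_levels(self) -> int:
        return self.level_currents.size


@dataclass(frozen=True, eq=False)
class Idealization:
    """Piecewise-constant level assignment.

    segments is an (n, 3) int array of (start, end, level_id) with half-open
    sample ranges that tile the analyzed span; consecutive segments carry
    different levels.
    """

    segments: np.ndarray
    sampling_rate: float
    levels: ConductanceLevels

    def __post_init__(self) -> None:
        seg = self.segments
        if seg.ndim != 2 or seg.shape[1] != 3:
            raise ValidationError("segments must be (n, 3)")
        if np.any(seg[1:, 0] != seg[:-1, 1]):
            raise ValidationError("segments must be contiguous")
        if np.any(seg[1:, 2] == seg[:-1, 2]):
            raise ValidationError("consecutive segments must change level")

    @property
    def dwell_times(self) -> np.ndarray:
        """Per-segment dwell durations in seconds."""
        return (self.segments[:, 1] - self.segments[:, 0]) / self.sampling_rate

    def labels(self) -> np.ndarray:
        """Per-sample level ids over the analyzed span."""
        n = int(self.segments[-1, 1] - self.segments[0, 0])
        out = np.empty(n, dtype=int)
        off = self.segments[0, 0]
        for s, e, lvl in self.segments:
            out[s - off:e - off] = lvl
        return out


@dataclass(frozen=True)
class TransitionEvent:
    """One level change: signed conductance jump and 10-90% duration."""

    time: float          # s, at the segment boundary
    duration_ms: float
    from_level: int
    to_level: int
    delta_g: float       # pS, conductance(to) - conductance(from)

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValidationError("duration must be >= 0")


def build_histogram(trace: Trace, window: tuple[float, float] | None = None,
                    bin_width: float | None = None) -> AmplitudeHistogram:
    """Amplitude histogram of the (windowed) trace, default 0.2 pA bins."""
    bw = bin_width if bin_width is not None else DEFAULT_CONFIG.bin_width_pA
    if bw <= 0:
        raise ValidationError("bin width must be > 0")
    x = trace.current
    if window is not None:
        t0, t1 = window
        fs = trace.protocol.sampling_rate
        i0, i1 = max(0, int(round(t0 * fs))), min(x.size, int(round(t1 * fs)))
        x = x[i0:i1]
    if x.size == 0:
        raise ValidationError("empty analysis window")
    lo = math.floor(x.min() / bw) * bw
    hi = math.ceil(x.max() / bw) * bw
    if hi <= lo:
        hi = lo + bw
    edges = np.arange(lo, hi + bw / 2, bw)
    if edges[-1] < x.max():
        edges = np.append(edges, edges[-1] + bw)
    counts, edges = np.histogram(x, bins=edges)
    return AmplitudeHistogram(bin_edges=edges, counts=counts, n_samples=x.size)


_SD_FLOOR = 1e-3  # pA; keeps noise-free peaks finite


def _weighted_em(centers: np.ndarray, counts: np.ndarray, k: int,
                 rng: np.random.Generator, bin_width: float,
                 sd_floor: float = _SD_FLOOR,
                 max_iter: int = 300, tol: float = 1e-8):
    """EM for a k-Gaussian mixture on binned (weighted) observations.

    The likelihood of a bin is the component CDF mass over the bin, so the
    criterion is a proper multinomial likelihood and narrow components gain
    nothing beyond the empirical bin mass.  Returns (weights, means, sds,
    log_likelihood) or None on failure.
    """
    n_total = counts.sum()
    half = bin_width / 2.0
    # init: draw k distinct centers weighted by counts, sd from global spread
    probs = counts / n_total
    mu = rng.choice(centers, size=k, replace=False, p=probs)
    mu = np.sort(mu)
    global_sd = math.sqrt(max(np.average((centers - np.average(centers, weights=counts)) ** 2,
                                         weights=counts), sd_floor**2))
    sd = np.full(k, max(global_sd / k, sd_floor))
    w = np.full(k, 1.0 / k)
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: bin probabilities as CDF differences (density at the bin
        # center would let a component collapse onto a single bin's mass)
        lo = (centers[None, :] - half - mu[:, None]) / sd[:, None]
        hi = (centers[None, :] + half - mu[:, None]) / sd[:, None]
        p_bin = np.maximum(ndtr(hi) - ndtr(lo), 1e-300)
        log_w = np.log(w)[:, None] + np.log(p_bin)
        m = log_w.max(axis=0)
        lse = m + np.log(np.exp(log_w - m).sum(axis=0))
        ll = float((counts * lse).sum())
        resp = np.exp(log_w - lse)          # (k, bins)
        # M-step (bin-center moment approximation)
        nk = resp @ counts
        if np.any(nk < 1e-12):
            return None
        w = nk / n_total
        mu = (resp * centers) @ counts / nk
        var = (resp * (centers[None, :] - mu[:, None]) ** 2) @ counts / nk
        sd = np.sqrt(np.maximum(var, sd_floor**2))
        if abs(ll - ll_old) < tol * n_total:
            order = np.argsort(mu)
            return w[order], mu[order], sd[order], ll
        ll_old = ll
    return None


def fit_mixture(samples: np.ndarray, k_max: int | None = None,
                config: AnalysisConfig = DEFAULT_CONFIG,
                seed: int = 12345, method: str = "binned") -> MixtureFit:
    """Fit 1..k_max Gaussians by EM and keep the BIC-optimal order.

    method="binned" (default) runs a weighted EM on the amplitude
    histogram (bin width config.bin_width_pA, far below the noise sd), so
    every sample informs the fit at negligible cost; multiple restarts with
    count-weighted random initialization, deterministic under the fixed
    internal seed.  method="raw" delegates to scikit-learn's
    GaussianMixture on (decimated) raw samples and serves as an
    independent cross-check of the binned fit.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 200:
        raise ValidationError("need at least 200 samples to fit a mixture")
    if k_max is None:
        k_max = config.k_max
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if method == "raw":
        return _fit_mixture_sklearn(x, k_max, config, seed)
    if method != "binned":
        raise ValidationError(f"unknown fit method {method!r}")

    bw = config.bin_width_pA
    lo = math.floor(x.min() / bw) * bw - bw / 2
    nbins = int(math.ceil((x.max() - lo) / bw)) + 1
    counts, edges = np.histogram(x, bins=nbins, range=(lo, lo + nbins * bw))
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    # keep zero bins out of the likelihood; weighting handles the rest
    centers_nz, counts_nz = centers[keep], counts[keep].astype(float)
    n = x.size

    best = None
    failures = []
    rng = np.random.default_rng(seed)
    sd_floor = max(_SD_FLOOR, bw / math.sqrt(12.0))  # within-bin spread
    for k in range(1, min(k_max, centers_nz.size) + 1):
        k_best = None
        n_tries = 1 if k == 1 else config.n_restarts
        for _ in range(n_tries):
            res = _weighted_em(centers_nz, counts_nz, k, rng, bin_width=bw,
                               sd_floor=sd_floor)
            if res is None:
                continue
            if k_best is None or res[3] > k_best[3]:
                k_best = res
        if k_best is None:
            failures.append(k)
            continue
        w, mu, sd, ll = k_best
        bic = -2.0 * ll + (3 * k - 1) * math.log(n)
        if best is None or bic < best[0]:
            best = (bic, k, w, mu, sd, ll)
    if best is None:
        raise FittingError(
            f"EM failed to converge for every k in 1..{k_max} "
            f"(failed orders: {failures})"
        )
    bic, k, w, mu, sd, ll = best
    comps = tuple((float(wi), float(mi), float(si))
                  for wi, mi, si in zip(w / w.sum(), mu, sd))
    return MixtureFit(components=comps, k=k, log_likelihood=float(ll),
                      score=float(bic), n_fit_samples=n)


def _fit_mixture_sklearn(x: np.ndarray, k_max: int,
                         config: AnalysisConfig, seed: int) -> MixtureFit:
    """Raw-sample EM via scikit-learn (comparison mode)."""
    if x.size > config.max_fit_samples:
        stride = int(math.ceil(x.size / config.max_fit_samples))
        x = x[::stride]
    X = x[:, None]
    best = None
    failures = []
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=config.n_restarts if k > 1 else 1,
            init_params="kmeans",
            reg_covar=_SD_FLOOR**2,
            max_iter=200,
            random_state=seed,
        )
        gm.fit(X)
        if not gm.converged_:
            failures.append(k)
            continue
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    if best is None:
        raise FittingError(
            f"EM failed to converge for every k in 1..{k_max} "
            f"(failed orders: {failures})"
        )
    bic, k, gm = best
    order = np.argsort(gm.means_[:, 0])
    comps = tuple(
        (float(gm.weights_[i]), float(gm.means_[i, 0]),
         float(math.sqrt(gm.covariances_[i, 0])))
        for i in order
    )
    return MixtureFit(
        components=comps, k=k,
        log_likelihood=float(gm.score(X) * X.shape[0]),
        score=float(bic), n_fit_samples=X.shape[0],
    )


def extract_levels(fit: MixtureFit, protocol: RecordingProtocol,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> ConductanceLevels:
    """Turn mixture components into a ladder of conductance levels.

    The lowest-mean component is the baseline.  Components are dropped if
    their weight is below config.min_component_weight (filter-ramp smear),
    merged into baseline if within event_threshold_sigmas baseline sds of
    it, and adjacent components closer than the same threshold are merged
    together (a split peak is one physical level).
    """
    vh = protocol.holding_potential
    if vh <= 0:
        raise ValidationError(
            "level extraction assumes openings as positive deflections "
            "(holding potential > 0)"
        )
    comps = [c for c in fit.components if c[0] >= config.min_component_weight]
    if not comps:
        comps = [max(fit.components, key=lambda c: c[0])]
    comps.sort(key=lambda c: c[1])

    thr = config.event_threshold_sigmas
    base_w, base_mu, base_sd = comps[0]
    rest = comps[1:]
    # merge near-baseline components into baseline (weighted)
    merged_rest = []
    for w, mu, sd in rest:
        if abs(mu - base_mu) < thr * base_sd:
            tot = base_w + w
            base_mu = (base_w * base_mu + w * mu) / tot
            base_sd = math.sqrt((base_w * base_sd**2 + w * sd**2) / tot)
            base_w = tot
        else:
            merged_rest.append([w, mu, sd])
    # merge adjacent non-baseline components closer than the threshold
    out = []
    for w, mu, sd in merged_rest:
        if out and (mu - out[-1][1]) < thr * base_sd:
            pw, pmu, psd = out[-1]
            tot = pw + w
            out[-1] = [tot, (pw * pmu + w * mu) / tot,
                       math.sqrt((pw * psd**2 + w * sd**2) / tot)]
        else:
            out.append([w, mu, sd])

    currents = np.array([base_mu] + [mu for _, mu, _ in out])
    conds = (currents - base_mu) / vh * 1000.0  # pA/mV -> pS
    return ConductanceLevels(
        baseline_current=float(base_mu),
        baseline_sd=float(base_sd),
        level_currents=currents,
        conductances=conds,
    )


def _segments_from_states(state: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [state.size]))
    return np.column_stack((starts, ends, state[starts])).astype(np.int64)


def _merge_short_runs(seg: np.ndarray, x: np.ndarray,
                      level_currents: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge dwells shorter than min_samples into the flanking level whose
    current is nearer the run's own mean, then coalesce."""
    seg = [list(row) for row in seg]

    def coalesce(rows):
        out = [rows[0]]
        for r in rows[1:]:
            if r[2] == out[-1][2]:
                out[-1][1] = r[1]
            else:
                out.append(r)
        return out

    while len(seg) > 1:
        durations = [e - s for s, e, _ in seg]
        short = [i for i, d in enumerate(durations) if d < min_samples]
        if not short:
            break
        i = min(short, key=lambda j: durations[j])
        s, e, _ = seg[i]
        mean = float(x[s:e].mean())
        left = seg[i - 1][2] if i > 0 else None
        right = seg[i + 1][2] if i + 1 < len(seg) else None
        if left is None:
            tgt = right
        elif right is None:
            tgt = left
        else:
            tgt = left if abs(level_currents[left] - mean) <= abs(
                level_currents[right] - mean) else right
        seg[i][2] = tgt
        seg = coalesce(seg)
    return np.asarray(seg, dtype=np.int64)


def idealize(trace: Trace, levels: ConductanceLevels,
             config: AnalysisConfig = DEFAULT_CONFIG,
             current: np.ndarray | None = None) -> Idealization:
    """Assign every sample to a conductance level.

    Nearest-level assignment with hysteresis: a switch between adjacent
    levels requires the signal to pass the midpoint by hysteresis_fraction
    of the gap.  Runs shorter than min_stable_dwell_ms are merged into the
    flanking level with nearer current, so the surviving dwells are the
    "stable states" between which transitions are scored.

    `current` overrides the trace signal (e.g. baseline-corrected).
    """
    x = np.asarray(current if current is not None else trace.current, float)
    fs = trace.protocol.sampling_rate
    L = levels.level_currents
    if L.size == 1:
        seg = np.array([[0, x.size, 0]], dtype=np.int64)
        return Idealization(seg, fs, levels)

    mid = (L[:-1] + L[1:]) / 2.0
    gap = np.diff(L)
    h = config.hysteresis_fraction
    up_thr = mid + h * gap     # must exceed to move up past level i
    dn_thr = mid - h * gap     # must drop below to move down past level i+1

    lo_bound = np.searchsorted(up_thr, x, side="left")    # count(up_thr < x)
    hi_bound = np.searchsorted(dn_thr, x, side="right")   # count(dn_thr <= x)

    # run-length encode the (lo, hi) constraint and evolve the clipped state
    key = lo_bound * (L.size + 1) + hi_bound
    change = np.flatnonzero(np.diff(key)) + 1
    starts = np.concatenate(([0], change))
    state = np.empty(x.size, dtype=np.int64)
    s = int(np.argmin(np.abs(L - x[0])))
    ends = np.concatenate((change, [x.size]))
    for a, b in zip(starts, ends):
        s = min(max(s, int(lo_bound[a])), int(hi_bound[a]))
        state[a:b] = s

    seg = _segments_from_states(state)
    min_samples = max(1, int(round(config.min_stable_dwell_ms / 1000.0 * fs)))
    seg = _merge_short_runs(seg, x, L, min_samples)
    return Idealization(seg, fs, levels)


def detect_transitions(ideal: Idealization, trace: Trace,
                       current: np.ndarray | None = None) -> list[TransitionEvent]:
    """One event per segment boundary with a 10-90% crossing duration.

    The duration is measured on the filtered current: the last time before
    the boundary at which the signal was still within 10% of the departing
    level, to the first time after at which it is within 10% of the arriving
    level.  No duration filtering happens here (the <10 ms rule is applied
    when computing G_max).
    """
    x = np.asarray(current if current is not None else trace.current, float)
    fs = ideal.sampling_rate
    L = ideal.levels.level_currents
    g = ideal.levels.conductances
    seg = ideal.segments
    events: list[TransitionEvent] = []
    win = int(round(0.06 * fs))  # 60 ms search cap per side
    for j in range(len(seg) - 1):
        p, q = int(seg[j, 2]), int(seg[j + 1, 2])
        m = int(seg[j, 1])
        ip, iq = L[p], L[q]
        x10 = ip + 0.1 * (iq - ip)
        x90 = ip + 0.9 * (iq - ip)
        rising = iq > ip
        a = max(int(seg[j, 0]), m - win)
        b = min(int(seg[j + 1, 1]), m + win)
        back = x[a:m]
        fwd = x[m:b]
        if rising:
            cand = np.flatnonzero(back <= x10)
            i10 = a + cand[-1] if cand.size else a
            cand = np.flatnonzero(fwd >= x90)
            i90 = m + cand[0] if cand.size else b - 1
        else:
            cand = np.flatnonzero(back >= x10)
            i10 = a + cand[-1] if cand.size else a
            cand = np.flatnonzero(fwd <= x90)
            i90 = m + cand[0] if cand.size else b - 1
        duration_ms = max(i90 - i10, 1) / fs * 1000.0
        events.append(TransitionEvent(
            time=m / fs, duration_ms=duration_ms,
            from_level=p, to_level=q, delta_g=float(g[q] - g[p]),
        ))
    return events


def piecewise_linear_baseline(trace: Trace, ideal: Idealization,
                              current: np.ndarray | None = None) -> np.ndarray:
    """Baseline estimate interpolated through closed-dwell means.

    Closed (level 0) segment means anchor a piecewise-linear baseline over
    time (flat extrapolation at the ends); this is the offset correction
    applied before every conductance statistic.  If no closed dwell exists
    the fitted baseline-peak current is used as a constant.
    """
    x = np.asarray(current if current is not None else trace.current, float)
    fs = ideal.sampling_rate
    closed = ideal.segments[ideal.segments[:, 2] == 0]
    if closed.shape[0] == 0:
        return np.full(x.size, ideal.levels.baseline_current)
    mids = (closed[:, 0] + closed[:, 1]) / 2.0 / fs
    means = np.array([x[s:e].mean() for s, e, _ in closed])
    if closed.shape[0] == 1:
        return np.full(x.size, means[0])
    t = np.arange(x.size) / fs
    return np.interp(t, mids, means)
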