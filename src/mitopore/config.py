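"""Analysis configuration shared by the idealization and statistics layers.

All tunables that the current-analysis procedure leaves open are collected
here so a run can be reproduced from a single serialized object.  Units are
the reporting units used throughout the package: seconds, milliseconds where
named, pA, pS, pC.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the single-channel analysis.

    Attributes
    ----------
    max_transition_duration_ms:
        Events slower than this are excluded from G_max (the <10 ms rule).
    gmean_window_s:
        Length of the pre-blocker window over which G_mean is averaged.
    q_interval_s:
        Length of the charge-integration window for Q_4s.
    min_stable_dwell_ms:
        Idealized dwells shorter than this are merged into a flanking level;
        what remains counts as a "stable state".  Default 20 ms, ~30x the
        10-90% rise time of the 500 Hz low-pass filter.
    event_threshold_sigmas:
        Mixture components closer to the baseline peak than this many
        baseline standard deviations are merged into baseline ("events out
        of the noise range" rule).
    hysteresis_fraction:
        Fraction of the inter-level gap that the signal must cross beyond
        the midpoint before the idealizer switches level.
    bin_width_pA:
        Amplitude-histogram bin width (reporting only; fitting uses raw
        samples).
    k_max, n_restarts, max_fit_samples:
        Gaussian-mixture model-selection range, EM restarts per order, and
        the decimation cap applied to the sample vector before fitting.
    min_component_weight:
        Mixture components below this weight are dropped before level
        extraction (filter-ramp samples produce low-weight smear components).
    post_blocker_settle_s:
        Dead time after a blocker addition before post-blocker statistics
        start, so the closing transient of the block itself is not scored
        as channel activity.
    include_closed_in_gmean:
        If True, G_mean averages over all window samples instead of
        activity (non-baseline) samples only.
    """

    max_transition_duration_ms: float = 10.0
    gmean_window_s: float = 30.0
    q_interval_s: float = 4.0
    min_stable_dwell_ms: float = 20.0
    event_threshold_sigmas: float = 3.0
    hysteresis_fraction: float = 0.25
    bin_width_pA: float = 0.2
    k_max: int = 6
    n_restarts: int = 10
    max_fit_samples: int = 20000
    min_component_weight: float = 0.02
    include_closed_in_gmean: bool = False
    post_blocker_settle_s: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "max_transition_duration_ms",
            "gmean_window_s",
            "q_interval_s",
            "min_stable_dwell_ms",
            "event_threshold_sigmas",
            "hysteresis_fraction",
            "bin_width_pA",
            "k_max",
            "n_restarts",
            "max_fit_samples",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"AnalysisConfig.{name} must be > 0")
        if not 0 <= self.min_component_weight < 0.5:
            raise ValidationError("min_component_weight must be in [0, 0.5)")
        if self.post_blocker_settle_s < 0:
            raise ValidationError("post_blocker_settle_s must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


DEFAULT_CONFIG = AnalysisConfig()
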