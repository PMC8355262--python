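"""Packaged channel models emulating the recorded genotypes.

Each preset is a small continuous-time Markov gating model whose analyzed
round-trip statistics (G_max, G_mean, Q_4s through the full idealization
pipeline) land on the per-genotype target values, with a default blocker
addition at 60 s into a 90 s recording at V_h = +20 mV.

Conductance levels are anchored to reported values (full PTP level 827 pS
for wild-type HeLa, 620 pS for the atractylate-induced ANT-type channel in
subunit-g-deleted cells, 1.3-1.5 nS for the historical full megachannel);
kinetics are free parameters chosen for realism, since dwell-time statistics
and open probability are not reported for any genotype.  Batch generation
jitters all conductances per trace with CV ~0.1 to emulate experiment-to-
experiment dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PresetError
from .simulate import (
    ChannelModel,
    RecordingProtocol,
    Trace,
    blocking_intervention,
    make_rate_matrix,
    simulate_channel_trace,
)

__all__ = [
    "PRESET_NAMES",
    "PRESET_TARGETS",
    "make_preset",
    "default_protocol",
    "simulate_preset",
    "DEFAULT_BLOCKER_TIME",
    "DEFAULT_DURATION",
    "JITTER_CV",
]

DEFAULT_BLOCKER_TIME = 60.0  # s; G_mean window is the preceding 30 s
DEFAULT_DURATION = 90.0      # s
JITTER_CV = 0.1              # per-trace conductance jitter


@dataclass(frozen=True)
class PresetTargets:
    """Nominal round-trip statistics a preset was calibrated to."""

    gmax_pS: float | None
    gmean_pS: float | None
    q4s_pC: float | None


#: Round-trip targets (means across traces) for the calibrated presets.
PRESET_TARGETS: dict[str, PresetTargets] = {
    "wt_hela_ptp": PresetTargets(827.0, 703.0, 48.0),
    "dg_atr_ant": PresetTargets(620.0, 434.0, 47.0),
    "wt_hap1_ptp": PresetTargets(827.0, 703.0, 48.0),
    "ant_channel": PresetTargets(600.0, None, None),
    "full_mmc": PresetTargets(1400.0, None, None),
    "null_closed": PresetTargets(None, None, None),
}


def _wt_like(full_pS: float, sub_pS: float, blocker: str,
             noise_sd: float = 1.2) -> tuple[ChannelModel, str]:
    # Busy gating: dwells ~0.1-0.2 s, direct closed<->open transitions so
    # the full-level jump appears as a fast event in every trace.
    rates = make_rate_matrix([
        # closed   sub     open
        [0.0,      2.87,   5.30],  # from closed
        [6.0,      0.0,    3.33],  # from sub
        [5.0,      1.5,    0.0],   # from open
    ])
    model = ChannelModel(
        states=(("closed", 0.0), ("sub", sub_pS), ("open", full_pS)),
        rates=rates,
        baseline_current=0.5,
        noise_sd=noise_sd,
        drift_slope=0.01,
        initial_state=0,
    )
    return model, blocker


def _ant_like(full_pS: float, sub_pS: float, blocker: str) -> tuple[ChannelModel, str]:
    # Sparse long openings: full-level episodes of a few seconds entered
    # directly from closed, against a background of brief substate sojourns.
    rates = make_rate_matrix([
        # closed   sub     open
        [0.0,      2.33,   0.146],
        [2.8,      0.0,    0.0345],
        [0.22,     0.0432, 0.0],
    ])
    model = ChannelModel(
        states=(("closed", 0.0), ("sub", sub_pS), ("open", full_pS)),
        rates=rates,
        baseline_current=0.5,
        noise_sd=1.2,
        drift_slope=0.01,
        initial_state=0,
    )
    return model, blocker


def _build(name: str):
    if name == "wt_hela_ptp":
        return _wt_like(827.0, 460.0, "Ba2+")
    if name == "wt_hap1_ptp":
        return _wt_like(827.0, 460.0, "CsA")
    if name == "dg_atr_ant":
        return _ant_like(620.0, 300.0, "BKA")
    if name == "ant_channel":
        return _ant_like(600.0, 300.0, "MgADP")
    if name == "full_mmc":
        return _wt_like(1400.0, 650.0, "CsA")
    if name == "null_closed":
        model = ChannelModel(
            states=(("closed", 0.0), ("open", 827.0)),
            rates=np.zeros((2, 2)),
            baseline_current=0.5,
            noise_sd=1.2,
            initial_state=0,
        )
        return model, None
    raise PresetError(
        f"unknown preset {name!r}; available: {sorted(PRESET_TARGETS)}"
    )


PRESET_NAMES = tuple(sorted(PRESET_TARGETS))


def make_preset(name: str, blocker_time: float = DEFAULT_BLOCKER_TIME):
    """Return (ChannelModel, default interventions) for a named preset.

    The default intervention is a full block (all conductance-increasing
    transitions abolished) by the genotype's characteristic blocker at
    `blocker_time`; `null_closed` has none.
    """
    model, blocker = _build(name)
    if blocker is None:
        return model, ()
    return model, (blocking_intervention(model, blocker_time, blocker),)


def default_protocol(duration: float = DEFAULT_DURATION) -> RecordingProtocol:
    """The study's recording protocol: +20 mV, 10 kHz sampling, 500 Hz filter."""
    return RecordingProtocol(duration=duration)


def simulate_preset(name: str, seed=0, duration: float = DEFAULT_DURATION,
                    blocker_time: float = DEFAULT_BLOCKER_TIME,
                    jitter_cv: float = JITTER_CV) -> Trace:
    """Simulate one trace from a preset with per-trace conductance jitter.

    The jitter factor (normal, CV `jitter_cv`, truncated at 0.5) scales all
    state conductances together, emulating experiment-to-experiment spread
    while preserving sub-state ratios.  Pass jitter_cv=0 for the nominal
    model.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    model, interventions = make_preset(name, blocker_time=blocker_time)
    interventions = tuple(iv for iv in interventions if iv.time <= duration)
    if jitter_cv > 0:
        factor = max(0.5, 1.0 + jitter_cv * rng.standard_normal())
        model = model.scaled(factor)
    return simulate_channel_trace(model, default_protocol(duration),
                                  interventions, seed=rng)
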