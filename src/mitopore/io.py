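"""File dialects: plain-text trace files, assay tables, run configuration.

The native trace format is columnar text with a ``# key: value`` header
block (holding potential, sampling rate, filter cutoff, interventions as
``label@time_s`` tokens) followed by ``time_s,current_pA`` rows.  Assay
series use the same header-plus-CSV shape.  Every simulation can write a
ground-truth JSON sidecar for test harnesses.  All formats round-trip
losslessly to well below 1e-9 pA.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import ParseError, ValidationError
from .simulate import (
    AbsorbanceSeries,
    FluorescenceSeries,
    Intervention,
    OcrSeries,
    RecordingProtocol,
    RoiTimecourseSet,
    Trace,
)

__all__ = [
    "read_trace",
    "write_trace",
    "write_truth",
    "read_absorbance",
    "write_absorbance",
    "read_fluorescence",
    "write_fluorescence",
    "read_ocr",
    "write_ocr",
    "read_timecourse",
    "write_timecourse",
    "RunConfig",
]

_MANDATORY_TRACE_KEYS = ("holding_potential_mV", "sampling_rate_hz", "filter_cutoff_hz")
_FLOAT_FMT = "%.12g"


def _parse_header(path: Path) -> tuple[dict[str, str], int]:
    """Read leading '# key: value' lines; returns (meta, n_header_lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if not body:
                continue
            if ":" not in body:
                raise ParseError(f"malformed header {body!r}", line=n)
            key, val = body.split(":", 1)
            meta[key.strip()] = val.strip()
    return meta, n


def _parse_interventions(token_string: str, header_line: int) -> tuple[Intervention, ...]:
    out = []
    for tok in filter(None, (t.strip() for t in token_string.split(","))):
        if "@" not in tok:
            raise ParseError(
                f"intervention token {tok!r} is not label@time_s", line=header_line
            )
        label, t = tok.rsplit("@", 1)
        try:
            out.append(Intervention(time=float(t), label=label))
        except ValueError as exc:
            raise ParseError(f"bad intervention time in {tok!r}", line=header_line) from exc
    return tuple(out)


def write_trace(trace: Trace, path) -> None:
    """Write a trace in the native dialect (header block + time/current CSV)."""
    path = Path(path)
    lines = [
        f"# holding_potential_mV: {trace.protocol.holding_potential:g}",
        f"# sampling_rate_hz: {trace.protocol.sampling_rate:g}",
        f"# filter_cutoff_hz: {trace.protocol.filter_cutoff:g}",
    ]
    if trace.interventions:
        toks = ",".join(f"{iv.label}@{iv.time:g}" for iv in trace.interventions)
        lines.append(f"# interventions: {toks}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        fh.write("time_s,current_pA\n")
        t = trace.times
        np.savetxt(fh, np.column_stack((t, trace.current)),
                   fmt=_FLOAT_FMT, delimiter=",")


def read_trace(path) -> Trace:
    """Read a native-dialect trace file; malformed input raises ParseError
    with the offending line number."""
    path = Path(path)
    meta, n_header = _parse_header(path)
    for key in _MANDATORY_TRACE_KEYS:
        if key not in meta:
            raise ParseError(f"missing mandatory header key {key!r}")
    try:
        df = pd.read_csv(path, skiprows=n_header)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not parse data table: {exc}") from exc
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}", line=n_header + 1)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size == 0:
        raise ParseError("trace has no samples", line=n_header + 2)
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ParseError("non-monotone time column", line=n_header + 3 + bad)
    fs = float(meta["sampling_rate_hz"])
    protocol = RecordingProtocol(
        duration=t.size / fs,
        holding_potential=float(meta["holding_potential_mV"]),
        sampling_rate=fs,
        filter_cutoff=float(meta["filter_cutoff_hz"]),
    )
    interventions = ()
    if "interventions" in meta:
        # header line number is approximate: the key's position in the block
        interventions = _parse_interventions(meta["interventions"], n_header)
    return Trace(protocol=protocol, current=df["current_pA"].to_numpy(dtype=float),
                 interventions=interventions)


def write_truth(trace: Trace, path) -> None:
    """Ground-truth sidecar: true dwell path and level conductances."""
    if trace.truth is None:
        raise ValidationError("trace carries no ground truth")
    tr = trace.truth
    payload = {
        "jump_times_s": tr.jump_times.tolist(),
        "states": tr.states.tolist(),
        "state_labels": list(tr.state_labels),
        "conductances_pS": tr.conductances_pS.tolist(),
        "duration_s": trace.protocol.duration,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _write_table(path, meta: dict, df: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_table(path, required_cols) -> tuple[dict[str, str], pd.DataFrame]:
    meta, n_header = _parse_header(Path(path))
    df = pd.read_csv(path, skiprows=n_header)
    for col in required_cols:
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}", line=n_header + 1)
    return meta, df


def write_absorbance(series: AbsorbanceSeries, path) -> None:
    meta = {"ala_time_s": f"{series.ala_time:g}"}
    if series.ca_time is not None:
        meta["ca_time_s"] = f"{series.ca_time:g}"
    _write_table(path, meta, pd.DataFrame({"time_s": series.times,
                                           "a540": series.a540}))


def read_absorbance(path) -> AbsorbanceSeries:
    meta, df = _read_table(path, ("time_s", "a540"))
    if "ala_time_s" not in meta:
        raise ParseError("missing mandatory header key 'ala_time_s'")
    return AbsorbanceSeries(
        times=df["time_s"].to_numpy(float), a540=df["a540"].to_numpy(float),
        ala_time=float(meta["ala_time_s"]),
        ca_time=float(meta["ca_time_s"]) if "ca_time_s" in meta else None,
    )


def write_fluorescence(series: FluorescenceSeries, path) -> None:
    meta = {
        "pulse_times_s": ",".join(f"{p:g}" for p in series.pulse_times),
        "pulse_size_uM": f"{series.pulse_size:g}",
        "protein_mg_ml": f"{series.protein:g}",
    }
    _write_table(path, meta, pd.DataFrame({"time_s": series.times,
                                           "fluorescence": series.fluorescence}))


def read_fluorescence(path) -> FluorescenceSeries:
    meta, df = _read_table(path, ("time_s", "fluorescence"))
    for key in ("pulse_times_s", "pulse_size_uM", "protein_mg_ml"):
        if key not in meta:
            raise ParseError(f"missing mandatory header key {key!r}")
    pulses = np.array([float(p) for p in meta["pulse_times_s"].split(",") if p])
    return FluorescenceSeries(
        times=df["time_s"].to_numpy(float),
        fluorescence=df["fluorescence"].to_numpy(float),
        pulse_times=pulses,
        pulse_size=float(meta["pulse_size_uM"]),
        protein=float(meta["protein_mg_ml"]),
    )


def write_ocr(series: OcrSeries, path) -> None:
    meta = {
        "injections": ",".join(f"{lab}@{t:g}" for lab, t in series.injections),
        "protein_ug": f"{series.protein:g}",
    }
    _write_table(path, meta, pd.DataFrame({"time_s": series.times,
                                           "ocr": series.ocr}))


def read_ocr(path) -> OcrSeries:
    meta, df = _read_table(path, ("time_s", "ocr"))
    for key in ("injections", "protein_ug"):
        if key not in meta:
            raise ParseError(f"missing mandatory header key {key!r}")
    inj = []
    for tok in meta["injections"].split(","):
        label, t = tok.rsplit("@", 1)
        inj.append((label.strip(), float(t)))
    return OcrSeries(times=df["time_s"].to_numpy(float),
                     ocr=df["ocr"].to_numpy(float),
                     injections=tuple(inj), protein=float(meta["protein_ug"]))


def write_timecourse(set_: RoiTimecourseSet, path) -> None:
    meta = {
        "addition_time_s": f"{set_.addition_time:g}",
        "background_calcein": f"{set_.background_calcein:g}",
        "background_tmrm": f"{set_.background_tmrm:g}",
        "condition": set_.condition,
    }
    n, m = set_.calcein.shape
    df = pd.DataFrame({
        "roi": np.repeat(np.arange(n), m),
        "time_s": np.tile(set_.times, n),
        "calcein": set_.calcein.ravel(),
        "tmrm": set_.tmrm.ravel(),
    })
    _write_table(path, meta, df)


def read_timecourse(path) -> RoiTimecourseSet:
    meta, df = _read_table(path, ("roi", "time_s", "calcein", "tmrm"))
    for key in ("addition_time_s", "background_calcein", "background_tmrm"):
        if key not in meta:
            raise ParseError(f"missing mandatory header key {key!r}")
    rois = np.sort(df["roi"].unique())
    times = np.sort(df[df["roi"] == rois[0]]["time_s"].to_numpy(float))
    cal = np.empty((rois.size, times.size))
    tm = np.empty((rois.size, times.size))
    for i, r in enumerate(rois):
        sub = df[df["roi"] == r].sort_values("time_s")
        cal[i] = sub["calcein"].to_numpy(float)
        tm[i] = sub["tmrm"].to_numpy(float)
    return RoiTimecourseSet(
        times=times, calcein=cal, tmrm=tm,
        background_calcein=float(meta["background_calcein"]),
        background_tmrm=float(meta["background_tmrm"]),
        addition_time=float(meta["addition_time_s"]),
        condition=meta.get("condition", "none"),
    )


@dataclasses.dataclass
class RunConfig:
    """Resolved settings of an analysis/simulation run, serializable to JSON.

    Every run writes its resolved configuration next to its outputs so a
    deterministic stage can be reproduced bit-identically.
    """

    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    preset: str | None = None
    seeds: tuple[int, ...] = ()
    output_dir: str = "."
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["analysis"] = self.analysis.to_dict()
        d["config_hash"] = self.analysis.hash()
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d.pop("config_hash", None)
        d["analysis"] = AnalysisConfig.from_dict(d["analysis"])
        d["seeds"] = tuple(d.get("seeds", ()))
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))
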