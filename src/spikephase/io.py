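"""Sweep containers and the sweep-archive file formats.

Canonical in-memory units are mV (voltage), pA (current) and ms (time);
both readers normalize on load whatever units the file declares.

Two on-disk dialects are supported behind one reader contract:

* an HDF5 container — one group per sweep (``sweep_000`` ...) holding
  ``voltage`` and ``current`` datasets, with units, sampling rate and the
  step table stored as attributes;
* a plain-CSV fallback — one ``sweep_NNN.csv`` per sweep with columns
  ``time_ms, voltage_mV, current_pA`` plus a ``manifest.json``.

Adapters for vendor acquisition formats (ABF, NWB) can be registered as
plugins implementing the same ``read_archive`` contract; none are bundled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Sweep",
    "CellRecording",
    "ProtocolDescriptor",
    "ArchiveError",
    "read_archive",
    "write_archive",
    "validate_protocol",
]

#: liquid junction potential (mV) recorded as metadata; traces are NOT corrected
JUNCTION_POTENTIAL_MV = 15.2

_VOLT_SCALE = {"mV": 1.0, "V": 1000.0, "uV": 1e-3}
_CURR_SCALE = {"pA": 1.0, "nA": 1000.0, "A": 1e12, "uA": 1e6}


class ArchiveError(ValueError):
    """A sweep archive failed validation; message names the offending field."""


@dataclass
class Sweep:
    """One current-clamp trial: voltage and command-current series.

    ``step_onset``/``step_offset`` delimit the command step as a
    half-open window [onset, offset) in ms, with sample 0 at t = 0 ms.
    """

    voltage: np.ndarray          # mV
    current: np.ndarray          # pA
    sampling_rate: float         # Hz
    step_amplitude: float        # pA
    step_onset: float            # ms
    step_offset: float           # ms

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape:
            raise ArchiveError(
                f"voltage ({self.voltage.size}) and current ({self.current.size}) "
                "series differ in length"
            )
        if self.sampling_rate <= 0:
            raise ArchiveError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not (0 <= self.step_onset <= self.step_offset <= self.duration + 1e-9):
            raise ArchiveError(
                f"step window [{self.step_onset}, {self.step_offset}) falls outside "
                f"the sweep (duration {self.duration:.3f} ms)"
            )

    @property
    def n_samples(self) -> int:
        return self.voltage.size

    @property
    def dt(self) -> float:
        """Sample interval, ms."""
        return 1000.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Time base in ms, sample 0 at t = 0."""
        return np.arange(self.n_samples) * self.dt

    def index_at(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_rate / 1000.0))


@dataclass
class CellRecording:
    """Ordered sweep set for one cell plus acquisition metadata."""

    cell_id: str
    sweeps: list[Sweep]
    group: str = ""
    junction_corrected: bool = False
    junction_potential: float = JUNCTION_POTENTIAL_MV
    temperature: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.sweeps:
            raise ArchiveError(f"cell {self.cell_id!r}: a recording needs >= 1 sweep")
        rates = {s.sampling_rate for s in self.sweeps}
        if len(rates) > 1:
            raise ArchiveError(
                f"cell {self.cell_id!r}: sweeps mix sampling rates {sorted(rates)}"
            )

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0].sampling_rate

    @property
    def step_amplitudes(self) -> np.ndarray:
        return np.array([s.step_amplitude for s in self.sweeps])

    def sweeps_by_amplitude(self, ascending: bool = True) -> list[Sweep]:
        return sorted(self.sweeps, key=lambda s: s.step_amplitude, reverse=not ascending)

    def hyperpolarizing_sweeps(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.step_amplitude < 0]

    def depolarizing_sweeps(self) -> list[Sweep]:
        return sorted(
            (s for s in self.sweeps if s.step_amplitude > 0),
            key=lambda s: s.step_amplitude,
        )


@dataclass
class ProtocolDescriptor:
    """Capability flags: which downstream analyses a recording supports."""

    step_amplitudes: np.ndarray
    has_hyperpolarizing: bool
    has_depolarizing_ladder: bool
    has_zero_current_epoch: bool
    sag_capable: bool
    rheobase_capable: bool
    rmp_capable: bool


def validate_protocol(recording: CellRecording) -> ProtocolDescriptor:
    """Inspect the step table and flag which analyses are computable.

    Sag needs a hyperpolarizing step; rheobase needs a monotone
    depolarizing ladder (>= 2 distinct positive amplitudes, or a single
    spiking-range step); RMP needs a zero-current epoch (any pre-step
    baseline or a zero-amplitude sweep).
    """
    amps = recording.step_amplitudes
    has_hyper = bool(np.any(amps < 0))
    pos = np.unique(amps[amps > 0])
    has_ladder = pos.size >= 1
    has_zero = bool(
        np.any(amps == 0) or any(s.step_onset > 0 for s in recording.sweeps)
    )
    return ProtocolDescriptor(
        step_amplitudes=np.sort(amps),
        has_hyperpolarizing=has_hyper,
        has_depolarizing_ladder=has_ladder,
        has_zero_current_epoch=has_zero,
        sag_capable=has_hyper,
        rheobase_capable=has_ladder,
        rmp_capable=has_zero,
    )


# ---------------------------------------------------------------------------
# HDF5 dialect
# ---------------------------------------------------------------------------

def write_archive(recording: CellRecording, path: str | Path) -> Path:
    """Write a recording as a single-file HDF5 sweep archive.

    Bytes are deterministic for identical input (dataset timestamps are
    disabled), so re-writing the same recording is byte-identical.
    """
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format"] = "spikephase-archive"
        f.attrs["format_version"] = 1
        f.attrs["cell_id"] = recording.cell_id
        f.attrs["group"] = recording.group
        f.attrs["sampling_rate_hz"] = float(recording.sampling_rate)
        f.attrs["voltage_units"] = "mV"
        f.attrs["current_units"] = "pA"
        f.attrs["junction_corrected"] = bool(recording.junction_corrected)
        f.attrs["junction_potential_mV"] = float(recording.junction_potential)
        if recording.temperature is not None:
            f.attrs["temperature_C"] = float(recording.temperature)
        if recording.metadata:
            f.attrs["metadata_json"] = json.dumps(recording.metadata, sort_keys=True)
        for i, s in enumerate(recording.sweeps):
            g = f.create_group(f"sweep_{i:03d}")
            g.attrs["step_amplitude_pA"] = float(s.step_amplitude)
            g.attrs["step_onset_ms"] = float(s.step_onset)
            g.attrs["step_offset_ms"] = float(s.step_offset)
            for name, data in (("voltage", s.voltage), ("current", s.current)):
                g.create_dataset(name, data=data, track_times=False)
    return path


def _require_attr(obj, name: str, context: str):
    if name not in obj.attrs:
        raise ArchiveError(f"{context}: missing required attribute {name!r}")
    return obj.attrs[name]


def _unit_scale(unit: str, table: dict, context: str) -> float:
    if unit not in table:
        raise ArchiveError(
            f"{context}: unknown unit {unit!r} (accepted: {sorted(table)})"
        )
    return table[unit]


def read_archive(path: str | Path) -> CellRecording:
    """Load a sweep archive (HDF5 file or CSV directory), normalizing units."""
    path = Path(path)
    if not path.exists():
        raise ArchiveError(f"no such archive: {path}")
    if path.is_dir():
        return _read_csv_archive(path)
    if not h5py.is_hdf5(path):
        raise ArchiveError(
            f"{path}: not an HDF5 archive (signature check failed at byte offset 0)"
        )
    with h5py.File(path, "r") as f:
        rate = float(_require_attr(f, "sampling_rate_hz", str(path)))
        if rate <= 0:
            raise ArchiveError(f"{path}: sampling_rate_hz must be > 0, got {rate}")
        vscale = _unit_scale(str(_require_attr(f, "voltage_units", str(path))),
                             _VOLT_SCALE, str(path))
        cscale = _unit_scale(str(_require_attr(f, "current_units", str(path))),
                             _CURR_SCALE, str(path))
        sweeps = []
        for key in sorted(k for k in f.keys() if k.startswith("sweep_")):
            g = f[key]
            ctx = f"{path}:{key}"
            v = np.asarray(g["voltage"]) * vscale
            c = np.asarray(g["current"]) * cscale
            if v.shape != c.shape:
                raise ArchiveError(
                    f"{ctx}: voltage length {v.size} != current length {c.size}"
                )
            sweeps.append(Sweep(
                voltage=v,
                current=c,
                sampling_rate=rate,
                step_amplitude=float(_require_attr(g, "step_amplitude_pA", ctx)) * cscale,
                step_onset=float(_require_attr(g, "step_onset_ms", ctx)),
                step_offset=float(_require_attr(g, "step_offset_ms", ctx)),
            ))
        meta = {}
        if "metadata_json" in f.attrs:
            meta = json.loads(f.attrs["metadata_json"])
        temp = float(f.attrs["temperature_C"]) if "temperature_C" in f.attrs else None
        return CellRecording(
            cell_id=str(f.attrs.get("cell_id", path.stem)),
            sweeps=sweeps,
            group=str(f.attrs.get("group", "")),
            junction_corrected=bool(f.attrs.get("junction_corrected", False)),
            junction_potential=float(
                f.attrs.get("junction_potential_mV", JUNCTION_POTENTIAL_MV)
            ),
            temperature=temp,
            metadata=meta,
        )


# ---------------------------------------------------------------------------
# CSV dialect (directory with manifest.json + one CSV per sweep)
# ---------------------------------------------------------------------------

def write_csv_archive(recording: CellRecording, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "spikephase-archive-csv",
        "format_version": 1,
        "cell_id": recording.cell_id,
        "group": recording.group,
        "sampling_rate_hz": recording.sampling_rate,
        "voltage_units": "mV",
        "current_units": "pA",
        "junction_corrected": recording.junction_corrected,
        "junction_potential_mV": recording.junction_potential,
        "temperature_C": recording.temperature,
        "sweeps": [],
    }
    for i, s in enumerate(recording.sweeps):
        name = f"sweep_{i:03d}.csv"
        manifest["sweeps"].append({
            "file": name,
            "step_amplitude_pA": s.step_amplitude,
            "step_onset_ms": s.step_onset,
            "step_offset_ms": s.step_offset,
        })
        with open(directory / name, "w") as fh:
            fh.write("time_ms,voltage_mV,current_pA\n")
            t = s.time
            for j in range(s.n_samples):
                fh.write(f"{t[j]:.6f},{s.voltage[j]:.9g},{s.current[j]:.9g}\n")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return directory


def _read_csv_archive(directory: Path) -> CellRecording:
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ArchiveError(f"{directory}: CSV archive missing manifest.json")
    manifest = json.loads(manifest_path.read_text())
    rate = manifest.get("sampling_rate_hz")
    if rate is None or rate <= 0:
        raise ArchiveError(f"{manifest_path}: missing or invalid sampling_rate_hz")
    vscale = _unit_scale(manifest.get("voltage_units", "mV"), _VOLT_SCALE,
                         str(manifest_path))
    cscale = _unit_scale(manifest.get("current_units", "pA"), _CURR_SCALE,
                         str(manifest_path))
    sweeps = []
    for entry in manifest["sweeps"]:
        fpath = directory / entry["file"]
        if not fpath.exists():
            raise ArchiveError(f"{fpath}: sweep file listed in manifest is missing")
        data = np.genfromtxt(fpath, delimiter=",", names=True)
        if data.size == 0 or any(
            c not in (data.dtype.names or ()) for c in ("voltage_mV", "current_pA")
        ):
            raise ArchiveError(
                f"{fpath}: expected columns time_ms,voltage_mV,current_pA"
            )
        sweeps.append(Sweep(
            voltage=np.atleast_1d(data["voltage_mV"]) * vscale,
            current=np.atleast_1d(data["current_pA"]) * cscale,
            sampling_rate=float(rate),
            step_amplitude=float(entry["step_amplitude_pA"]) * cscale,
            step_onset=float(entry["step_onset_ms"]),
            step_offset=float(entry["step_offset_ms"]),
        ))
    return CellRecording(
        cell_id=manifest.get("cell_id", directory.name),
        sweeps=sweeps,
        group=manifest.get("group", ""),
        junction_corrected=bool(manifest.get("junction_corrected", False)),
        junction_potential=float(
            manifest.get("junction_potential_mV", JUNCTION_POTENTIAL_MV)
        ),
        temperature=manifest.get("temperature_C"),
    )
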