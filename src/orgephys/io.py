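"""Core data model and I/O for organoid MEA recordings.

Two in-memory containers carry everything downstream:

* :class:`SpikeTrainSet` -- spike-sorted single units (times in seconds,
  per-unit electrode position in micrometres on the array).
* :class:`LFPSet` -- an electrodes x samples voltage matrix in microvolts
  with its sampling rate and electrode layout.

Readers accept a flat CSV spike table or a Kilosort-style output directory,
and HDF5 or raw-binary voltage matrices.  Times are float64 seconds
everywhere inside the package; sample indices appear only at I/O boundaries.
"""

from __future__ import annotations

import ast
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "LFPSet",
    "UnitQualityRecord",
    "ValidationError",
    "BAND_LABELS",
    "load_spike_trains",
    "save_spike_trains",
    "curate_units",
    "load_lfp",
    "save_lfp",
]

#: Allowed values for :attr:`LFPSet.band`.
BAND_LABELS = ("raw", "lfp", "delta", "theta", "alpha", "beta", "gamma")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class SpikeTrainSet:
    """Spike-sorted single units with electrode geometry.

    Parameters
    ----------
    unit_ids
        Unique integer labels, one per unit.
    spike_times
        Mapping ``unit_id -> float64 array`` of spike times in seconds,
        strictly increasing, non-negative and bounded by ``duration``.
    unit_positions
        Mapping ``unit_id -> (x_um, y_um)`` on the array, or ``None`` when
        geometry is unknown (positions are only needed for spatial stages).
    duration
        Recording length in seconds.
    meta
        Free-form provenance map (source files, curation log, seeds ...).
    """

    unit_ids: np.ndarray
    spike_times: dict[int, np.ndarray]
    unit_positions: dict[int, tuple[float, float]] | None
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        if len(np.unique(self.unit_ids)) != len(self.unit_ids):
            raise ValidationError("unit_ids must be unique")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        for uid in self.unit_ids:
            t = np.asarray(self.spike_times[int(uid)], dtype=np.float64)
            self.spike_times[int(uid)] = t
            if t.size and (t[0] < 0 or t[-1] > self.duration + 1e-9):
                raise ValidationError(
                    f"unit {uid}: spike times outside [0, duration]"
                )
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"unit {uid}: spike times not strictly increasing"
                )
        if self.unit_positions is not None:
            for uid in self.unit_ids:
                xy = self.unit_positions.get(int(uid))
                if xy is None or not np.all(np.isfinite(xy)):
                    raise ValidationError(f"unit {uid}: position missing/not finite")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def train(self, unit_id: int) -> np.ndarray:
        return self.spike_times[int(unit_id)]

    def n_spikes(self, unit_id: int) -> int:
        return int(self.spike_times[int(unit_id)].size)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times.values()))

    def subset(self, keep_ids) -> "SpikeTrainSet":
        keep = [int(u) for u in keep_ids]
        pos = None
        if self.unit_positions is not None:
            pos = {u: self.unit_positions[u] for u in keep}
        return SpikeTrainSet(
            unit_ids=np.asarray(keep, dtype=np.int64),
            spike_times={u: self.spike_times[u] for u in keep},
            unit_positions=pos,
            duration=self.duration,
            meta=dict(self.meta),
        )

    def firing_rate(self, unit_id: int) -> float:
        return self.n_spikes(unit_id) / self.duration


@dataclass
class LFPSet:
    """Electrodes x samples voltage matrix in microvolts."""

    data: np.ndarray
    fs: float
    electrode_positions: np.ndarray
    band: str = "raw"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be electrodes x samples")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        self.electrode_positions = np.asarray(self.electrode_positions, dtype=np.float64)
        if self.electrode_positions.shape != (self.data.shape[0], 2):
            raise ValidationError(
                "electrode_positions must be (n_electrodes, 2); got "
                f"{self.electrode_positions.shape} for {self.data.shape[0]} electrodes"
            )
        if self.band not in BAND_LABELS:
            raise ValidationError(f"band must be one of {BAND_LABELS}")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class UnitQualityRecord:
    """Spike-sorting quality metrics used to curate the unit table."""

    unit_id: int
    isi_violation_fraction: float
    firing_rate: float
    snr: float

    def __post_init__(self) -> None:
        for name in ("isi_violation_fraction", "firing_rate", "snr"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Spike-train I/O
# ---------------------------------------------------------------------------

def _from_table(df: pd.DataFrame, duration: float | None) -> SpikeTrainSet:
    if not {"unit_id", "time_s"}.issubset(df.columns):
        raise ValidationError("spike CSV needs columns unit_id,time_s[,x_um,y_um]")
    if np.any(df["time_s"].to_numpy() < 0):
        bad = sorted(df.loc[df["time_s"] < 0, "unit_id"].unique().tolist())
        raise ValidationError(f"negative spike times for units {bad}")
    have_pos = {"x_um", "y_um"}.issubset(df.columns)
    unit_ids = np.sort(df["unit_id"].unique()).astype(np.int64)
    times: dict[int, np.ndarray] = {}
    positions: dict[int, tuple[float, float]] | None = {} if have_pos else None
    for uid, grp in df.groupby("unit_id"):
        t = np.sort(grp["time_s"].to_numpy(dtype=np.float64))
        # collapse duplicate timestamps (sub-sample collisions)
        if t.size > 1:
            t = np.unique(t)
        times[int(uid)] = t
        if have_pos:
            positions[int(uid)] = (
                float(grp["x_um"].iloc[0]),
                float(grp["y_um"].iloc[0]),
            )
    if duration is None:
        duration = float(max((t[-1] for t in times.values() if t.size), default=0.0))
        duration = duration if duration > 0 else 1.0
    return SpikeTrainSet(unit_ids, times, positions, float(duration))


def _read_params_file(path: Path) -> dict:
    """Parse a Kilosort ``params.py``-style key = value text file."""
    out: dict = {}
    for line in path.read_text().splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        try:
            out[key.strip()] = ast.literal_eval(val.strip())
        except (ValueError, SyntaxError):
            out[key.strip()] = val.strip().strip("'\"")
    return out


def _from_kilosort_dir(path: Path, duration: float | None) -> SpikeTrainSet:
    for fname in ("spike_times.npy", "spike_clusters.npy", "params.py"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing {path / fname}")
    params = _read_params_file(path / "params.py")
    fs = float(params.get("sample_rate", params.get("fs", 0.0)))
    if fs <= 0:
        raise ValidationError(f"no positive sample_rate in {path / 'params.py'}")
    samples = np.load(path / "spike_times.npy").ravel().astype(np.int64)
    clusters = np.load(path / "spike_clusters.npy").ravel().astype(np.int64)
    if samples.size != clusters.size:
        raise ValidationError("spike_times and spike_clusters length mismatch")
    if np.any(samples < 0):
        bad = sorted(np.unique(clusters[samples < 0]).tolist())
        raise ValidationError(f"negative spike sample indices for units {bad}")
    df = pd.DataFrame({"unit_id": clusters, "time_s": samples / fs})

    # Optional geometry: phy-style cluster_info.tsv maps units to channels.
    info_path = path / "cluster_info.tsv"
    chan_path = path / "channel_positions.npy"
    if info_path.exists() and chan_path.exists():
        chan_pos = np.load(chan_path)
        info = pd.read_csv(info_path, sep="\t")
        id_col = "cluster_id" if "cluster_id" in info.columns else "id"
        ch = dict(zip(info[id_col].astype(int), info["ch"].astype(int)))
        df["x_um"] = [chan_pos[ch[u], 0] if u in ch else np.nan for u in df["unit_id"]]
        df["y_um"] = [chan_pos[ch[u], 1] if u in ch else np.nan for u in df["unit_id"]]
        if df[["x_um", "y_um"]].isna().any().any():
            df = df.drop(columns=["x_um", "y_um"])
    sts = _from_table(df, duration)
    sts.meta["source"] = str(path)
    sts.meta["fs"] = fs
    return sts


def load_spike_trains(
    path, format: str = "csv", duration: float | None = None
) -> SpikeTrainSet:
    """Read spike-sorted single units from disk.

    Parameters
    ----------
    path
        CSV file (columns ``unit_id,time_s[,x_um,y_um]``) or a Kilosort-style
        directory (``spike_times.npy`` sample indices, ``spike_clusters.npy``,
        ``params.py`` with ``sample_rate``, optional ``channel_positions.npy``
        + ``cluster_info.tsv`` for geometry).
    format
        ``"csv"`` or ``"kilosort_dir"``.
    duration
        Recording length in seconds; inferred as the last spike time if
        omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format == "csv":
        sts = _from_table(pd.read_csv(path), duration)
        sts.meta["source"] = str(path)
        return sts
    if format == "kilosort_dir":
        return _from_kilosort_dir(path, duration)
    raise ValidationError(f"unknown format {format!r}")


def save_spike_trains(trains: SpikeTrainSet, path) -> None:
    """Write a spike table CSV (round-trips with :func:`load_spike_trains`)."""
    rows = []
    for uid in trains.unit_ids:
        uid = int(uid)
        t = trains.spike_times[uid]
        if trains.unit_positions is not None:
            x, y = trains.unit_positions[uid]
            rows.append(pd.DataFrame(
                {"unit_id": uid, "time_s": t, "x_um": x, "y_um": y}))
        else:
            rows.append(pd.DataFrame({"unit_id": uid, "time_s": t}))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["unit_id", "time_s"])
    df.to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def curate_units(
    trains: SpikeTrainSet,
    quality: list[UnitQualityRecord],
    isi_violation_max: float = 0.3,
    rate_min: float = 0.05,
    snr_min: float = 5.0,
) -> SpikeTrainSet:
    """Drop units failing the spike-sorting quality gates.

    A unit is removed when its ISI-violation fraction is *above*
    ``isi_violation_max``, its firing rate is *below* ``rate_min`` or its SNR
    is *below* ``snr_min`` -- values exactly at a threshold are retained.
    Removal reasons are logged under ``meta['curation']``.
    """
    qmap = {int(q.unit_id): q for q in quality}
    missing = [int(u) for u in trains.unit_ids if int(u) not in qmap]
    if missing:
        raise ValidationError(f"no quality record for units {missing}")
    keep, removed = [], {}
    for uid in trains.unit_ids:
        q = qmap[int(uid)]
        reasons = []
        if q.isi_violation_fraction > isi_violation_max:
            reasons.append("isi_violation")
        if q.firing_rate < rate_min:
            reasons.append("low_rate")
        if q.snr < snr_min:
            reasons.append("low_snr")
        if reasons:
            removed[int(uid)] = reasons
        else:
            keep.append(int(uid))
    out = trains.subset(keep)
    out.meta.setdefault("curation", {}).update(
        {str(k): v for k, v in removed.items()})
    return out


# ---------------------------------------------------------------------------
# LFP I/O
# ---------------------------------------------------------------------------

def load_lfp(
    path,
    fs_in: float | None = None,
    layout: np.ndarray | None = None,
    gain_uv_per_bit: float | None = None,
    n_electrodes: int | None = None,
    dtype: str = "int16",
) -> LFPSet:
    """Read a voltage matrix from HDF5 or raw binary.

    HDF5 layout: dataset ``data`` (electrodes x samples) with attrs ``fs``,
    ``band``, ``t0`` and a dataset ``positions``.  Raw binary: interleaved
    ``dtype`` samples with ``n_electrodes`` rows; ``gain_uv_per_bit`` scales
    integer counts to microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["data"][...].astype(np.float64)
            fs = float(f["data"].attrs.get("fs", fs_in or 0.0))
            band = str(f["data"].attrs.get("band", "raw"))
            t0 = float(f["data"].attrs.get("t0", 0.0))
            positions = f["positions"][...] if "positions" in f else layout
        if gain_uv_per_bit is not None:
            data = data * gain_uv_per_bit
        return LFPSet(data, fs, positions, band=band, t0=t0)
    # raw binary
    if fs_in is None or layout is None or n_electrodes is None:
        raise ValidationError("raw binary needs fs_in, layout and n_electrodes")
    flat = np.fromfile(path, dtype=np.dtype(dtype))
    if flat.size % n_electrodes:
        raise ValidationError(
            f"file length {flat.size} not divisible by {n_electrodes} electrodes")
    data = flat.reshape(-1, n_electrodes).T.astype(np.float64)
    if gain_uv_per_bit is not None:
        data = data * gain_uv_per_bit
    return LFPSet(data, float(fs_in), layout, band="raw")


def save_lfp(lfp: LFPSet, path) -> None:
    """Write an :class:`LFPSet` to HDF5 (float32 voltages)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=lfp.data.astype(np.float32))
        d.attrs["fs"] = lfp.fs
        d.attrs["band"] = lfp.band
        d.attrs["t0"] = lfp.t0
        f.create_dataset("positions", data=lfp.electrode_positions)


def write_json(obj, path) -> None:
    """Serialize a result object to JSON with stable key order."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
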