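"""Domain types and plain-CSV serialization for sensor-array voltammetry.

A measurement campaign with an electronic tongue produces, per sample, one
current-vs-potential trace for every working electrode in the array, plus
metadata (a class label and/or known analyte concentrations).  This module
holds the shared containers for those data and a diff-friendly on-disk
layout: one manifest CSV plus one trace CSV per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "LoadError",
    "ValidationError",
    "PotentialProgram",
    "Voltammogram",
    "ArraySample",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "drop_sensors",
]

# Manifest columns that are not analyte concentrations.
_MANIFEST_FIXED_COLS = ("sample_id", "class_label", "replicate_index", "trace_file")


class DatasetError(ValueError):
    """Base class for dataset construction and I/O failures."""


class ValidationError(DatasetError):
    """A container invariant is violated."""


class LoadError(DatasetError):
    """A referenced file is missing or unreadable."""


@dataclass(frozen=True)
class PotentialProgram:
    """Triangular (cyclic) potential sweep: start -> vertex -> start.

    ``step_V`` records the nominal instrument step increment; the actual
    trace length is fixed by ``n_points`` (instrument exports do not always
    match the count implied by the potential window and step).

    Parameters
    ----------
    start_V : float
        Initial (and final) potential of the cycle, in volts.
    vertex_V : float
        Turning potential, in volts.
    step_V : float
        Nominal step potential in volts; must be positive.
    n_points : int
        Number of points in the full cycle (>= 4).
    """

    start_V: float = -0.7
    vertex_V: float = 1.2
    step_V: float = 0.010
    n_points: int = 424

    def __post_init__(self) -> None:
        if not self.step_V > 0:
            raise ValidationError(f"step_V must be > 0, got {self.step_V}")
        if self.n_points < 4:
            raise ValidationError(f"n_points must be >= 4, got {self.n_points}")

    def potentials(self) -> np.ndarray:
        """Potential sequence of the full cycle (V), length ``n_points``."""
        n_fwd = (self.n_points + 1) // 2
        fwd = np.linspace(self.start_V, self.vertex_V, n_fwd)
        rev = np.linspace(self.vertex_V, self.start_V, self.n_points - n_fwd + 1)[1:]
        return np.concatenate([fwd, rev])

    def forward_mask(self) -> np.ndarray:
        """Boolean mask of the forward (start -> vertex) branch."""
        mask = np.zeros(self.n_points, dtype=bool)
        mask[: (self.n_points + 1) // 2] = True
        return mask


@dataclass
class Voltammogram:
    """A single sensor's current trace over a potential program.

    Currents are in microamperes, potentials in volts.
    """

    sensor_id: str
    potentials: np.ndarray
    currents: np.ndarray

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape or self.potentials.ndim != 1:
            raise ValidationError(
                f"sensor {self.sensor_id!r}: potentials and currents must be "
                f"1-D vectors of equal length "
                f"({self.potentials.shape} vs {self.currents.shape})"
            )
        if not (np.isfinite(self.potentials).all() and np.isfinite(self.currents).all()):
            raise ValidationError(f"sensor {self.sensor_id!r}: non-finite trace values")

    def __len__(self) -> int:
        return self.currents.size


@dataclass
class ArraySample:
    """All sensors' voltammograms for one measured sample.

    ``concentrations`` maps analyte name to concentration in µM; missing
    analytes are treated as 0 µM (blanks are first-class samples).
    """

    sample_id: str
    class_label: str
    concentrations: dict[str, float]
    voltammograms: dict[str, Voltammogram]
    replicate_index: int = 0

    def __post_init__(self) -> None:
        for analyte, c in self.concentrations.items():
            if c < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative concentration "
                    f"{c} for {analyte!r}"
                )
        grids = [v.potentials for v in self.voltammograms.values()]
        for v, grid in zip(self.voltammograms.values(), grids):
            if not np.array_equal(grids[0], grid):
                raise ValidationError(
                    f"sample {self.sample_id!r}: sensor {v.sensor_id!r} uses a "
                    "different potential grid than the first sensor"
                )

    def concentration(self, analyte: str) -> float:
        return float(self.concentrations.get(analyte, 0.0))


@dataclass
class Dataset:
    """Ordered collection of array samples with a fixed sensor roster."""

    samples: list[ArraySample]
    sensor_roster: list[str]
    analytes: list[str]

    def __post_init__(self) -> None:
        self.sensor_roster = list(self.sensor_roster)
        self.analytes = list(self.analytes)
        for s in self.samples:
            for sid in self.sensor_roster:
                if sid not in s.voltammograms:
                    raise ValidationError(
                        f"sample {s.sample_id!r} lacks a voltammogram for "
                        f"sensor {sid!r}"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def class_labels(self) -> list[str]:
        return [s.class_label for s in self.samples]

    def concentration_matrix(self) -> np.ndarray:
        """Samples × analytes concentration matrix (µM)."""
        return np.array(
            [[s.concentration(a) for a in self.analytes] for s in self.samples],
            dtype=float,
        )


def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Serialize a dataset to ``out_dir`` and return the manifest path.

    Layout: ``manifest.csv`` plus ``traces/<sample_id>.csv``, where each
    trace file has a ``potential_V`` column followed by one current column
    (µA) per sensor in roster order.  Floats are written with the shortest
    round-trip representation, so ``read_dataset`` reproduces the arrays
    bit for bit.
    """
    out_dir = Path(out_dir)
    trace_dir = out_dir / "traces"
    try:
        trace_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise LoadError(f"cannot create output directory {out_dir}: {exc}") from exc

    rows = []
    for s in ds.samples:
        rel = Path("traces") / f"{s.sample_id}.csv"
        cols: dict[str, np.ndarray] = {}
        if ds.sensor_roster:
            first = s.voltammograms[ds.sensor_roster[0]]
            cols["potential_V"] = first.potentials
            for sid in ds.sensor_roster:
                cols[sid] = s.voltammograms[sid].currents
        pd.DataFrame(cols).to_csv(out_dir / rel, index=False)
        row = {
            "sample_id": s.sample_id,
            "class_label": s.class_label,
            "replicate_index": s.replicate_index,
        }
        for a in ds.analytes:
            row[a] = s.concentration(a)
        row["trace_file"] = rel.as_posix()
        rows.append(row)

    manifest = out_dir / "manifest.csv"
    columns = ["sample_id", "class_label", "replicate_index", *ds.analytes, "trace_file"]
    pd.DataFrame(rows, columns=columns).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset from a manifest CSV written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise LoadError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(
        manifest_path,
        dtype={"sample_id": str, "class_label": str},
        float_precision="round_trip",
    )
    for col in _MANIFEST_FIXED_COLS:
        if col not in df.columns:
            raise ValidationError(f"manifest missing required column {col!r}")
    analytes = [c for c in df.columns if c not in _MANIFEST_FIXED_COLS]

    base = manifest_path.parent
    samples: list[ArraySample] = []
    roster: list[str] | None = None
    ref_len: int | None = None
    for _, row in df.iterrows():
        trace_path = base / str(row["trace_file"])
        if not trace_path.exists():
            raise LoadError(
                f"trace file for sample {row['sample_id']!r} not found: {trace_path}"
            )
        trace = pd.read_csv(trace_path, float_precision="round_trip")
        if "potential_V" not in trace.columns:
            raise ValidationError(
                f"trace file {trace_path} lacks a 'potential_V' column"
            )
        sensors = [c for c in trace.columns if c != "potential_V"]
        if roster is None:
            roster = sensors
        elif sensors != roster:
            raise ValidationError(
                f"sample {row['sample_id']!r}: sensor columns {sensors} do not "
                f"match roster {roster}"
            )
        if ref_len is None:
            ref_len = len(trace)
        elif len(trace) != ref_len:
            raise ValidationError(
                f"sample {row['sample_id']!r}: trace length {len(trace)} differs "
                f"from first sample's {ref_len} (sensors {roster})"
            )
        potentials = trace["potential_V"].to_numpy()
        vgrams = {
            sid: Voltammogram(sid, potentials, trace[sid].to_numpy())
            for sid in sensors
        }
        conc = {a: float(row[a]) if pd.notna(row[a]) else 0.0 for a in analytes}
        samples.append(
            ArraySample(
                sample_id=str(row["sample_id"]),
                class_label=str(row["class_label"]),
                concentrations=conc,
                voltammograms=vgrams,
                replicate_index=int(row["replicate_index"]),
            )
        )
    return Dataset(samples=samples, sensor_roster=roster or [], analytes=analytes)


def drop_sensors(ds: Dataset, removed: Iterable[str]) -> Dataset:
    """Return a copy of ``ds`` with ``removed`` sensors excluded.

    The operation is order-insensitive and never mutates its input; at
    least one sensor must remain.
    """
    removed = set(removed)
    unknown = removed - set(ds.sensor_roster)
    if unknown:
        raise ValidationError(f"unknown sensors: {sorted(unknown)}")
    kept = [sid for sid in ds.sensor_roster if sid not in removed]
    if not kept:
        raise ValidationError("cannot remove all sensors from the roster")
    new_samples = [
        ArraySample(
            sample_id=s.sample_id,
            class_label=s.class_label,
            concentrations=dict(s.concentrations),
            voltammograms={sid: s.voltammograms[sid] for sid in kept},
            replicate_index=s.replicate_index,
        )
        for s in ds.samples
    ]
    return Dataset(samples=new_samples, sensor_roster=kept, analytes=list(ds.analytes))
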