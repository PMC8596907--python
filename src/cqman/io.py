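"""Plate I/O and display-only smoothing.

The canonical exchange format is a *long* CSV with one row per (well, cycle)
and columns ``well,gene,sample,concentration,cycle,fluorescence``.  A *wide*
dialect (one ``Cycle`` column plus one column per well, with an optional
sidecar annotation CSV ``well,gene,sample,concentration``) is accepted as a
convenience importer.

Savitzky-Golay smoothing is provided strictly for visual display: no
quantification routine in this package ever consumes its output.  Smoothing
raw qPCR data before analysis is known to bias quantification, so the
analysis path works on raw fluorescence only.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import CurveValidationError, FormatError, ParameterError

LONG_COLUMNS = ["well", "gene", "sample", "concentration", "cycle", "fluorescence"]

#: Fixed column order of the per-curve results CSV.
RESULT_COLUMNS = [
    "well_id", "gene", "y0", "ymax", "b", "x0", "x_sdm",
    "fq", "cq", "e_individual", "e_mean", "f0", "status",
]

_RESULT_NUMERIC = [c for c in RESULT_COLUMNS if c not in ("well_id", "gene", "status")]

MIN_CYCLES = 10


@dataclasses.dataclass(frozen=True, eq=False)
class AmplificationCurve:
    """One well's raw fluorescence trace with its annotations.

    Cycles are 1-based consecutive integers; fluorescence is in arbitrary
    instrument units.  ``known_concentration`` is the input amount for
    dilution-series standards and ``None`` for unknowns/NTCs.
    """

    well_id: str
    gene: str
    sample: str
    known_concentration: float | None
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles)
        fluor = np.asarray(self.fluorescence, dtype=float)
        if cycles.size != fluor.size:
            raise CurveValidationError(
                f"well {self.well_id!r}: cycles ({cycles.size}) and fluorescence "
                f"({fluor.size}) lengths differ"
            )
        if cycles.size < MIN_CYCLES:
            raise CurveValidationError(
                f"well {self.well_id!r}: at least {MIN_CYCLES} cycles required, "
                f"got {cycles.size}"
            )
        cycles_f = np.asarray(cycles, dtype=float)
        if not np.all(np.isfinite(cycles_f)) or np.any(cycles_f != np.round(cycles_f)):
            raise CurveValidationError(
                f"well {self.well_id!r}: cycle numbers must be integers"
            )
        cycles_i = cycles_f.astype(int)
        if not np.array_equal(cycles_i, np.arange(1, cycles_i.size + 1)):
            raise CurveValidationError(
                f"well {self.well_id!r}: cycles must be consecutive integers "
                "starting at 1 (no gaps)"
            )
        if not np.all(np.isfinite(fluor)):
            raise CurveValidationError(
                f"well {self.well_id!r}: fluorescence contains non-finite values"
            )
        conc = self.known_concentration
        if conc is not None:
            conc = float(conc)
            if not np.isfinite(conc) or conc <= 0:
                raise CurveValidationError(
                    f"well {self.well_id!r}: known_concentration must be positive"
                )
        object.__setattr__(self, "known_concentration", conc)
        object.__setattr__(self, "cycles", cycles_i)
        object.__setattr__(self, "fluorescence", fluor)
        self.cycles.setflags(write=False)
        self.fluorescence.setflags(write=False)

    @property
    def n_cycles(self) -> int:
        return int(self.cycles.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmplificationCurve):
            return NotImplemented
        return (
            self.well_id == other.well_id
            and self.gene == other.gene
            and self.sample == other.sample
            and (
                (self.known_concentration is None and other.known_concentration is None)
                or (
                    self.known_concentration is not None
                    and other.known_concentration is not None
                    and self.known_concentration == other.known_concentration
                )
            )
            and np.array_equal(self.cycles, other.cycles)
            and np.array_equal(self.fluorescence, other.fluorescence)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclasses.dataclass(frozen=True, eq=False)
class PlateData:
    """A collection of amplification curves from one run/export."""

    curves: tuple[AmplificationCurve, ...]
    dataset_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        wells = [c.well_id for c in self.curves]
        if len(set(wells)) != len(wells):
            dupes = sorted({w for w in wells if wells.count(w) > 1})
            raise CurveValidationError(f"duplicate well ids in plate: {dupes}")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateData):
            return NotImplemented
        return (
            self.dataset_label == other.dataset_label
            and self.curves == other.curves
        )

    __hash__ = None  # type: ignore[assignment]

    def to_long_frame(self) -> pd.DataFrame:
        """Flatten to the long CSV schema (one row per well x cycle)."""
        rows = []
        for c in self.curves:
            conc = c.known_concentration
            rows.append(
                pd.DataFrame(
                    {
                        "well": c.well_id,
                        "gene": c.gene,
                        "sample": c.sample,
                        "concentration": np.nan if conc is None else conc,
                        "cycle": c.cycles,
                        "fluorescence": c.fluorescence,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=LONG_COLUMNS)
        return pd.concat(rows, ignore_index=True)[LONG_COLUMNS]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _numeric_or_raise(series: pd.Series, name: str, path) -> pd.Series:
    coerced = pd.to_numeric(series, errors="coerce")
    bad = coerced.isna()
    if bad.any():
        # +2: one for the header row, one for 0-based indexing
        row = int(bad.idxmax()) + 2
        raise FormatError(
            f"{path}: non-numeric {name} value {series[bad.idxmax()]!r} at row {row}"
        )
    return coerced


def read_amplification_csv(
    path,
    dialect: str = "long",
    annotations=None,
    dataset_label: str | None = None,
) -> PlateData:
    """Read a plate of amplification curves from CSV.

    Parameters
    ----------
    path
        CSV file.  Long dialect: columns ``well,gene,sample,concentration,
        cycle,fluorescence``.  Wide dialect: a ``Cycle`` column plus one
        column per well.
    dialect
        ``"long"`` (canonical) or ``"wide"``.
    annotations
        For the wide dialect only: sidecar CSV with columns
        ``well,gene,sample,concentration``.  Wells absent from the sidecar
        get empty gene/sample and no concentration.
    """
    if dialect == "long":
        return _read_long(path, dataset_label)
    if dialect == "wide":
        return _read_wide(path, annotations, dataset_label)
    raise ParameterError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")


def _read_long(path, dataset_label: str | None) -> PlateData:
    df = pd.read_csv(
        path,
        dtype={"well": str, "gene": str, "sample": str},
        float_precision="round_trip",
    )
    _require_columns(df, LONG_COLUMNS, path)
    df = df.reset_index(drop=True)
    fluor = _numeric_or_raise(df["fluorescence"], "fluorescence", path)
    cycle = _numeric_or_raise(df["cycle"], "cycle", path)
    conc = pd.to_numeric(df["concentration"], errors="coerce")

    curves = []
    for well, grp in df.groupby("well", sort=False):
        idx = grp.index
        order = np.argsort(cycle[idx].to_numpy(), kind="stable")
        c_conc = conc[idx].iloc[0]
        curves.append(
            AmplificationCurve(
                well_id=str(well),
                gene=str(grp["gene"].iloc[0]) if pd.notna(grp["gene"].iloc[0]) else "",
                sample=str(grp["sample"].iloc[0]) if pd.notna(grp["sample"].iloc[0]) else "",
                known_concentration=None if pd.isna(c_conc) else float(c_conc),
                cycles=cycle[idx].to_numpy()[order],
                fluorescence=fluor[idx].to_numpy()[order],
            )
        )
    label = dataset_label if dataset_label is not None else str(path)
    return PlateData(curves=tuple(curves), dataset_label=label)


def _read_wide(path, annotations, dataset_label: str | None) -> PlateData:
    df = pd.read_csv(path, float_precision="round_trip")
    if "Cycle" not in df.columns:
        raise FormatError(f"{path}: missing required column 'Cycle'")
    ann: dict[str, tuple[str, str, float | None]] = {}
    if annotations is not None:
        ann_df = pd.read_csv(annotations, dtype={"well": str, "gene": str, "sample": str})
        _require_columns(ann_df, ["well", "gene", "sample", "concentration"], annotations)
        for _, row in ann_df.iterrows():
            conc = pd.to_numeric(row["concentration"], errors="coerce")
            ann[str(row["well"])] = (
                str(row["gene"]) if pd.notna(row["gene"]) else "",
                str(row["sample"]) if pd.notna(row["sample"]) else "",
                None if pd.isna(conc) else float(conc),
            )
    cycles = _numeric_or_raise(df["Cycle"], "Cycle", path).to_numpy()
    curves = []
    for col in df.columns:
        if col == "Cycle":
            continue
        fluor = _numeric_or_raise(df[col], f"fluorescence ({col})", path).to_numpy()
        gene, sample, conc = ann.get(str(col), (str(col), "", None))
        curves.append(
            AmplificationCurve(
                well_id=str(col), gene=gene, sample=sample,
                known_concentration=conc, cycles=cycles, fluorescence=fluor,
            )
        )
    label = dataset_label if dataset_label is not None else str(path)
    return PlateData(curves=tuple(curves), dataset_label=label)


def write_plate_csv(plate: PlateData, path) -> None:
    """Write a plate in the long dialect (exact float round-trip)."""
    plate.to_long_frame().to_csv(path, index=False)


def write_results(results, path) -> None:
    """Write per-curve quantification results to CSV.

    ``results`` is an iterable of quantification results (anything exposing
    the RESULT_COLUMNS fields, e.g. ``QuantResult``) or an equivalent
    DataFrame.  Floats are rendered with 9 significant digits; rows whose
    status is not ``"ok"`` leave unavailable numeric fields blank.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        rows = []
        for r in results:
            if dataclasses.is_dataclass(r):
                d = dataclasses.asdict(r)
            else:
                d = dict(r)
            rows.append({c: d.get(c, np.nan) for c in RESULT_COLUMNS})
        df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("well_id", "gene", "status") else np.nan
    df = df[RESULT_COLUMNS]

    out = df.copy()
    for col in _RESULT_NUMERIC:
        vals = pd.to_numeric(out[col], errors="coerce")
        out[col] = ["" if not np.isfinite(v) else format(v, ".9g") for v in vals]
    out.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={"well_id": str, "gene": str, "status": str})
    _require_columns(df, RESULT_COLUMNS, path)
    for col in _RESULT_NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[RESULT_COLUMNS]


def smooth_for_display(
    curve: AmplificationCurve, window: int = 5, order: int = 2
) -> np.ndarray:
    """Savitzky-Golay smoothed fluorescence, for plotting only.

    The returned sequence must never be fed back into any quantification
    routine; fitting always uses ``curve.fluorescence`` directly.
    """
    n = curve.n_cycles
    if not isinstance(window, (int, np.integer)) or not isinstance(order, (int, np.integer)):
        raise ParameterError("window and order must be integers")
    if window % 2 != 1:
        raise ParameterError(f"window must be odd, got {window}")
    if order < 0 or window < order + 2:
        raise ParameterError(f"window ({window}) must be >= order+2 ({order + 2})")
    if window > n:
        raise ParameterError(f"window ({window}) exceeds curve length ({n})")
    return savgol_filter(np.asarray(curve.fluorescence, dtype=float), window, order)


def plate_from_records(records: Iterable[dict], dataset_label: str = "") -> PlateData:
    """Build a plate from per-well dicts with keys matching AmplificationCurve."""
    return PlateData(
        curves=tuple(AmplificationCurve(**rec) for rec in records),
        dataset_label=dataset_label,
    )
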