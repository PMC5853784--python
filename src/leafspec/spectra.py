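"""Spectral records, trait tables, and their tabular text formats.

A leaf spectrum is a reflectance fraction on a strictly ascending 1 nm
wavelength grid.  The canonical ingest grid is 350-2500 nm (2151 points),
matching ASD-class full-range field spectroradiometers; trimming to the
400-2400 nm analysis window is a preprocessing step, not done at ingest.

Two text dialects are supported:

* wide  -- one row per record, wavelength columns named ``w350`` ... ``w2500``
* long  -- tidy triples ``record_id, wavelength_nm, reflectance``

Trait tables are plain delimited files with a header naming trait columns
(``Narea``, ``Nmass``, ``LMA``, ``SPAD``, ``Vcmax``, ``Vcmax25``, ``J`` ...)
plus the record key columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical full-range ingest grid (inclusive ends, 1 nm step).
FULL_RANGE_NM = (350, 2500)

#: Trait columns the pipeline knows about, with units.
TRAIT_UNITS = {
    "Narea": "g m-2",
    "Nmass": "mg g-1",
    "Parea": "g m-2",
    "Pmass": "mg g-1",
    "LMA": "g m-2",
    "SPAD": "unitless",
    "A": "umol CO2 m-2 s-1",
    "gs": "mol m-2 s-1",
    "Vcmax": "umol CO2 m-2 s-1",
    "Vcmax25": "umol CO2 m-2 s-1",
    "J": "umol m-2 s-1",
    "Vcmax25_per_Narea": "umol CO2 g-1 N s-1",
}

#: Record key columns for trait tables and spectral files.
KEY_COLUMNS = ["genotype", "experiment", "repetition", "leaf_replicate"]


class SpectrumError(ValueError):
    """Violation of a spectrum invariant (grid, finiteness, range)."""


class TraitTableError(ValueError):
    """Violation of a trait-table invariant (negative value, bad units)."""


@dataclass(frozen=True)
class Spectrum:
    """One leaf's reflectance on a 1 nm wavelength grid.

    Parameters
    ----------
    wavelengths_nm:
        Strictly ascending integer grid with exact 1 nm step.
    reflectance:
        Reflectance fraction per wavelength.  Raw (uncorrected) spectra may
        exceed 1 near detector splices, hence the ingest ceiling of 1.5.
    instrument_id:
        Free label for the spectroradiometer.
    junction_wavelengths_nm:
        Detector splice positions for this instrument, e.g. ``(1000, 1800)``
        for the Australian unit or ``(1000, 1830)`` for the Mexican one.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    instrument_id: str = "unknown"
    junction_wavelengths_nm: tuple[int, ...] = (1000, 1800)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=np.int64)
        r = np.asarray(self.reflectance, dtype=np.float64)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "reflectance", r)
        if w.ndim != 1 or r.ndim != 1 or w.size != r.size:
            raise SpectrumError("wavelengths and reflectance must be 1-D and equal length")
        if w.size < 2:
            raise SpectrumError("spectrum needs at least 2 wavelengths")
        dw = np.diff(w)
        if not np.all(dw == 1):
            bad = int(w[np.argmax(dw != 1)])
            raise SpectrumError(f"wavelength grid must ascend in exact 1 nm steps (break after {bad} nm)")
        if not np.all(np.isfinite(r)):
            raise SpectrumError("non-finite reflectance value")
        if r.min() < 0.0 or r.max() > 1.5:
            raise SpectrumError(
                f"reflectance outside ingest range [0, 1.5]: min={r.min():.4g} max={r.max():.4g}"
            )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.reflectance, other.reflectance)
        )

    def value_at(self, wavelength_nm: int) -> float:
        """Reflectance at an exact grid wavelength."""
        w0 = int(self.wavelengths_nm[0])
        idx = int(wavelength_nm) - w0
        if idx < 0 or idx >= len(self):
            raise SpectrumError(
                f"wavelength {wavelength_nm} nm outside spectrum domain "
                f"[{w0}, {int(self.wavelengths_nm[-1])}]"
            )
        return float(self.reflectance[idx])

    def covers(self, wavelength_nm: int) -> bool:
        return int(self.wavelengths_nm[0]) <= wavelength_nm <= int(self.wavelengths_nm[-1])

    def with_reflectance(self, reflectance: np.ndarray) -> "Spectrum":
        return replace(self, reflectance=np.asarray(reflectance, dtype=np.float64))


@dataclass(frozen=True)
class SpectralRecord:
    """A spectrum plus the metadata identifying the measured leaf.

    ``(genotype, experiment, repetition, leaf_replicate)`` uniquely identifies
    a record within a dataset.  ``repetition`` is the experimental-design
    repetition; ``leaf_replicate`` indexes repeated scans of one leaf (the
    sentinel ``"mean"`` marks a replicate average).
    """

    spectrum: Spectrum
    genotype: str
    experiment: str = "exp"
    repetition: int | str = 1
    leaf_replicate: int | str = 1
    stage: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.genotype, self.experiment, self.repetition, self.leaf_replicate)

    @property
    def record_id(self) -> str:
        return "|".join(str(k) for k in self.key)


def _parse_int_label(value) -> int | str:
    """Repetition / leaf_replicate: integer when possible, else kept as label."""
    try:
        return int(value)
    except (TypeError, ValueError):
        return str(value)


def record_id_parts(record_id: str) -> dict:
    parts = str(record_id).split("|")
    out = {"genotype": parts[0] if parts else str(record_id)}
    out["experiment"] = parts[1] if len(parts) > 1 else "exp"
    out["repetition"] = _parse_int_label(parts[2]) if len(parts) > 2 else 1
    out["leaf_replicate"] = _parse_int_label(parts[3]) if len(parts) > 3 else 1
    return out


# ---------------------------------------------------------------------------
# Spectral file I/O
# ---------------------------------------------------------------------------

def _records_to_wide_frame(records: Sequence[SpectralRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "genotype": rec.genotype,
            "experiment": rec.experiment,
            "repetition": rec.repetition,
            "leaf_replicate": rec.leaf_replicate,
            "stage": rec.stage,
            "instrument_id": rec.spectrum.instrument_id,
            "junctions": ";".join(str(j) for j in rec.spectrum.junction_wavelengths_nm),
        }
        row.update(
            {f"w{int(w)}": float(r) for w, r in zip(rec.spectrum.wavelengths_nm, rec.spectrum.reflectance)}
        )
        rows.append(row)
    if not rows:
        cols = KEY_COLUMNS + ["stage", "instrument_id", "junctions"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def _wide_frame_to_records(df: pd.DataFrame, path: str) -> list[SpectralRecord]:
    wcols = [c for c in df.columns if c.startswith("w") and c[1:].isdigit()]
    if not wcols:
        raise SpectrumError(f"{path}: no wavelength columns (expected names like 'w350')")
    wl = np.array(sorted(int(c[1:]) for c in wcols), dtype=np.int64)
    ordered = [f"w{w}" for w in wl]
    records: list[SpectralRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        vals = pd.to_numeric(row[ordered], errors="coerce").to_numpy(dtype=np.float64)
        if np.isnan(vals).any():
            col = ordered[int(np.argmax(np.isnan(vals)))]
            raise SpectrumError(f"{path}: non-numeric reflectance at row {i + 2}, column {col}")
        junctions = tuple(
            int(j) for j in str(row.get("junctions", "1000;1800")).split(";") if str(j).strip()
        )
        spec = Spectrum(
            wavelengths_nm=wl,
            reflectance=vals,
            instrument_id=str(row.get("instrument_id", "unknown")),
            junction_wavelengths_nm=junctions or (1000, 1800),
        )
        records.append(
            SpectralRecord(
                spectrum=spec,
                genotype=str(row.get("genotype", f"rec{i}")),
                experiment=str(row.get("experiment", "exp")),
                repetition=_parse_int_label(row.get("repetition", 1)),
                leaf_replicate=_parse_int_label(row.get("leaf_replicate", 1)),
                stage=str(row.get("stage", "")) if not pd.isna(row.get("stage", "")) else "",
            )
        )
    return records


def read_spectra(path: str | Path, dialect: str = "wide") -> list[SpectralRecord]:
    """Read spectral records from a delimited text file.

    ``dialect="wide"``: one row per record, one column per wavelength.
    ``dialect="long"``: ``record_id, wavelength_nm, reflectance`` triples.
    Input order of records is preserved.  Grid and value invariants are
    validated on every record; violations raise :class:`SpectrumError` naming
    the offending row or record.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if dialect == "wide":
        return _wide_frame_to_records(df, str(path))
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")

    required = {"record_id", "wavelength_nm", "reflectance"}
    if not required.issubset(df.columns):
        raise SpectrumError(f"{path}: long dialect needs columns {sorted(required)}")
    refl = pd.to_numeric(df["reflectance"], errors="coerce")
    if refl.isna().any():
        row = int(refl.index[refl.isna()][0]) + 2
        raise SpectrumError(f"{path}: non-numeric reflectance at row {row}, column reflectance")
    records = []
    for rid, grp in df.groupby("record_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        wl = grp["wavelength_nm"].to_numpy(dtype=np.int64)
        if wl.size >= 2 and not np.all(np.diff(wl) == 1):
            gap = int(wl[np.argmax(np.diff(wl) != 1)])
            raise SpectrumError(f"{path}: record {rid!r} grid not contiguous (break after {gap} nm)")
        spec = Spectrum(wavelengths_nm=wl, reflectance=grp["reflectance"].to_numpy(dtype=np.float64))
        records.append(SpectralRecord(spectrum=spec, **record_id_parts(str(rid))))
    return records


def write_spectra(records: Sequence[SpectralRecord], path: str | Path, dialect: str = "wide") -> Path:
    """Write records to a delimited text file; lossless round trip with
    :func:`read_spectra` (reflectance is serialized at full float precision)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    if dialect == "wide":
        df = _records_to_wide_frame(records)
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
        return path
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")
    rows = []
    for rec in records:
        for w, r in zip(rec.spectrum.wavelengths_nm, rec.spectrum.reflectance):
            rows.append((rec.record_id, int(w), float(r)))
    df = pd.DataFrame(rows, columns=["record_id", "wavelength_nm", "reflectance"])
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-record trait values with fixed unit conventions.

    Wraps a DataFrame keyed by record; trait columns follow
    :data:`TRAIT_UNITS`.  Unknown columns are preserved untouched in
    ``extra_columns``.  All present trait values must be positive, and where
    ``Narea``, ``Nmass`` and ``LMA`` are all present they must satisfy
    ``Narea = Nmass * LMA / 1000`` within 1% (unit consistency: mg g-1 times
    g m-2 over 1000 gives g m-2).
    """

    data: pd.DataFrame
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def traits_present(self) -> list[str]:
        return [c for c in TRAIT_UNITS if c in self.data.columns]

    def validate(self) -> None:
        for col in self.traits_present:
            vals = self.data[col].dropna()
            bad = vals[vals <= 0]
            if len(bad):
                rec = bad.index[0]
                raise TraitTableError(f"non-positive {col}={bad.iloc[0]:.4g} for record {rec!r}")
        cols = {"Narea", "Nmass", "LMA"}
        if cols.issubset(self.data.columns):
            sub = self.data[list(cols)].dropna()
            if len(sub):
                derived = sub["Nmass"] * sub["LMA"] / 1000.0
                rel = np.abs(derived - sub["Narea"]) / sub["Narea"]
                if (rel > 0.01).any():
                    rec = rel.index[int(np.argmax(rel.to_numpy() > 0.01))]
                    raise TraitTableError(
                        f"record {rec!r}: Narea inconsistent with Nmass*LMA/1000 by "
                        f"{100 * float(rel.loc[rec]):.1f}% (>1%)"
                    )

    def values_for(self, trait: str, record_ids: Iterable[str] | None = None) -> pd.Series:
        if trait not in self.data.columns:
            raise TraitTableError(f"trait {trait!r} not present (have {self.traits_present})")
        s = self.data[trait]
        if record_ids is not None:
            s = s.reindex(list(record_ids))
        return s


def read_trait_table(path: str | Path, index_col: str = "record_id") -> TraitTable:
    """Read a delimited trait table; unknown columns are kept as metadata."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if index_col in df.columns:
        df = df.set_index(index_col)
    extras = [c for c in df.columns if c not in TRAIT_UNITS and c not in KEY_COLUMNS]
    return TraitTable(data=df, extra_columns=extras)


def write_trait_table(table: TraitTable, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.data.to_csv(path, sep=sep, index=True, index_label="record_id", float_format="%.17g")
    return path
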