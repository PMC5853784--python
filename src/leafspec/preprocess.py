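"""Spectral pre-treatment: splice-jump correction, the 800 nm outlier rule,
trimming to the analysis window, and replicate averaging.

Full-range field spectroradiometers stitch three detectors; at the
junction wavelengths the apparent reflectance steps discontinuously (the
"jump").  Jumps are corrected per instrument at its junction wavelengths
(1000 and 1800 nm, or 1000 and 1830 nm), then implausible spectra are
removed by their reflectance at 800 nm (kept iff within [0.35, 0.6]), and
only the 400-2400 nm window is retained for modelling.

Default pipeline order: jump correction -> replicate averaging -> outlier
filter -> trim; the order is configurable in :func:`preprocess_records`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .spectra import Spectrum, SpectralRecord, SpectrumError

#: Outlier rule: keep a spectrum iff lo <= r(band) <= hi.
OUTLIER_BAND_NM = 800
OUTLIER_RANGE = (0.35, 0.60)

#: Analysis window after trimming (inclusive ends).
TRIM_RANGE_NM = (400, 2400)

_MIN_SEGMENT = 5  # points needed on each side of a junction


class PreprocessError(ValueError):
    pass


def _extrapolate_linear(w: np.ndarray, r: np.ndarray, target_w: float) -> float:
    """Least-squares line through (w, r), evaluated at target_w."""
    slope, icept = np.polyfit(w.astype(float), r, 1)
    return float(slope * target_w + icept)


def correct_detector_jumps(
    spectrum: Spectrum,
    junctions: Sequence[int] | None = None,
    method: str = "additive",
) -> Spectrum:
    """Remove detector-splice steps at each junction wavelength.

    The segment beyond a junction is shifted so that its first point matches
    a linear extrapolation of the last ``5`` points of the preceding segment;
    junctions are processed left to right and the reference segment (below
    the first junction) is never altered.  ``method="additive"`` (default)
    shifts by an offset; ``method="multiplicative"`` rescales the segment by
    the ratio instead.  Correcting an already continuous spectrum is the
    identity to machine precision, and the operation is idempotent.
    """
    if junctions is None:
        junctions = spectrum.junction_wavelengths_nm
    if method not in {"additive", "multiplicative"}:
        raise ValueError(f"unknown method {method!r}")
    w = spectrum.wavelengths_nm
    r = spectrum.reflectance.copy()
    w0, w1 = int(w[0]), int(w[-1])
    for j in sorted(int(j) for j in junctions):
        if not (w0 < j < w1):
            raise PreprocessError(f"junction {j} nm not strictly inside domain [{w0}, {w1}]")
        idx = j - w0  # last index of the segment at/below the junction
        if idx + 1 < _MIN_SEGMENT or (len(r) - (idx + 1)) < _MIN_SEGMENT:
            raise PreprocessError(f"fewer than {_MIN_SEGMENT} points on one side of junction {j} nm")
        lo = idx + 1 - _MIN_SEGMENT
        predicted = _extrapolate_linear(w[lo : idx + 1], r[lo : idx + 1], float(w[idx + 1]))
        observed = r[idx + 1]
        if method == "additive":
            r[idx + 1 :] += predicted - observed
        else:
            if observed <= 0:
                raise PreprocessError(f"multiplicative correction undefined at junction {j} (r<=0)")
            r[idx + 1 :] *= predicted / observed
    return spectrum.with_reflectance(np.clip(r, 0.0, None))


def is_continuous_at(spectrum: Spectrum, junction_nm: int, window: int = 20, factor: float = 3.0) -> bool:
    """Continuity check used by the correction invariant: the step across the
    junction must not exceed ``factor`` times the median |delta r| over the
    ``window`` points below it."""
    w0 = int(spectrum.wavelengths_nm[0])
    idx = junction_nm - w0
    r = spectrum.reflectance
    below = r[max(0, idx - window) : idx + 1]
    tol = factor * float(np.median(np.abs(np.diff(below))))
    return abs(float(r[idx + 1] - r[idx])) <= max(tol, 1e-12)


@dataclass(frozen=True)
class RemovedRecord:
    record: SpectralRecord
    r800: float
    reason: str  # "below 0.35" / "above 0.6"


def filter_outliers(
    records: Iterable[SpectralRecord],
    band_nm: int = OUTLIER_BAND_NM,
    bounds: tuple[float, float] = OUTLIER_RANGE,
) -> tuple[list[SpectralRecord], list[RemovedRecord]]:
    """Apply the reflectance-at-800-nm plausibility rule.

    A record is kept iff ``lo <= r(band) <= hi`` (bounds inclusive: removal
    requires reflectance strictly lower than 0.35 or strictly higher than
    0.6).  Removed records are returned with the measured value and the
    violated bound, never silently dropped.
    """
    lo, hi = bounds
    kept: list[SpectralRecord] = []
    removed: list[RemovedRecord] = []
    for rec in records:
        if not rec.spectrum.covers(band_nm):
            raise PreprocessError(f"record {rec.record_id}: spectrum does not cover {band_nm} nm")
        r = rec.spectrum.value_at(band_nm)
        if r < lo:
            removed.append(RemovedRecord(rec, r, f"below {lo}"))
        elif r > hi:
            removed.append(RemovedRecord(rec, r, f"above {hi}"))
        else:
            kept.append(rec)
    return kept, removed


def trim_spectrum(spectrum: Spectrum, low_nm: int = TRIM_RANGE_NM[0], high_nm: int = TRIM_RANGE_NM[1]) -> Spectrum:
    """Restrict the spectrum to [low_nm, high_nm], inclusive both ends
    (400-2400 defaults give exactly 2001 wavelengths).  Idempotent."""
    w0, w1 = int(spectrum.wavelengths_nm[0]), int(spectrum.wavelengths_nm[-1])
    if low_nm < w0 or high_nm > w1 or low_nm >= high_nm:
        raise PreprocessError(f"trim range [{low_nm}, {high_nm}] outside spectrum domain [{w0}, {w1}]")
    i0, i1 = low_nm - w0, high_nm - w0
    return replace(
        spectrum,
        wavelengths_nm=spectrum.wavelengths_nm[i0 : i1 + 1],
        reflectance=spectrum.reflectance[i0 : i1 + 1],
    )


def average_replicates(records: Iterable[SpectralRecord]) -> list[SpectralRecord]:
    """Average repeated scans of one leaf: group by (genotype, experiment,
    repetition), take the pointwise mean, and mark ``leaf_replicate="mean"``.
    Groups must share a wavelength grid.  Group order follows first
    appearance; a singleton group keeps its values unchanged."""
    groups: dict[tuple, list[SpectralRecord]] = {}
    for rec in records:
        groups.setdefault((rec.genotype, rec.experiment, rec.repetition), []).append(rec)
    out: list[SpectralRecord] = []
    for key, members in groups.items():
        grid = members[0].spectrum.wavelengths_nm
        for m in members[1:]:
            if not np.array_equal(m.spectrum.wavelengths_nm, grid):
                raise PreprocessError(f"mixed wavelength grids within replicate group {key}")
        mean_r = np.mean([m.spectrum.reflectance for m in members], axis=0)
        out.append(replace(members[0], spectrum=members[0].spectrum.with_reflectance(mean_r), leaf_replicate="mean"))
    return out


def preprocess_records(
    records: Sequence[SpectralRecord],
    junctions: Sequence[int] | None = None,
    jump_method: str = "additive",
    average: bool = True,
    outlier_bounds: tuple[float, float] = OUTLIER_RANGE,
    trim: tuple[int, int] = TRIM_RANGE_NM,
    order: Sequence[str] = ("jumps", "average", "filter", "trim"),
) -> tuple[list[SpectralRecord], list[RemovedRecord]]:
    """Run the full pre-treatment in the given stage order; returns the kept
    records and the audit list of removed ones."""
    recs = list(records)
    removed: list[RemovedRecord] = []
    for stage in order:
        if stage == "jumps":
            recs = [
                replace(r, spectrum=correct_detector_jumps(r.spectrum, junctions, jump_method))
                for r in recs
            ]
        elif stage == "average":
            if average:
                recs = average_replicates(recs)
        elif stage == "filter":
            recs, rem = filter_outliers(recs, bounds=outlier_bounds)
            removed.extend(rem)
        elif stage == "trim":
            recs = [replace(r, spectrum=trim_spectrum(r.spectrum, *trim)) for r in recs]
        else:
            raise ValueError(f"unknown preprocessing stage {stage!r}")
    return recs, removed
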