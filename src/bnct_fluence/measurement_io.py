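"""Reading and writing per-target neutron-flux measurement series.

Measurement campaigns record, for each Li target lot, the cumulative proton
charge delivered before each activation-foil measurement and the measured
saturated-activity flux (Bq/mA/atom), optionally with a relative
measurement uncertainty.  Files are plain comma-delimited UTF-8 text with a
header; fluxes are written with 6 significant digits, which preserves the
~1e-15 Bq/mA/atom scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "FluxMeasurement",
    "MeasurementSeries",
    "SeriesValidationWarning",
    "ParseError",
    "MAX_INCREMENT_MC",
    "FULL_SERIES_MIN_POINTS",
    "read_series",
    "write_series",
    "write_results",
    "read_results",
]

#: Protocol bound on the charge accumulated between consecutive measurements.
MAX_INCREMENT_MC = 86.4e3

#: A full lifetime campaign comprises more than this many measurements.
FULL_SERIES_MIN_POINTS = 55

_SERIES_COLUMNS = [
    "target_id",
    "cumulative_charge_mC",
    "flux_Bq_per_mA_per_atom",
    "rel_uncertainty",
]

_RESULT_COLUMNS = [
    "target_id",
    "treatment_index",
    "d_mC",
    "required_charge_mC",
    "method",
    "delivered_fluence",
    "discrepancy_percent",
]


class SeriesValidationWarning(UserWarning):
    """Protocol deviation in a measurement series (warn, don't fail)."""


class ParseError(ValueError):
    """Malformed measurement file; message names the offending row."""


@dataclass(frozen=True)
class FluxMeasurement:
    """One activation-foil flux measurement on a Li target."""

    cumulative_charge: float  # mC delivered before this measurement
    flux: float  # Bq/mA/atom
    rel_uncertainty: Optional[float] = None  # dimensionless fraction

    def __post_init__(self) -> None:
        if self.cumulative_charge < 0:
            raise ValueError("cumulative_charge must be >= 0")
        if not self.flux > 0:
            raise ValueError("flux must be > 0")
        if self.rel_uncertainty is not None and not (0 < self.rel_uncertainty < 1):
            raise ValueError("rel_uncertainty must lie in (0, 1)")


@dataclass(frozen=True)
class MeasurementSeries:
    """Ordered flux measurements for one Li target lot.

    Charges must be strictly increasing.  The measurement protocol expects
    consecutive charge increments below ``MAX_INCREMENT_MC`` and more than
    ``FULL_SERIES_MIN_POINTS`` points for a full lifetime campaign; both are
    warnings, not errors, so partial (pre-treatment) series remain valid.
    """

    target_id: str
    measurements: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        charges = [p.cumulative_charge for p in self.measurements]
        for i in range(1, len(charges)):
            if charges[i] <= charges[i - 1]:
                raise ValueError(
                    f"target {self.target_id!r}: cumulative charge not strictly "
                    f"increasing at index {i} ({charges[i - 1]} -> {charges[i]})"
                )

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def prefix(self, n: int) -> "MeasurementSeries":
        """The first ``n`` measurements, as available before a treatment."""
        return MeasurementSeries(self.target_id, self.measurements[:n])

    def check_protocol(self) -> list[str]:
        """Return (and warn about) protocol deviations in this series."""
        issues = []
        charges = [p.cumulative_charge for p in self.measurements]
        for i in range(1, len(charges)):
            inc = charges[i] - charges[i - 1]
            if inc >= MAX_INCREMENT_MC:
                issues.append(
                    f"target {self.target_id!r}: increment {inc:.6g} mC at index "
                    f"{i} is not below {MAX_INCREMENT_MC:.6g} mC"
                )
        if len(charges) <= FULL_SERIES_MIN_POINTS:
            issues.append(
                f"target {self.target_id!r}: {len(charges)} points; a full "
                f"lifetime series has more than {FULL_SERIES_MIN_POINTS}"
            )
        for msg in issues:
            warnings.warn(msg, SeriesValidationWarning, stacklevel=2)
        return issues


def read_series(path: Union[str, Path]) -> list[MeasurementSeries]:
    """Read a measurement CSV into one series per distinct target.

    Expects columns ``target_id, cumulative_charge_mC,
    flux_Bq_per_mA_per_atom[, rel_uncertainty]``.  Rows for each target must
    appear with strictly increasing charge; duplicate or decreasing charges
    are a :class:`ParseError` naming the row.  Protocol deviations (large
    increments, short series) are warned about, not fatal.
    """
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
        raise ParseError(f"{path}: {exc}") from exc

    missing = [c for c in _SERIES_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_unc = "rel_uncertainty" in frame.columns

    for col in _SERIES_COLUMNS[1:3] + (["rel_uncertainty"] if has_unc else []):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value {frame.loc[bad[0], col]!r} in "
                f"column {col!r} at data row {bad[0] + 1}"
            )
        frame[col] = coerced

    out: list[MeasurementSeries] = []
    for target_id, group in frame.groupby("target_id", sort=False):
        charges = group["cumulative_charge_mC"].to_numpy()
        for j in range(1, len(charges)):
            if charges[j] <= charges[j - 1]:
                row = group.index[j] + 1
                kind = "duplicate" if charges[j] == charges[j - 1] else "decreasing"
                raise ParseError(
                    f"{path}: {kind} cumulative charge for target "
                    f"{target_id!r} at data row {row}"
                )
        points = []
        for _, rec in group.iterrows():
            unc = rec["rel_uncertainty"] if has_unc else None
            if unc is not None and pd.isna(unc):
                unc = None
            points.append(
                FluxMeasurement(
                    cumulative_charge=float(rec["cumulative_charge_mC"]),
                    flux=float(rec["flux_Bq_per_mA_per_atom"]),
                    rel_uncertainty=float(unc) if unc is not None else None,
                )
            )
        series = MeasurementSeries(str(target_id), points)
        series.check_protocol()
        out.append(series)
    return out


def _series_frame(series_list: Iterable[MeasurementSeries]) -> pd.DataFrame:
    rows = []
    for series in series_list:
        for p in series.measurements:
            rows.append(
                {
                    "target_id": series.target_id,
                    "cumulative_charge_mC": p.cumulative_charge,
                    "flux_Bq_per_mA_per_atom": p.flux,
                    "rel_uncertainty": p.rel_uncertainty,
                }
            )
    return pd.DataFrame(rows, columns=_SERIES_COLUMNS)


def write_series(
    series_list: Sequence[MeasurementSeries], path: Union[str, Path]
) -> None:
    """Write measurement series to the CSV layout read by :func:`read_series`."""
    frame = _series_frame(series_list)
    frame.to_csv(path, index=False, float_format="%.6g")


def write_results(results, path: Union[str, Path]) -> None:
    """Write compensation results to CSV.

    ``results`` is a non-empty iterable of objects with the fields of
    ``CompensationResult`` plus ``target_id`` and ``treatment_index``
    attributes (see :mod:`bnct_fluence.validation`).  Values are written
    with full repr precision so that read-back reproduces them exactly.
    """
    rows = [
        {
            "target_id": r.target_id,
            "treatment_index": r.treatment_index,
            "d_mC": repr(r.d),
            "required_charge_mC": repr(r.required_charge),
            "method": r.method,
            "delivered_fluence": repr(r.delivered_fluence),
            "discrepancy_percent": repr(r.discrepancy_percent),
        }
        for r in results
    ]
    if not rows:
        raise ValueError("results table is empty")
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame with numeric columns."""
    frame = pd.read_csv(path)
    missing = [c for c in _RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing result columns {missing}")
    return frame
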