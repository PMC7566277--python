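"""Stoichiometric nitrogen mass balance and the N2/npNO3- performance index.

In an autotrophic nitrogen-removal reactor fed ammonium only, the
nitrogen missing from the effluent is attributed to anammox-derived N2
gas.  Measured nitrate is split by stoichiometry into an anammox
by-product pool (apNO3-: 0.26 mol NO3- per 1.02 mol N2) and a
nitrification-derived pool (npNO3-).  The ratio N2-N / npNO3--N is the
system-performance index: high when ammonium leaves as gas, low when it
accumulates as nitrate.  Biomass assimilation and heterotrophic
denitrification are ignored in the balance (autotrophs grow very slowly
and no organic carbon is fed).

All balances are computed on a rate basis (mg N/day = concentration x
flow); the index is dimensionless so concentration inputs at constant
flow give identical ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import NO3_PER_N2_MOL, _N2_N

__all__ = [
    "ChemRecord",
    "NitrogenPartition",
    "AP_NO3_PER_N2",
    "partition_nitrogen",
    "partition_series",
    "moving_average",
    "chem_series_from_concentrations",
]

#: apNO3--N produced per N2-N produced (0.26 mol NO3- per 1.02 mol N2;
#: on a nitrogen-mass basis mol-N ratios equal mass-N ratios)
AP_NO3_PER_N2 = NO3_PER_N2_MOL / _N2_N

#: below this nitrification-derived nitrate rate (mg N/day) the index is
#: reported as missing rather than divided through
RATIO_GUARD = 1e-9

#: tolerated negative inferred N2 (fraction of influent load) before a
#: measurement-noise warning is attached
NEGATIVE_DEFICIT_TOL = 0.02


@dataclass(frozen=True)
class ChemRecord:
    """One day of reactor nitrogen chemistry, on a mg N/day rate basis."""

    day: float
    influent_nh4: float
    effluent_nh4: float
    effluent_no2: float
    effluent_no3: float
    temperature: float = float("nan")
    ph: float = float("nan")
    do: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("influent_nh4", "effluent_nh4", "effluent_no2",
                     "effluent_no3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class NitrogenPartition:
    """Inferred N2 and the nitrate origin split for one record.

    ``ratio`` is NaN when npNO3- is (numerically) zero; ``noisy_deficit``
    flags records whose raw nitrogen deficit was negative beyond the
    measurement-noise tolerance before flooring.
    """

    day: float
    n2: float
    ap_no3: float
    np_no3: float
    ratio: float
    noisy_deficit: bool = False


def partition_nitrogen(record: ChemRecord) -> NitrogenPartition:
    """Infer N2 from the nitrogen deficit and split nitrate by origin.

    n2 = influent NH4-N - (effluent NH4-N + NO2-N + NO3-N), floored at 0;
    apNO3- = n2 * 0.26/2.04; npNO3- = effluent NO3-N - apNO3-;
    ratio = n2 / npNO3- (missing when npNO3- <= 0).
    """
    raw_deficit = record.influent_nh4 - (
        record.effluent_nh4 + record.effluent_no2 + record.effluent_no3)
    noisy = False
    if raw_deficit < 0:
        tol = NEGATIVE_DEFICIT_TOL * max(record.influent_nh4, 1.0)
        if -raw_deficit > tol:
            noisy = True
            warnings.warn(
                f"day {record.day}: effluent nitrogen exceeds influent by "
                f"{-raw_deficit:.3g} mg N/day (measurement noise); "
                "inferred N2 floored at 0", stacklevel=2)
    n2 = max(raw_deficit, 0.0)
    ap_no3 = n2 * AP_NO3_PER_N2
    # np_no3 may come out <= 0 when measured nitrate is below the
    # stoichiometrically attributable by-product; the ratio is then
    # reported missing rather than divided through
    np_no3 = record.effluent_no3 - ap_no3
    ratio = n2 / np_no3 if np_no3 > RATIO_GUARD else float("nan")
    return NitrogenPartition(day=record.day, n2=n2, ap_no3=ap_no3,
                             np_no3=np_no3, ratio=ratio, noisy_deficit=noisy)


def chem_series_from_concentrations(
    chem: pd.DataFrame, flow: float
) -> list[ChemRecord]:
    """Convert a chemistry table (effluent concentrations in mg N/L, as
    written by the simulator) into rate-basis ChemRecords using the flow
    (L/day)."""
    if flow <= 0:
        raise ValueError("flow must be > 0")
    records = []
    for row in chem.itertuples(index=False):
        records.append(ChemRecord(
            day=float(row.day),
            influent_nh4=float(row.nh4_in_mgN_d),
            effluent_nh4=float(row.nh4_out_mgN_L) * flow,
            effluent_no2=float(row.no2_out_mgN_L) * flow,
            effluent_no3=float(row.no3_out_mgN_L) * flow,
            temperature=float(getattr(row, "temp_C", float("nan"))),
            ph=float(getattr(row, "ph", float("nan"))),
            do=float(getattr(row, "do_mgO2_L", float("nan"))),
        ))
    return records


def partition_series(
    records: list[ChemRecord], smoothing_window: float | None = 6.25
) -> pd.DataFrame:
    """Partition every record; optionally add an HRT-window smoothed ratio.

    Returns a DataFrame with columns day, n2, ap_no3, np_no3, ratio and
    (if smoothing requested) ratio_smoothed.
    """
    parts = [partition_nitrogen(r) for r in records]
    df = pd.DataFrame({
        "day": [p.day for p in parts],
        "n2": [p.n2 for p in parts],
        "ap_no3": [p.ap_no3 for p in parts],
        "np_no3": [p.np_no3 for p in parts],
        "ratio": [p.ratio for p in parts],
    })
    if smoothing_window is not None:
        smoothed = moving_average(
            list(zip(df["day"], df["ratio"])), smoothing_window)
        df["ratio_smoothed"] = [v for _, v in smoothed]
    return df


def moving_average(
    series: list[tuple[float, float]], window: float
) -> list[tuple[float, float]]:
    """Centered moving average over a +/- window/2 day neighbourhood.

    The default pipeline window is the hydraulic retention time (6.25
    days), so the smoothed index reflects reactor-turnover-scale trends.
    Missing (NaN) values are excluded from each mean; output has the same
    length and days as the input.
    """
    if not series:
        raise ValueError("empty series")
    if window <= 0:
        raise ValueError("window must be > 0")
    days = np.asarray([d for d, _ in series], dtype=float)
    vals = np.asarray([v for _, v in series], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    half = window / 2.0
    out = []
    for d in days:
        mask = (np.abs(days - d) <= half) & np.isfinite(vals)
        out.append(float(np.mean(vals[mask])) if mask.any() else float("nan"))
    return list(zip(days.tolist(), out))
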