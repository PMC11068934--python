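"""Closed-form metrics derived from cellular assays.

Two quantities back the functional follow-up of predicted key drivers:

* **Doubling time** from a proliferation assay,
  ``Td = (T2 - T1) * ln(2) / ln(N2 / N1)`` for cell counts ``N1 -> N2``
  over the interval ``T1 -> T2`` during exponential growth.

* **Mitochondrial phenotypes** from a Seahorse mitochondrial stress test:
  a 12-timepoint oxygen-consumption-rate (OCR) trace is averaged into four
  condition means — A (basal, timepoints 1-3), B (oligomycin, 4-6),
  C (FCCP, 7-9), D (rotenone/antimycin A, 10-12) — and the derived
  respiration quantities are plain differences: non-mitochondrial = D,
  basal = A-D, ATP-linked = A-B, proton leak = B-D, maximal capacity =
  C-D, reserve capacity = C-A.  The identity basal = ATP-linked +
  proton leak holds by construction.

OCR values are expected pre-normalized per well (e.g. by Hoechst cell
count).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GrowthObservation",
    "OcrTrace",
    "MitoPhenotypes",
    "doubling_time",
    "seahorse_phenotypes",
    "seahorse_from_table",
]

#: Seahorse condition -> its three technical-replicate timepoints
CONDITION_TIMEPOINTS = {
    "A": (1, 2, 3),   # basal
    "B": (4, 5, 6),   # oligomycin
    "C": (7, 8, 9),   # FCCP
    "D": (10, 11, 12),  # rotenone / antimycin A
}


@dataclass(frozen=True)
class GrowthObservation:
    """Two cell counts bracketing an exponential-growth interval (times in days)."""

    t1: float
    t2: float
    n1: float
    n2: float

    def __post_init__(self) -> None:
        if self.t2 <= self.t1:
            raise ValueError("t2 must be greater than t1")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("cell counts must be positive")


@dataclass(frozen=True)
class OcrTrace:
    """Twelve-timepoint oxygen-consumption trace for one well/replicate."""

    ocr: dict[int, float]

    def __post_init__(self) -> None:
        missing = [t for t in range(1, 13) if t not in self.ocr]
        if missing:
            raise ValueError(f"missing OCR timepoints: {missing}")
        bad = [t for t, v in self.ocr.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite OCR values at timepoints: {bad}")

    def condition_mean(self, condition: str) -> float:
        return sum(self.ocr[t] for t in CONDITION_TIMEPOINTS[condition]) / 3.0


@dataclass(frozen=True)
class MitoPhenotypes:
    """Derived respiration quantities (OCR units)."""

    non_mito: float
    basal: float
    atp_linked: float
    proton_leak: float
    max_capacity: float
    reserve_capacity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "non_mito": self.non_mito,
            "basal": self.basal,
            "atp_linked": self.atp_linked,
            "proton_leak": self.proton_leak,
            "max_capacity": self.max_capacity,
            "reserve_capacity": self.reserve_capacity,
        }


def doubling_time(obs: GrowthObservation) -> float:
    """Population doubling time in days: ``(T2-T1) * ln(2) / ln(N2/N1)``.

    Raises on zero growth (``N2 == N1``); a shrinking population returns a
    negative doubling time with a warning.
    """
    if obs.n2 == obs.n1:
        raise ZeroDivisionError("N2 == N1: zero growth, doubling time undefined")
    td = (obs.t2 - obs.t1) * math.log(2.0) / math.log(obs.n2 / obs.n1)
    if obs.n2 < obs.n1:
        warnings.warn(
            "population shrank over the interval; returning negative doubling time",
            stacklevel=2,
        )
    return td


def seahorse_phenotypes(trace: OcrTrace) -> MitoPhenotypes:
    """Condition means A-D and the six derived respiration quantities."""
    a = trace.condition_mean("A")
    b = trace.condition_mean("B")
    c = trace.condition_mean("C")
    d = trace.condition_mean("D")
    return MitoPhenotypes(
        non_mito=d,
        basal=a - d,
        atp_linked=a - b,
        proton_leak=b - d,
        max_capacity=c - d,
        reserve_capacity=c - a,
    )


def seahorse_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well phenotypes from a tidy assay table.

    Expects columns ``well``, ``timepoint`` (1..12), ``value`` and an
    optional ``group``; returns one row per well with the six phenotypes
    (plus the group label when present).
    """
    required = {"well", "timepoint", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    rows = []
    for well, sub in table.groupby("well", sort=True):
        trace = OcrTrace(
            ocr={int(t): float(v) for t, v in zip(sub["timepoint"], sub["value"])}
        )
        record = {"well": well, **seahorse_phenotypes(trace).as_dict()}
        if "group" in sub.columns:
            record["group"] = sub["group"].iloc[0]
        rows.append(record)
    return pd.DataFrame(rows).set_index("well")
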