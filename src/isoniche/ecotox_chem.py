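"""Toxic-unit scoring of pesticide residues and water-chemistry summaries.

The toxic pressure of a water sample under concentration addition is

    TU_sum = log10 Σᵢ Cᵢ / Eᵢ

with Cᵢ the measured concentration of pesticide i (µg/L) and Eᵢ the
acute endpoint (EC50 or LC50, µg/L) of the most sensitive standard test
organism of the relevant class — *Daphnia magna* 48-h EC50 or
*Chironomus* sp. 96-h LC50 for invertebrates, 72-h algal EC50 for
algae.  Detections below the limit of quantification (LOQ) enter at
half the LOQ.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class OrganismClass(str, enum.Enum):
    invertebrate = "invertebrate"
    algae = "algae"


@dataclass(frozen=True)
class PesticideMeasurement:
    """One substance in one water sample.

    ``conc`` is the quantified concentration (µg/L); for a detection
    below the LOQ set ``below_loq=True`` and leave ``conc`` at the
    measured (unreliable) value or 0 — the half-LOQ substitution is
    applied during scoring.  ``detected`` covers sub-LOQ detections.
    """

    substance: str
    conc: float
    loq: float
    detected: bool = True
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.loq <= 0:
            raise ValueError(f"{self.substance}: LOQ must be positive")
        if self.conc < 0:
            raise ValueError(f"{self.substance}: concentration must be >= 0")

    @property
    def effective_conc(self) -> float:
        """Concentration entering the TU sum (half LOQ when sub-LOQ)."""
        if not self.detected:
            return 0.0
        return self.loq / 2.0 if self.below_loq else self.conc


@dataclass(frozen=True)
class ToxEndpoint:
    """Acute toxicity endpoint for one substance and organism class."""

    substance: str
    organism_class: OrganismClass
    endpoint: float
    basis: str = ""

    def __post_init__(self) -> None:
        if self.endpoint <= 0:
            raise ValueError(f"{self.substance}: endpoint must be positive")


@dataclass
class WaterChemistry:
    """Per-site environmental chemistry snapshot (Table-style row).

    Nutrients in mg/L, temperature in °C, conductivity in µS/cm.  PO₄³⁻
    and NO₂⁻ are carried for completeness but do not enter the nutrient
    sum, which is NH₄⁺ + NO₃⁻.
    """

    site_id: str
    temp: float
    ec: float
    ph: float
    o2: float
    nh4: float
    no3: float
    no2: float = 0.0
    po4: float = 0.0
    pesticides: list[PesticideMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("nh4", "no3", "no2", "po4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.site_id}: {name} must be >= 0")

    @property
    def nutrient_sum(self) -> float:
        return self.nh4 + self.no3

    @property
    def n_detections(self) -> int:
        return sum(1 for m in self.pesticides if m.detected)


class MissingEndpointError(KeyError):
    pass


def _best_endpoints(
    endpoints: Iterable[ToxEndpoint], organism_class: OrganismClass
) -> dict[str, float]:
    # most sensitive = minimum endpoint per substance within the class
    best: dict[str, float] = {}
    for e in endpoints:
        if e.organism_class is organism_class:
            cur = best.get(e.substance)
            if cur is None or e.endpoint < cur:
                best[e.substance] = e.endpoint
    return best


def tu_sum(
    measurements: Sequence[PesticideMeasurement],
    endpoints: Iterable[ToxEndpoint],
    organism_class: OrganismClass,
) -> float | None:
    """log₁₀ sum of toxic units for one water sample.

    Returns ``None`` (no toxic pressure) when nothing was detected —
    log of zero is undefined and a sentinel is more honest than −∞.
    Raises :class:`MissingEndpointError` naming the substance if a
    detected substance lacks an endpoint for the organism class.
    """
    best = _best_endpoints(endpoints, organism_class)
    total = 0.0
    any_detected = False
    for m in measurements:
        if not m.detected:
            continue
        any_detected = True
        if m.substance not in best:
            raise MissingEndpointError(
                f"no {organism_class.value} endpoint for substance {m.substance!r}"
            )
        total += m.effective_conc / best[m.substance]
    if not any_detected or total == 0.0:
        return None
    return math.log10(total)


def water_summaries(
    chem: Sequence[WaterChemistry],
    type_map: Mapping[str, str],
    endpoints: Iterable[ToxEndpoint] = (),
) -> pd.DataFrame:
    """Per-type means and sample SDs of detection counts and nutrient sums.

    ``type_map`` maps site_id to its water-body type.  SDs use the n−1
    denominator and are reported as missing for a single-site type.
    The per-site table (one row per site, with the NH₄⁺+NO₃⁻ column
    and optional TU sums) is available via :func:`site_table`.
    """
    per_site = site_table(chem, type_map, endpoints)
    return summaries_from_site_table(per_site)


def summaries_from_site_table(per_site: pd.DataFrame) -> pd.DataFrame:
    """Per-type mean/SD of detection counts and nutrient sums from a
    per-site frame with columns wb_type, n_detections, nutrient_sum."""
    rows = []
    for t, grp in per_site.groupby("wb_type", sort=True):
        for var in ("n_detections", "nutrient_sum"):
            vals = grp[var].astype(float)
            rows.append(
                {
                    "wb_type": t,
                    "variable": var,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n_sites": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def site_table(
    chem: Sequence[WaterChemistry],
    type_map: Mapping[str, str],
    endpoints: Iterable[ToxEndpoint] = (),
) -> pd.DataFrame:
    """One row per site: chemistry, nutrient sum, detections, TU sums."""
    endpoints = list(endpoints)
    rows = []
    for c in chem:
        row = {
            "site_id": c.site_id,
            "wb_type": str(type_map[c.site_id]),
            "temp": c.temp,
            "ec": c.ec,
            "ph": c.ph,
            "o2": c.o2,
            "nh4": c.nh4,
            "no3": c.no3,
            "po4": c.po4,
            "nutrient_sum": c.nutrient_sum,
            "n_detections": c.n_detections,
        }
        if endpoints:
            for oc in OrganismClass:
                tu = tu_sum(c.pesticides, endpoints, oc)
                row[f"tu_sum_{oc.value}"] = np.nan if tu is None else tu
        rows.append(row)
    return pd.DataFrame(rows)


def read_pesticide_table(frame: pd.DataFrame) -> dict[str, list[PesticideMeasurement]]:
    """Parse a long pesticide CSV (site, substance, conc, loq, detected,
    below_loq) into per-site measurement lists."""
    out: dict[str, list[PesticideMeasurement]] = {}
    for r in frame.itertuples(index=False):
        out.setdefault(str(r.site_id), []).append(
            PesticideMeasurement(
                substance=str(r.substance),
                conc=float(r.conc),
                loq=float(r.loq),
                detected=bool(r.detected),
                below_loq=bool(getattr(r, "below_loq", False)),
            )
        )
    return out


def read_endpoint_table(frame: pd.DataFrame) -> list[ToxEndpoint]:
    """Parse an endpoint CSV (substance, organism_class, endpoint, basis)."""
    return [
        ToxEndpoint(
            substance=str(r.substance),
            organism_class=OrganismClass(r.organism_class),
            endpoint=float(r.endpoint),
            basis=str(getattr(r, "basis", "")),
        )
        for r in frame.itertuples(index=False)
    ]
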