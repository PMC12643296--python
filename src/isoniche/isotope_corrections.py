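"""δ-notation conversion and mean-offset signal corrections.

Two field signals overlay the trophic structure of the study systems and
are removed by pure translations before niche comparison:

* organic fertilizer enriches δ¹⁵N in ditches relative to ponds, so the
  difference of pooled consumer means is subtracted from ditch δ¹⁵N;
* maize (a C4 plant) enriches δ¹³C of consumers in ponds bordering maize
  fields, so the difference of pooled consumer means between maize ponds
  and the remaining ponds is subtracted from the maize ponds' δ¹³C.

Both corrections shift every sample of the target stratum by the same
constant, preserving within-group variances and all pairwise geometry.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from isoniche.core_data import SampleTable, WaterBodyType


class CorrectionAxis(str, enum.Enum):
    d15N = "d15N"
    d13C = "d13C"


@dataclass(frozen=True)
class CorrectionReport:
    """Record of one mean-offset correction.

    ``offset_applied = target_mean - reference_mean`` is subtracted from
    the target stratum, aligning pooled means.
    """

    axis: CorrectionAxis
    target_sites: frozenset[str]
    reference_mean: float
    target_mean: float
    offset_applied: float

    def to_json_dict(self) -> dict:
        return {
            "axis": self.axis.value,
            "target_sites": sorted(self.target_sites),
            "reference_mean": self.reference_mean,
            "target_mean": self.target_mean,
            "offset_applied": self.offset_applied,
        }


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """δ value (‰) from a raw isotope ratio and a reference ratio.

    δX = (R_sample / R_standard − 1) × 10³ with R the ¹³C/¹²C or
    ¹⁵N/¹⁴N ratio and the standard VPDB (carbon) or atmospheric air
    (nitrogen).
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be strictly positive")
    return (r_sample / r_standard - 1.0) * 1e3


def correct_d15N_fertilizer(table: SampleTable) -> tuple[SampleTable, CorrectionReport]:
    """Remove the fertilizer δ¹⁵N enrichment from ditch consumers.

    The pooled consumer mean δ¹⁵N is computed per water-body type
    (unweighted over analyzed samples); the ditch-minus-pond difference
    is subtracted from every ditch sample's δ¹⁵N.  Pond rows and the
    δ¹³C axis are untouched.  After the correction the pooled per-type
    means coincide exactly (up to floating tolerance).
    """
    ditch = [s.d15N for s in table if s.wb_type is WaterBodyType.ditch]
    pond = [s.d15N for s in table if s.wb_type is WaterBodyType.pond]
    if not ditch or not pond:
        raise ValueError("both water-body types are required for the d15N correction")
    target_mean = float(np.mean(ditch))
    reference_mean = float(np.mean(pond))
    offset = target_mean - reference_mean
    _warn_if_already_applied(table, "d15N fertilizer correction")
    corrected = [
        replace(s, d15N=s.d15N - offset) if s.wb_type is WaterBodyType.ditch else s
        for s in table
    ]
    report = CorrectionReport(
        axis=CorrectionAxis.d15N,
        target_sites=frozenset(table.sites(WaterBodyType.ditch)),
        reference_mean=reference_mean,
        target_mean=target_mean,
        offset_applied=offset,
    )
    out = SampleTable(
        corrected,
        [*table.provenance, f"d15N fertilizer correction: offset {offset:+.4f} permil"],
    )
    return out, report


def correct_d13C_maize(
    table: SampleTable, maize_sites: Iterable[str]
) -> tuple[SampleTable, CorrectionReport]:
    """Remove the maize (C4) δ¹³C enrichment from selected pond sites.

    The reference mean is pooled over consumers of all *other* pond
    sites; the maize-minus-reference difference is subtracted from δ¹³C
    of samples in ``maize_sites`` only.
    """
    maize = frozenset(str(s) for s in maize_sites)
    if not maize:
        raise ValueError("maize_sites must be non-empty")
    site_types = table.site_types
    unknown = maize - set(site_types)
    if unknown:
        raise ValueError(f"maize_sites not in table: {sorted(unknown)}")
    non_pond = [s for s in maize if site_types[s] is not WaterBodyType.pond]
    if non_pond:
        raise ValueError(f"maize_sites must be ponds, got: {sorted(non_pond)}")
    ref_ponds = [
        s for s, t in site_types.items() if t is WaterBodyType.pond and s not in maize
    ]
    if not ref_ponds:
        raise ValueError("maize_sites cover every pond; no reference ponds remain")

    target_vals = [s.d13C for s in table if s.site_id in maize]
    ref_vals = [s.d13C for s in table if s.site_id in set(ref_ponds)]
    target_mean = float(np.mean(target_vals))
    reference_mean = float(np.mean(ref_vals))
    offset = target_mean - reference_mean
    _warn_if_already_applied(table, "d13C maize correction")
    corrected = [
        replace(s, d13C=s.d13C - offset) if s.site_id in maize else s for s in table
    ]
    report = CorrectionReport(
        axis=CorrectionAxis.d13C,
        target_sites=maize,
        reference_mean=reference_mean,
        target_mean=target_mean,
        offset_applied=offset,
    )
    out = SampleTable(
        corrected,
        [*table.provenance, f"d13C maize correction: offset {offset:+.4f} permil"],
    )
    return out, report


def _warn_if_already_applied(table: SampleTable, label: str) -> None:
    # A second application is mechanically allowed but only a no-op when
    # the means already coincide; flag it.
    if any(label in note for note in table.provenance):
        warnings.warn(f"{label} applied more than once", stacklevel=3)
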