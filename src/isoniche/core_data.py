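"""Domain types, tabular I/O and the sample-count arithmetic.

The unit of accounting throughout is the *analyzed sample* (one tin
capsule, which may pool several small individuals of one family), keyed
by site, water-body type and functional feeding group (FFG).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class WaterBodyType(str, enum.Enum):
    """Type of agricultural small water body."""

    pond = "pond"
    ditch = "ditch"


class FFG(str, enum.Enum):
    """Functional feeding group of a benthic invertebrate."""

    collector_filterer = "collector_filterer"
    collector_gatherer = "collector_gatherer"
    grazer_scraper = "grazer_scraper"
    omnivore = "omnivore"
    predator = "predator"
    shredder = "shredder"


#: FFGs conventionally regarded as primary consumers (feeding on FPOM,
#: CPOM, biofilm or plant tissue rather than animal prey).
PRIMARY_CONSUMERS: frozenset[FFG] = frozenset(
    {
        FFG.collector_filterer,
        FFG.collector_gatherer,
        FFG.grazer_scraper,
        FFG.shredder,
    }
)

# Free-text FFG labels seen in field data files, normalized to the enum.
_FFG_SYNONYMS: dict[str, FFG] = {
    "collector_filterer": FFG.collector_filterer,
    "collector/filterer": FFG.collector_filterer,
    "collector-filterer": FFG.collector_filterer,
    "collectorfilterer": FFG.collector_filterer,
    "filterer": FFG.collector_filterer,
    "collector_gatherer": FFG.collector_gatherer,
    "collector/gatherer": FFG.collector_gatherer,
    "collector-gatherer": FFG.collector_gatherer,
    "collectorgatherer": FFG.collector_gatherer,
    "gatherer": FFG.collector_gatherer,
    "grazer_scraper": FFG.grazer_scraper,
    "grazer/scraper": FFG.grazer_scraper,
    "grazer-scraper": FFG.grazer_scraper,
    "grazerscraper": FFG.grazer_scraper,
    "grazer": FFG.grazer_scraper,
    "scraper": FFG.grazer_scraper,
    "omnivore": FFG.omnivore,
    "omnivorous": FFG.omnivore,
    "predator": FFG.predator,
    "shredder": FFG.shredder,
}

_WB_SYNONYMS: dict[str, WaterBodyType] = {
    "pond": WaterBodyType.pond,
    "ditch": WaterBodyType.ditch,
}

# Column-name synonyms, matched case-insensitively after stripping.
_COLUMN_SYNONYMS: dict[str, str] = {
    "sample_id": "sample_id",
    "sampleid": "sample_id",
    "id": "sample_id",
    "site_id": "site_id",
    "siteid": "site_id",
    "site": "site_id",
    "wb_type": "wb_type",
    "wbtype": "wb_type",
    "type": "wb_type",
    "water_body_type": "wb_type",
    "ffg": "ffg",
    "functional_feeding_group": "ffg",
    "taxon": "taxon",
    "taxa": "taxon",
    "d13c": "d13C",
    "δ13c": "d13C",
    "delta13c": "d13C",
    "d15n": "d15N",
    "δ15n": "d15N",
    "delta15n": "d15N",
}

REQUIRED_COLUMNS = ("sample_id", "site_id", "wb_type", "ffg", "d13C", "d15N")


class ValidationError(ValueError):
    """An input table violates a structural contract."""


def normalize_ffg(label: str) -> FFG:
    """Map a free-text FFG label onto one of the six categories.

    Unknown labels raise; guessing a feeding group would silently
    misclassify a sample.
    """
    key = str(label).strip().lower().replace(" ", "_")
    try:
        return _FFG_SYNONYMS[key]
    except KeyError:
        raise ValidationError(f"unknown functional feeding group label: {label!r}")


@dataclass(frozen=True)
class IsotopeSample:
    """One analyzed specimen or pooled capsule.

    δ values are per-mil: δ¹³C relative to VPDB, δ¹⁵N relative to
    atmospheric air.
    """

    sample_id: str
    site_id: str
    wb_type: WaterBodyType
    ffg: FFG
    d13C: float
    d15N: float
    taxon: str | None = None


@dataclass
class SampleTable:
    """Validated collection of isotope samples with provenance notes."""

    samples: list[IsotopeSample]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("sample table is empty after validation")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id values: {dupes[:5]}")
        by_site: dict[str, WaterBodyType] = {}
        for s in self.samples:
            prev = by_site.setdefault(s.site_id, s.wb_type)
            if prev is not s.wb_type:
                raise ValidationError(
                    f"site {s.site_id!r} appears with both water-body types"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def site_types(self) -> dict[str, WaterBodyType]:
        return {s.site_id: s.wb_type for s in self.samples}

    def sites(self, wb_type: WaterBodyType | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if wb_type is None or s.wb_type is wb_type:
                seen.setdefault(s.site_id)
        return list(seen)

    def with_provenance(self, note: str) -> "SampleTable":
        return SampleTable(list(self.samples), [*self.provenance, note])

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view (one row per analyzed sample)."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "site_id": [s.site_id for s in self.samples],
                "wb_type": [s.wb_type.value for s in self.samples],
                "ffg": [s.ffg.value for s in self.samples],
                "taxon": [s.taxon for s in self.samples],
                "d13C": [s.d13C for s in self.samples],
                "d15N": [s.d15N for s in self.samples],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CountsSummary:
    """Sample-count aggregation over sites, types and FFGs."""

    per_group: dict[tuple[str, FFG], int]
    per_type_ffg: dict[tuple[WaterBodyType, FFG], int]
    per_type_total: dict[WaterBodyType, int]
    per_type_mean_per_site: dict[WaterBodyType, float]
    ffg_set_means: dict[tuple[WaterBodyType, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site_id": site, "ffg": ffg.value, "n": n}
            for (site, ffg), n in sorted(self.per_group.items())
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "per_group": {f"{s}|{f.value}": n for (s, f), n in self.per_group.items()},
            "per_type_ffg": {
                f"{t.value}|{f.value}": n for (t, f), n in self.per_type_ffg.items()
            },
            "per_type_total": {t.value: n for t, n in self.per_type_total.items()},
            "per_type_mean_per_site": {
                t.value: m for t, m in self.per_type_mean_per_site.items()
            },
            "ffg_set_means": {
                f"{t.value}|{name}": m for (t, name), m in self.ffg_set_means.items()
            },
        }


def _canonical_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        key = str(col).strip().lower()
        if key in _COLUMN_SYNONYMS:
            mapping[col] = _COLUMN_SYNONYMS[key]
    return mapping


def read_isotope_table(
    path: str | Path, *, delimiter: str | None = None
) -> tuple[SampleTable, list[str]]:
    """Read a CSV/TSV isotope sample table.

    Column names are matched case-insensitively against a synonym map
    (``d15N`` / ``δ15N`` / ``delta15N`` all work).  Rows whose FFG label
    cannot be normalized or whose δ values are non-numeric are rejected
    with row-level diagnostics rather than failing the whole file.

    Returns
    -------
    (table, diagnostics)
        The validated table and a list of human-readable messages for
        every rejected row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    raw = raw.rename(columns=_canonical_columns(raw.columns))
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    if raw.empty:
        raise ValidationError(f"{path.name}: no data rows")

    samples: list[IsotopeSample] = []
    diagnostics: list[str] = []
    for idx, row in raw.iterrows():
        rowno = int(idx) + 2  # header is line 1
        try:
            ffg = normalize_ffg(row["ffg"])
            wb_key = str(row["wb_type"]).strip().lower()
            if wb_key not in _WB_SYNONYMS:
                raise ValidationError(f"unknown water-body type {row['wb_type']!r}")
            d13C = float(row["d13C"])
            d15N = float(row["d15N"])
            if not (pd.notna(d13C) and pd.notna(d15N)):
                raise ValidationError("non-finite delta value")
            taxon = row.get("taxon")
            taxon = None if pd.isna(taxon) else str(taxon)
            samples.append(
                IsotopeSample(
                    sample_id=str(row["sample_id"]),
                    site_id=str(row["site_id"]),
                    wb_type=_WB_SYNONYMS[wb_key],
                    ffg=ffg,
                    d13C=d13C,
                    d15N=d15N,
                    taxon=taxon,
                )
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append(f"row {rowno}: rejected ({exc})")
    if not samples:
        raise ValidationError(f"{path.name}: every row was rejected")
    table = SampleTable(samples, [f"read from {path.name}"])
    return table, diagnostics


def table_from_frame(frame: pd.DataFrame, provenance: str = "") -> SampleTable:
    """Build a SampleTable from an in-memory long-format DataFrame."""
    samples = [
        IsotopeSample(
            sample_id=str(r.sample_id),
            site_id=str(r.site_id),
            wb_type=WaterBodyType(r.wb_type),
            ffg=normalize_ffg(r.ffg),
            d13C=float(r.d13C),
            d15N=float(r.d15N),
            taxon=getattr(r, "taxon", None),
        )
        for r in frame.itertuples(index=False)
    ]
    return SampleTable(samples, [provenance] if provenance else [])


def summarize_counts(
    table: SampleTable,
    ffg_sets: Mapping[str, Iterable[FFG]] | None = None,
) -> CountsSummary:
    """Aggregate analyzed-sample counts.

    ``ffg_sets`` names subsets of FFGs whose pooled per-site mean is
    reported per water-body type; the default reports primary consumers
    (collector/filterer + collector/gatherer + grazer/scraper +
    shredder), omnivores and predators.  A subset mean is the subset's
    total sample count of a type divided by the number of sites of that
    type, so it is an average *per site*, not per FFG.
    """
    if ffg_sets is None:
        ffg_sets = {
            "primary_consumers": PRIMARY_CONSUMERS,
            "omnivores": {FFG.omnivore},
            "predators": {FFG.predator},
        }
    per_group: dict[tuple[str, FFG], int] = {}
    per_type_ffg: dict[tuple[WaterBodyType, FFG], int] = {}
    per_type_total: dict[WaterBodyType, int] = {}
    for s in table:
        per_group[(s.site_id, s.ffg)] = per_group.get((s.site_id, s.ffg), 0) + 1
        per_type_ffg[(s.wb_type, s.ffg)] = per_type_ffg.get((s.wb_type, s.ffg), 0) + 1
        per_type_total[s.wb_type] = per_type_total.get(s.wb_type, 0) + 1

    n_sites = {t: len(table.sites(t)) for t in per_type_total}
    per_type_mean = {t: per_type_total[t] / n_sites[t] for t in per_type_total}

    ffg_set_means: dict[tuple[WaterBodyType, str], float] = {}
    for t in per_type_total:
        for name, members in ffg_sets.items():
            total = sum(per_type_ffg.get((t, f), 0) for f in members)
            ffg_set_means[(t, name)] = total / n_sites[t]

    return CountsSummary(
        per_group=per_group,
        per_type_ffg=per_type_ffg,
        per_type_total=per_type_total,
        per_type_mean_per_site=per_type_mean,
        ffg_set_means=ffg_set_means,
    )


def filter_min_group_size(
    table: SampleTable,
    min_n: int,
    *,
    by: str = "site",
) -> tuple[SampleTable, list[tuple]]:
    """Drop groups with fewer than ``min_n`` analyzed samples.

    ``by='site'`` groups on (site × FFG); ``by='type'`` groups on
    (water-body type × FFG).  Returns the filtered table and the list of
    dropped group keys.  Idempotent: re-applying with the same ``min_n``
    is a no-op.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    if by not in {"site", "type"}:
        raise ValueError("by must be 'site' or 'type'")
    key = (
        (lambda s: (s.site_id, s.ffg)) if by == "site" else (lambda s: (s.wb_type, s.ffg))
    )
    counts: dict[tuple, int] = {}
    for s in table:
        counts[key(s)] = counts.get(key(s), 0) + 1
    dropped = sorted(k for k, n in counts.items() if n < min_n)
    kept = [s for s in table if key(s) not in set(dropped)]
    if not kept:
        raise ValidationError(
            f"min_n={min_n} removed every group ({len(dropped)} groups dropped)"
        )
    note = f"filter_min_group_size(min_n={min_n}, by={by}): dropped {len(dropped)} group(s)"
    return SampleTable(kept, [*table.provenance, note]), dropped


def _replace_sample(s: IsotopeSample, **kw) -> IsotopeSample:
    return replace(s, **kw)
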