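"""Domain types and field-protocol arithmetic for streamflow duration assessment.

This module holds the vocabulary of the method — streamflow duration classes,
reaches, visits, raw indicator records — together with the three pieces of
deterministic arithmetic that sit underneath everything else:

* truth-labeling a reach from a daily flow record (the 5% zero-flow /
  flowing-day rule),
* the assessment reach-length rule (40x mean bankfull width, clamped to
  40-200 m), and
* conversion of raw indicator records into the numeric metric table used for
  screening and modeling.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields
from datetime import date as _date
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StreamflowClass",
    "PredictedClass",
    "SUBREGIONS",
    "EVIDENCE_TIERS",
    "COVER_CATEGORIES",
    "Reach",
    "TaxonObservation",
    "IndicatorRecord",
    "Visit",
    "FlowRecord",
    "MetricMeta",
    "MetricTable",
    "classify_flow_record",
    "reach_length",
    "compute_metrics",
]


class StreamflowClass(str, enum.Enum):
    """True flow-duration class of a reach.

    Ordered by flow duration: Ephemeral < Intermittent < Perennial.
    Ephemeral reaches flow only in direct response to precipitation;
    intermittent reaches flow seasonally; perennial reaches flow year-round.
    """

    EPHEMERAL = "Ephemeral"
    INTERMITTENT = "Intermittent"
    PERENNIAL = "Perennial"

    @property
    def duration_rank(self) -> int:
        return _CLASS_RANK[self]

    def __lt__(self, other: "StreamflowClass") -> bool:  # type: ignore[override]
        if not isinstance(other, StreamflowClass):
            return NotImplemented
        return self.duration_rank < other.duration_rank


_CLASS_RANK = {
    StreamflowClass.EPHEMERAL: 0,
    StreamflowClass.INTERMITTENT: 1,
    StreamflowClass.PERENNIAL: 2,
}


class PredictedClass(str, enum.Enum):
    """Outcome of a classification, including the two hedged outcomes.

    ``AT_LEAST_INTERMITTENT`` asserts the reach is not ephemeral without
    resolving intermittent vs perennial; ``NEED_MORE_INFORMATION`` is the
    abstention outcome.
    """

    EPHEMERAL = "Ephemeral"
    INTERMITTENT = "Intermittent"
    PERENNIAL = "Perennial"
    AT_LEAST_INTERMITTENT = "At least intermittent"
    NEED_MORE_INFORMATION = "Need more information"

    @classmethod
    def from_true(cls, true_class: StreamflowClass) -> "PredictedClass":
        return cls(true_class.value)


SUBREGIONS = ("CA", "NV", "AZ", "NM_TX", "CO_WY_UT_MT")
EVIDENCE_TIERS = ("preferred", "usgs_gage", "acceptable")

#: Ordinal streambed-cover categories (algae, moss, liverworts) and their codes.
COVER_CATEGORIES = ("ND", "lt2", "2_10", "10_40", "ge40")
_COVER_CODE = {c: i for i, c in enumerate(COVER_CATEGORIES)}

#: Taxon group flags recognized on invertebrate observations.
TAXON_GROUPS = ("EPT", "mayfly", "perennial", "noninsect", "GOLD", "OCH")

#: Per-morphotaxon tally cap used in the field protocol.
MORPHOTAXON_CAP = 10


@dataclass(frozen=True)
class Reach:
    """A stream section with consistent hydrologic conditions; the assessment unit."""

    reach_id: str
    subregion: str
    true_class: StreamflowClass
    evidence_tier: str = "preferred"
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.subregion not in SUBREGIONS:
            raise ValueError(
                f"unknown subregion {self.subregion!r}; expected one of {SUBREGIONS}"
            )
        if self.evidence_tier not in EVIDENCE_TIERS:
            raise ValueError(
                f"unknown evidence tier {self.evidence_tier!r}; "
                f"expected one of {EVIDENCE_TIERS}"
            )


@dataclass(frozen=True)
class TaxonObservation:
    """One invertebrate morphotaxon record from a visit.

    ``count`` is the raw field tally; abundance metrics cap it at
    ``MORPHOTAXON_CAP`` individuals per morphotaxon. ``groups`` flags
    membership in indicator groups (EPT, mayfly, perennial-indicator,
    non-insect, GOLD, OCH). ``live`` is False for shell/case/exuvia-only
    evidence, which counts toward presence and richness but is tracked so
    live-only abundance metrics can exclude it.
    """

    taxon: str
    count: int
    groups: frozenset = frozenset()
    live: bool = True

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"taxon {self.taxon!r}: negative count {self.count}")
        unknown = set(self.groups) - set(TAXON_GROUPS)
        if unknown:
            raise ValueError(f"taxon {self.taxon!r}: unknown group flags {sorted(unknown)}")

    @property
    def capped_count(self) -> int:
        return min(self.count, MORPHOTAXON_CAP)


# Ordinal indicator scores measured per the New Mexico protocol, passed through
# as metrics under these column names.
_NM_SCORE_METRICS = {
    "sinuosity_score": "sinuosity_score",
    "entrenchment_score": "entrenchment_score",
    "substrate_sorting_score": "substratesorting_score",
    "riffle_pool_score": "riffpoolseq_score",
    "sediment_deposition_score": "seddeposition_score",
    "water_in_channel_score": "waterinchannel_score",
    "vegetation_difference_score": "vegdiff_score",
    "rooted_upland_plants_score": "rootedplants_score",
    "fish_abundance_score": "fishabund_score2",
    "invert_abundance_score": "bmiabund_score",
    "algal_abundance_score": "algabund_score",
    "amphibian_abundance_score": "amphabund_score",
}

#: Fields that must be present for a visit to enter analysis. Incomplete
#: visits are excluded (not imputed), with a logged reason.
MANDATORY_INDICATORS = (
    "hydrophyte_species_count",
    "invertebrates",
    "surface_flow_pct",
    "algal_cover_livedead",
)


@dataclass
class IndicatorRecord:
    """Raw per-visit field measurements. ``None`` marks a missing observation."""

    # counts
    hydrophyte_species_count: Optional[int] = None
    invertebrates: Optional[Sequence[TaxonObservation]] = None
    woody_jam_count: Optional[int] = None
    isolated_pool_count: Optional[int] = None
    # percents
    surface_flow_pct: Optional[float] = None
    subsurface_flow_pct: Optional[float] = None
    shading_readings: Optional[Sequence[float]] = None  # densiometer, [0, 100] each
    # ordinal NM scores (small-integer scales)
    sinuosity_score: Optional[int] = None
    entrenchment_score: Optional[int] = None
    substrate_sorting_score: Optional[int] = None
    riffle_pool_score: Optional[int] = None
    sediment_deposition_score: Optional[int] = None
    water_in_channel_score: Optional[int] = None
    vegetation_difference_score: Optional[int] = None
    rooted_upland_plants_score: Optional[int] = None
    fish_abundance_score: Optional[int] = None
    invert_abundance_score: Optional[int] = None
    algal_abundance_score: Optional[int] = None
    amphibian_abundance_score: Optional[int] = None
    soil_moisture_max_score: Optional[int] = None
    # ordinal cover categories
    algal_cover_live: Optional[str] = None
    algal_cover_livedead: Optional[str] = None
    moss_cover: Optional[str] = None
    liverwort_cover: Optional[str] = None
    # booleans
    hydric_soils: Optional[bool] = None
    seeps_springs: Optional[bool] = None
    iron_oxidizing: Optional[bool] = None
    fish_present: Optional[bool] = None
    mosquitofish_present: Optional[bool] = None
    amphibians_present: Optional[bool] = None
    snakes_present: Optional[bool] = None
    # geometry
    bankfull_widths: Optional[Sequence[float]] = None  # meters; protocol uses 3

    def validate(self) -> list:
        """Return a list of invariant-violation messages (empty if valid)."""
        problems = []
        for name in ("surface_flow_pct", "subsurface_flow_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                problems.append(f"{name}={v} outside [0, 100]")
        if self.shading_readings is not None:
            for r in self.shading_readings:
                if not 0.0 <= r <= 100.0:
                    problems.append(f"shading reading {r} outside [0, 100]")
        for name in ("hydrophyte_species_count", "woody_jam_count", "isolated_pool_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                problems.append(f"{name}={v} is negative")
        for name in ("algal_cover_live", "algal_cover_livedead", "moss_cover", "liverwort_cover"):
            v = getattr(self, name)
            if v is not None and v not in COVER_CATEGORIES:
                problems.append(f"{name}={v!r} not one of {COVER_CATEGORIES}")
        if self.bankfull_widths is not None:
            for w in self.bankfull_widths:
                if w <= 0:
                    problems.append(f"non-positive bankfull width {w}")
        return problems

    def missing_mandatory(self) -> list:
        return [n for n in MANDATORY_INDICATORS if getattr(self, n) is None]


@dataclass
class Visit:
    """One field visit to a reach. Visit 1 is the initial visit."""

    reach_id: str
    visit_index: int
    date: Optional[_date] = None
    indicators: Optional[IndicatorRecord] = None
    flow_state: Optional[str] = None  # "dry" | "flowing"; derived if None

    def __post_init__(self) -> None:
        if self.visit_index < 1:
            raise ValueError("visit_index must be >= 1")
        if self.flow_state is None and self.indicators is not None:
            sf = self.indicators.surface_flow_pct
            if sf is not None:
                # convention: a visit is "flowing" iff any surface flow was seen
                self.flow_state = "flowing" if sf > 0 else "dry"
        if self.flow_state is not None and self.flow_state not in ("dry", "flowing"):
            raise ValueError(f"flow_state must be 'dry' or 'flowing', got {self.flow_state!r}")


@dataclass(frozen=True)
class FlowRecord:
    """Ordered daily flow observations for a reach.

    ``flowing`` is a boolean array, one entry per day; ``dates`` are strictly
    increasing. Used to truth-label reaches from logger/gage records.
    """

    dates: tuple
    flowing: tuple

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.flowing):
            raise ValueError("dates and flowing must have equal length")
        for a, b in zip(self.dates, self.dates[1:]):
            if not a < b:
                raise ValueError("dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def flowing_fraction(self) -> float:
        if len(self) == 0:
            raise ValueError("empty flow record")
        return float(np.mean(np.asarray(self.flowing, dtype=bool)))

    @classmethod
    def from_states(cls, dates: Iterable, states: Iterable[str]) -> "FlowRecord":
        flow = []
        for s in states:
            if s not in ("flowing", "zero_flow"):
                raise ValueError(f"state must be 'flowing' or 'zero_flow', got {s!r}")
            flow.append(s == "flowing")
        return cls(tuple(dates), tuple(flow))


def classify_flow_record(record: FlowRecord) -> StreamflowClass:
    """Truth-label a reach from a daily flow record.

    Perennial if strictly fewer than 5% of days are zero-flow; Ephemeral if
    strictly fewer than 5% of days are flowing; Intermittent otherwise.
    Exactly 5% on either side falls to Intermittent (strict inequalities).
    """
    if len(record) == 0:
        raise ValueError("cannot classify an empty flow record")
    f = record.flowing_fraction
    if 1.0 - f < 0.05:
        return StreamflowClass.PERENNIAL
    if f < 0.05:
        return StreamflowClass.EPHEMERAL
    return StreamflowClass.INTERMITTENT


def reach_length(widths: Sequence[float]) -> float:
    """Assessment reach length in meters: 40x mean bankfull width, clamped to [40, 200]."""
    if len(widths) == 0:
        raise ValueError("at least one bankfull width is required")
    for w in widths:
        if w <= 0:
            raise ValueError(f"bankfull widths must be positive, got {w}")
    return float(min(200.0, max(40.0, 40.0 * float(np.mean(widths)))))


@dataclass(frozen=True)
class MetricMeta:
    """Per-column metadata for a metric table."""

    metric_type: str  # biological | geomorphological | hydrological | geospatial
    direct_water: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.metric_type not in (
            "biological",
            "geomorphological",
            "hydrological",
            "geospatial",
        ):
            raise ValueError(f"unknown metric_type {self.metric_type!r}")
        if self.direct_water and self.metric_type != "hydrological":
            raise ValueError("direct_water applies only to hydrological metrics")


class MetricTable:
    """Visits x numeric metrics, keyed by (reach_id, visit_index), with metadata.

    Thin wrapper over a pandas DataFrame that carries per-column
    :class:`MetricMeta` and the list of visits excluded as incomplete.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        metadata: Mapping[str, MetricMeta],
        exclusions: Optional[Sequence[tuple]] = None,
    ):
        if data.index.nlevels != 2:
            raise ValueError("MetricTable index must be (reach_id, visit_index)")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate (reach_id, visit_index) keys: {dupes}")
        missing = [c for c in data.columns if c not in metadata]
        if missing:
            raise ValueError(f"metadata missing for columns: {missing}")
        self.data = data
        self.metadata = dict(metadata)
        self.exclusions = list(exclusions or [])

    # -- convenience views ------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def metric_names(self) -> list:
        return list(self.data.columns)

    def initial_visits(self) -> "MetricTable":
        """Rows for visit_index 1 only (revisits are withheld from analysis)."""
        mask = self.data.index.get_level_values(1) == 1
        return MetricTable(self.data.loc[mask], self.metadata, self.exclusions)

    def revisit_reaches(self) -> list:
        """Reach ids having at least two visits in the table."""
        counts = self.data.groupby(level=0).size()
        return sorted(counts.index[counts >= 2])

    def select_metrics(
        self,
        include_geospatial: bool = True,
        include_direct_water: bool = True,
    ) -> "MetricTable":
        cols = []
        for c in self.data.columns:
            m = self.metadata[c]
            if not include_geospatial and m.metric_type == "geospatial":
                continue
            if not include_direct_water and m.direct_water:
                continue
            cols.append(c)
        return MetricTable(self.data[cols], {c: self.metadata[c] for c in cols}, self.exclusions)

    def subset_columns(self, columns: Sequence[str]) -> "MetricTable":
        return MetricTable(
            self.data[list(columns)],
            {c: self.metadata[c] for c in columns},
            self.exclusions,
        )

    def subset_reaches(self, reach_ids: Iterable[str]) -> "MetricTable":
        wanted = set(reach_ids)
        mask = [rid in wanted for rid in self.data.index.get_level_values(0)]
        return MetricTable(self.data.loc[mask], self.metadata, self.exclusions)


def _group_stats(taxa: Sequence[TaxonObservation]):
    """Capped abundance and family richness, total and per indicator group."""
    total_abund = sum(t.capped_count for t in taxa)
    richness = len({t.taxon for t in taxa})
    out = {"TotalAbundance": total_abund, "Richness": richness}
    group_abund = {g: 0 for g in TAXON_GROUPS}
    group_taxa = {g: set() for g in TAXON_GROUPS}
    group_live = {g: 0 for g in TAXON_GROUPS}
    for t in taxa:
        for g in t.groups:
            group_abund[g] += t.capped_count
            group_taxa[g].add(t.taxon)
            if t.live:
                group_live[g] += t.capped_count

    def rel(num, den):
        return num / den if den > 0 else 0.0

    goldoch_abund = group_abund["GOLD"] + group_abund["OCH"]
    goldoch_taxa = len(group_taxa["GOLD"] | group_taxa["OCH"])
    out.update(
        {
            "mayfly_abundance": group_abund["mayfly"],
            "perennial_abundance": group_abund["perennial"],
            "perennial_taxa": len(group_taxa["perennial"]),
            "perennial_live_abundance": group_live["perennial"],
            "EPT_abundance": group_abund["EPT"],
            "EPT_taxa": len(group_taxa["EPT"]),
            "EPT_relabd": rel(group_abund["EPT"], total_abund),
            "EPT_reltaxa": rel(len(group_taxa["EPT"]), richness),
            "GOLD_relabd": rel(group_abund["GOLD"], total_abund),
            "GOLD_reltaxa": rel(len(group_taxa["GOLD"]), richness),
            "OCH_relabd": rel(group_abund["OCH"], total_abund),
            "OCH_reltaxa": rel(len(group_taxa["OCH"]), richness),
            "GOLDOCH_relabd": rel(goldoch_abund, total_abund),
            "GOLDOCH_reltaxa": rel(goldoch_taxa, richness),
            "Noninsect_abundance": group_abund["noninsect"],
            "Noninsect_taxa": len(group_taxa["noninsect"]),
            "Noninsect_relabund": rel(group_abund["noninsect"], total_abund),
            "Noninsect_reltaxa": rel(len(group_taxa["noninsect"]), richness),
        }
    )
    return out


def _bool_metric(v: Optional[bool]) -> float:
    return float(bool(v)) if v is not None else np.nan


_METRIC_META = {
    # invertebrate metrics
    **{
        name: MetricMeta("biological", description=desc)
        for name, desc in {
            "TotalAbundance": "total aquatic invertebrate abundance (capped tallies)",
            "Richness": "total aquatic invertebrate family richness",
            "mayfly_abundance": "abundance of mayflies",
            "perennial_abundance": "abundance of perennial-indicator taxa",
            "perennial_taxa": "richness of perennial-indicator taxa",
            "perennial_live_abundance": "abundance of live perennial-indicator taxa",
            "EPT_abundance": "EPT abundance",
            "EPT_taxa": "EPT richness",
            "EPT_relabd": "EPT relative abundance",
            "EPT_reltaxa": "EPT relative richness",
            "GOLD_relabd": "GOLD relative abundance",
            "GOLD_reltaxa": "GOLD relative richness",
            "OCH_relabd": "OCH relative abundance",
            "OCH_reltaxa": "OCH relative richness",
            "GOLDOCH_relabd": "GOLD+OCH relative abundance",
            "GOLDOCH_reltaxa": "GOLD+OCH relative richness",
            "Noninsect_abundance": "non-insect abundance",
            "Noninsect_taxa": "non-insect richness",
            "Noninsect_relabund": "non-insect relative abundance",
            "Noninsect_reltaxa": "non-insect relative richness",
            "bmiabund_score": "aquatic invertebrate abundance score (NM)",
            "fishabund_score2": "fish abundance score (NM), excluding mosquitofish",
            "amphabund_score": "amphibian abundance score (NM)",
            "vert_score": "presence of aquatic vertebrates",
            "vert_sumscore": "number of aquatic vertebrate types detected",
            "algabund_score": "filamentous algal abundance score (NM)",
            "alglive_cover_score": "live algal cover on the streambed (ordinal)",
            "alglivedead_cover_score": "live or dead algal cover on the streambed (ordinal)",
            "vegdiff_score": "difference in vegetation score (NM)",
            "rootedplants_score": "upland rooted plants in streambed score (NM)",
            "hydrophytes_present_noflag": "number of hydrophytic plant species (FACW/OBL)",
            "moss_cover_score": "streamer moss cover in the channel (ordinal)",
            "liverwort_cover_score": "liverwort cover in the channel (ordinal)",
            "PctShading": "percent stream shading (densiometer mean)",
            "iofb_score": "presence of iron-oxidizing fungi or bacteria",
        }.items()
    },
    # geomorphological
    **{
        name: MetricMeta("geomorphological", description=desc)
        for name, desc in {
            "sinuosity_score": "sinuosity score (NM)",
            "entrenchment_score": "entrenchment/floodplain connectivity score (NM)",
            "substratesorting_score": "substrate sorting score (NM)",
            "riffpoolseq_score": "riffle-pool sequence score (NM)",
            "seddeposition_score": "sediment deposition score (NM)",
            "BankWidthMean": "mean bankfull width (m)",
        }.items()
    },
    # hydrological; direct_water marks direct measures of surface-water presence
    "waterinchannel_score": MetricMeta(
        "hydrological", direct_water=True, description="water in channel score (NM)"
    ),
    "pctsurfaceflow": MetricMeta(
        "hydrological", direct_water=True, description="percent surface flow in channel"
    ),
    "pctsubsurfaceflow": MetricMeta(
        "hydrological",
        direct_water=True,
        description="percent surface or subsurface flow in channel",
    ),
    "SoilMoist_MaxScore": MetricMeta(
        "hydrological", direct_water=True, description="maximum soil moisture score"
    ),
    "isolatedpools_count": MetricMeta(
        "hydrological", direct_water=True, description="number of isolated pools"
    ),
    "seeps_score": MetricMeta(
        "hydrological", direct_water=True, description="presence of seeps or springs"
    ),
    "hydric_score": MetricMeta("hydrological", description="presence of hydric soils"),
    "woodyjam_count": MetricMeta("hydrological", description="number of woody jams"),
}


def compute_metrics(
    visits: Sequence[Visit],
    extra_columns: Optional[pd.DataFrame] = None,
    extra_metadata: Optional[Mapping[str, MetricMeta]] = None,
) -> MetricTable:
    """Convert raw indicator records into the numeric metric table.

    One row per visit, keyed by (reach_id, visit_index). Invertebrate
    abundances use tallies capped at 10 per morphotaxon; richness counts
    distinct families; relative metrics are group/total with the 0/0 case
    defined as 0. Ordinal scores and covers pass through as metric columns.
    Visits missing a mandatory indicator are excluded with a logged reason.

    ``extra_columns`` (e.g., pre-computed geospatial metrics, indexed the same
    way) are passed through untouched; their metadata defaults to geospatial.
    """
    rows = {}
    exclusions = []
    for v in visits:
        key = (v.reach_id, v.visit_index)
        if key in rows:
            raise ValueError(f"duplicate visit key {key}")
        ind = v.indicators
        if ind is None:
            exclusions.append((key, "no indicator record"))
            logger.warning("visit %s excluded: no indicator record", key)
            continue
        problems = ind.validate()
        if problems:
            raise ValueError(f"visit {key}: invalid indicators: {problems}")
        missing = ind.missing_mandatory()
        if missing:
            reason = f"missing mandatory indicators: {missing}"
            exclusions.append((key, reason))
            logger.warning("visit %s excluded: %s", key, reason)
            continue

        row = _group_stats(list(ind.invertebrates))
        for field_name, metric_name in _NM_SCORE_METRICS.items():
            val = getattr(ind, field_name)
            row[metric_name] = np.nan if val is None else float(val)
        row["hydrophytes_present_noflag"] = float(ind.hydrophyte_species_count)
        row["alglive_cover_score"] = (
            _COVER_CODE[ind.algal_cover_live] if ind.algal_cover_live is not None else np.nan
        )
        row["alglivedead_cover_score"] = _COVER_CODE[ind.algal_cover_livedead]
        row["moss_cover_score"] = (
            _COVER_CODE[ind.moss_cover] if ind.moss_cover is not None else np.nan
        )
        row["liverwort_cover_score"] = (
            _COVER_CODE[ind.liverwort_cover] if ind.liverwort_cover is not None else np.nan
        )
        row["PctShading"] = (
            float(np.mean(ind.shading_readings))
            if ind.shading_readings is not None
            else np.nan
        )
        vert_flags = [ind.fish_present, ind.amphibians_present, ind.snakes_present]
        row["vert_score"] = float(any(bool(f) for f in vert_flags if f is not None))
        row["vert_sumscore"] = float(sum(bool(f) for f in vert_flags if f is not None))
        row["iofb_score"] = _bool_metric(ind.iron_oxidizing)
        row["hydric_score"] = _bool_metric(ind.hydric_soils)
        row["seeps_score"] = _bool_metric(ind.seeps_springs)
        row["pctsurfaceflow"] = float(ind.surface_flow_pct)
        row["pctsubsurfaceflow"] = (
            float(ind.subsurface_flow_pct) if ind.subsurface_flow_pct is not None else np.nan
        )
        row["SoilMoist_MaxScore"] = (
            float(ind.soil_moisture_max_score)
            if ind.soil_moisture_max_score is not None
            else np.nan
        )
        row["isolatedpools_count"] = (
            float(ind.isolated_pool_count) if ind.isolated_pool_count is not None else np.nan
        )
        row["woodyjam_count"] = (
            float(ind.woody_jam_count) if ind.woody_jam_count is not None else np.nan
        )
        row["BankWidthMean"] = (
            float(np.mean(ind.bankfull_widths)) if ind.bankfull_widths is not None else np.nan
        )
        rows[key] = row

    index = pd.MultiIndex.from_tuples(rows.keys(), names=["reach_id", "visit_index"])
    data = pd.DataFrame(list(rows.values()), index=index)
    metadata = {c: _METRIC_META[c] for c in data.columns}

    if extra_columns is not None:
        extra = extra_columns.reindex(data.index)
        for c in extra.columns:
            if c in data.columns:
                raise ValueError(f"extra column {c!r} collides with a computed metric")
            data[c] = extra[c]
            meta = (extra_metadata or {}).get(c, MetricMeta("geospatial", description=c))
            metadata[c] = meta

    return MetricTable(data, metadata, exclusions)
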