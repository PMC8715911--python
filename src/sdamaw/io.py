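"""CSV I/O for field data, metric tables, flow records and beta-form inputs.

All files are UTF-8, comma-delimited, header row mandatory. Category labels
are exact ASCII tokens (see :data:`sdamaw.beta_method.DISPLAY_LABELS` for
the mapping to the field-form display labels). Validation failures are
collected and reported together with row/column context.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .beta_method import (
    ALGAL_COVER_LEVELS,
    BetaInputs,
)
from .core_data import (
    COVER_CATEGORIES,
    FlowRecord,
    IndicatorRecord,
    MetricMeta,
    MetricTable,
    Reach,
    StreamflowClass,
    TaxonObservation,
    Visit,
)

__all__ = [
    "ValidationError",
    "read_field_data",
    "write_field_data",
    "read_flow_records",
    "write_flow_records",
    "read_metric_table",
    "write_metric_table",
    "read_beta_inputs",
    "read_reaches",
    "write_reaches",
]

_PathLike = Union[str, Path]


class ValidationError(ValueError):
    """A file failed schema validation; ``errors`` itemizes every problem."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


_SCALAR_FIELDS = [
    f.name
    for f in dataclasses.fields(IndicatorRecord)
    if f.name not in ("invertebrates", "shading_readings", "bankfull_widths")
]
_BOOL_FIELDS = {
    "hydric_soils",
    "seeps_springs",
    "iron_oxidizing",
    "fish_present",
    "mosquitofish_present",
    "amphibians_present",
    "snakes_present",
}


def write_field_data(
    visits: Sequence[Visit], visits_path: _PathLike, taxa_path: _PathLike
) -> None:
    """Write visits as a wide CSV plus a long-format taxa CSV."""
    rows = []
    taxa_rows = []
    for v in visits:
        ind = v.indicators or IndicatorRecord()
        row = {"reach_id": v.reach_id, "visit_index": v.visit_index,
               "date": v.date.isoformat() if v.date else ""}
        for name in _SCALAR_FIELDS:
            row[name] = getattr(ind, name)
        for name in ("shading_readings", "bankfull_widths"):
            seq = getattr(ind, name)
            row[name] = "" if seq is None else ";".join(str(float(x)) for x in seq)
        rows.append(row)
        if ind.invertebrates is not None:
            for t in ind.invertebrates:
                taxa_rows.append(
                    {
                        "reach_id": v.reach_id,
                        "visit_index": v.visit_index,
                        "taxon": t.taxon,
                        "count": t.count,
                        "group_flags": ";".join(sorted(t.groups)),
                        "live": t.live,
                    }
                )
    pd.DataFrame(rows).to_csv(visits_path, index=False)
    pd.DataFrame(
        taxa_rows,
        columns=["reach_id", "visit_index", "taxon", "count", "group_flags", "live"],
    ).to_csv(taxa_path, index=False)


def _parse_scalar(name: str, raw, errors, where: str):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    if name in _BOOL_FIELDS:
        s = str(raw).strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        errors.append(f"{where}: {name}={raw!r} is not a boolean")
        return None
    if name in ("algal_cover_live", "algal_cover_livedead", "moss_cover", "liverwort_cover"):
        s = str(raw).strip()
        if s not in COVER_CATEGORIES:
            errors.append(f"{where}: {name}={s!r} not one of {COVER_CATEGORIES}")
            return None
        return s
    try:
        val = float(raw)
    except (TypeError, ValueError):
        errors.append(f"{where}: {name}={raw!r} is not numeric")
        return None
    if name.endswith("_count") or name.endswith("_score") or name == "hydrophyte_species_count":
        return int(val)
    return val


def read_field_data(
    visits_path: _PathLike, taxa_path: Optional[_PathLike] = None
) -> list:
    """Read visits (and optional long-format taxa) back into Visit records.

    Unknown columns, bad category tokens and duplicate (reach_id,
    visit_index) keys raise :class:`ValidationError` itemizing every problem.
    """
    frame = pd.read_csv(visits_path, dtype=object)
    errors: list = []
    known = {"reach_id", "visit_index", "date", "flow_state",
             "shading_readings", "bankfull_widths", *_SCALAR_FIELDS}
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        errors.append(f"unknown columns: {unknown}")

    taxa_by_key: dict = {}
    if taxa_path is not None:
        taxa = pd.read_csv(taxa_path, dtype=object)
        for i, r in taxa.iterrows():
            where = f"taxa row {i}"
            try:
                groups = frozenset(
                    g for g in str(r.get("group_flags") or "").split(";") if g
                )
                live_raw = r.get("live")
                live = (
                    True
                    if live_raw is None or (isinstance(live_raw, float) and np.isnan(live_raw))
                    else str(live_raw).strip().lower() in ("true", "1", "yes")
                )
                obs = TaxonObservation(
                    taxon=str(r["taxon"]),
                    count=int(float(r["count"])),
                    groups=groups,
                    live=live,
                )
            except (KeyError, ValueError) as exc:
                errors.append(f"{where}: {exc}")
                continue
            key = (str(r["reach_id"]), int(float(r["visit_index"])))
            taxa_by_key.setdefault(key, []).append(obs)

    visits = []
    seen = set()
    for i, r in frame.iterrows():
        where = f"row {i}"
        try:
            key = (str(r["reach_id"]), int(float(r["visit_index"])))
        except (KeyError, ValueError):
            errors.append(f"{where}: bad reach_id/visit_index")
            continue
        if key in seen:
            errors.append(f"{where}: duplicate (reach_id, visit_index) {key}")
            continue
        seen.add(key)
        kwargs = {}
        for name in _SCALAR_FIELDS:
            if name in frame.columns:
                kwargs[name] = _parse_scalar(name, r[name], errors, where)
        for name in ("shading_readings", "bankfull_widths"):
            raw = r.get(name)
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)) and raw != "":
                try:
                    kwargs[name] = tuple(float(x) for x in str(raw).split(";"))
                except ValueError:
                    errors.append(f"{where}: {name}={raw!r} is not ';'-separated numbers")
        if key in taxa_by_key or "invertebrates" not in kwargs:
            kwargs["invertebrates"] = taxa_by_key.get(key)
        ind = IndicatorRecord(**kwargs)
        problems = ind.validate()
        if problems:
            errors.extend(f"{where}: {p}" for p in problems)
            continue
        date_raw = r.get("date")
        date = (
            pd.Timestamp(date_raw).date()
            if date_raw not in (None, "") and not (isinstance(date_raw, float) and np.isnan(date_raw))
            else None
        )
        visits.append(Visit(reach_id=key[0], visit_index=key[1], date=date, indicators=ind))
    if errors:
        raise ValidationError(errors)
    return visits


def write_reaches(reaches: Sequence[Reach], path: _PathLike) -> None:
    pd.DataFrame(
        [
            {
                "reach_id": r.reach_id,
                "subregion": r.subregion,
                "true_class": r.true_class.value,
                "evidence_tier": r.evidence_tier,
                "latitude": r.latitude,
                "longitude": r.longitude,
            }
            for r in reaches
        ]
    ).to_csv(path, index=False)


def read_reaches(path: _PathLike) -> list:
    frame = pd.read_csv(path, dtype=object)
    errors: list = []
    reaches = []
    seen = set()
    for i, r in frame.iterrows():
        try:
            rid = str(r["reach_id"])
            if rid in seen:
                errors.append(f"row {i}: duplicate reach_id {rid!r}")
                continue
            seen.add(rid)
            reaches.append(
                Reach(
                    reach_id=rid,
                    subregion=str(r["subregion"]),
                    true_class=StreamflowClass(str(r["true_class"])),
                    evidence_tier=str(r.get("evidence_tier") or "preferred"),
                )
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(errors)
    return reaches


def write_flow_records(records: dict, path: _PathLike) -> None:
    """Write {reach_id: FlowRecord} as long CSV (reach_id, date, state)."""
    rows = []
    for rid, rec in records.items():
        for d, f in zip(rec.dates, rec.flowing):
            rows.append({"reach_id": rid, "date": d.isoformat(),
                         "state": "flowing" if f else "zero_flow"})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_flow_records(path: _PathLike) -> dict:
    frame = pd.read_csv(path, dtype=object)
    errors: list = []
    out = {}
    for rid, group in frame.groupby("reach_id", sort=True):
        try:
            dates = [pd.Timestamp(d).date() for d in group["date"]]
            order = np.argsort(dates)
            out[str(rid)] = FlowRecord.from_states(
                [dates[i] for i in order],
                [str(group["state"].iloc[i]) for i in order],
            )
        except ValueError as exc:
            errors.append(f"reach {rid}: {exc}")
    if errors:
        raise ValidationError(errors)
    return out


def write_metric_table(table: MetricTable, data_path: _PathLike, meta_path: _PathLike) -> None:
    table.data.to_csv(data_path)
    pd.DataFrame(
        [
            {
                "metric": name,
                "metric_type": m.metric_type,
                "direct_water": m.direct_water,
                "description": m.description,
            }
            for name, m in table.metadata.items()
        ]
    ).to_csv(meta_path, index=False)


def read_metric_table(data_path: _PathLike, meta_path: _PathLike) -> MetricTable:
    data = pd.read_csv(data_path, index_col=[0, 1])
    meta_frame = pd.read_csv(meta_path)
    metadata = {
        str(r["metric"]): MetricMeta(
            metric_type=str(r["metric_type"]),
            direct_water=bool(r["direct_water"]) if not isinstance(r["direct_water"], str)
            else str(r["direct_water"]).strip().lower() == "true",
            description=str(r["description"]) if not pd.isna(r["description"]) else "",
        )
        for _, r in meta_frame.iterrows()
    }
    return MetricTable(data, metadata)


def read_beta_inputs(path: _PathLike) -> pd.DataFrame:
    """Read a field-form CSV of per-visit beta-method inputs.

    Accepts either raw measurements (``hydrophyte_count``,
    ``invertebrate_abundance``, ``ept_present``, ``algal_cover``,
    ``fish_present``) or pre-categorized tokens (``hydrophytes``,
    ``invertebrates``, ``ept``, ``algae``, ``algal_cover``,
    ``fish_present``). Returns the frame with a ``beta_inputs`` column of
    validated :class:`BetaInputs`.
    """
    frame = pd.read_csv(path, dtype=object, keep_default_na=False)
    errors: list = []
    inputs = []
    raw_form = "hydrophyte_count" in frame.columns
    for i, r in frame.iterrows():
        where = f"row {i}"
        try:
            fish = str(r.get("fish_present", "false")).strip().lower() in ("true", "1", "yes")
            cover = str(r.get("algal_cover", "ND")).strip() or "ND"
            if cover not in ALGAL_COVER_LEVELS:
                raise ValueError(f"algal_cover={cover!r} not one of {ALGAL_COVER_LEVELS}")
            if raw_form:
                b = BetaInputs.from_counts(
                    hydrophyte_count=int(float(r["hydrophyte_count"])),
                    invertebrate_abundance=int(float(r["invertebrate_abundance"])),
                    ept_present=str(r["ept_present"]).strip().lower() in ("true", "1", "yes"),
                    algal_cover=cover,
                    fish_present=fish,
                )
            else:
                b = BetaInputs(
                    hydrophytes=str(r["hydrophytes"]),
                    invertebrates=str(r["invertebrates"]),
                    ept=str(r["ept"]),
                    algae=str(r["algae"]),
                    algal_cover=cover,
                    fish_present=fish,
                )
        except (KeyError, ValueError) as exc:
            errors.append(f"{where}: {exc}")
            continue
        inputs.append(b)
    if errors:
        raise ValidationError(errors)
    out = frame.copy()
    out["beta_inputs"] = inputs
    return out
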