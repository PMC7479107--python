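"""Readers and writers for farm descriptors, species tables and surveys.

File formats
------------
*Farm descriptor* — one YAML document per farm::

    farm:
      turbines:                   # one entry per turbine model
        - blade_length_m: 40
          tower_height_m: 80
          rotor_speed_rpm: 10
          count: 10
      rows: 1
      frontal_area_m2: 240000     # or: row_widths_m: [2000]
    location:
      low_visibility_days: 36
      observation_days: 360
      sensitive_area_distance_km: 30   # omit when no sensitive area
      on_migratory_pass: true
      neighbour_farm_distances_km: [7.0]

*Species table* — comma-separated, UTF-8, header row, one species per
row, "." decimal separator.  Columns: ``name``, ``size_class``,
``months_present``, ``periods`` (semicolon-separated subset of
breeding;winter;passage), ``flight_height_min_m``,
``flight_height_max_m`` (or a single ``flight_height_m``),
``flight_type``, ``flock_class``, ``collision_record`` (or
``collision_study_pct``), ``strategy``, ``redbook``, ``socioeconomic``
(0/1/true/false).  Optional: ``modal_flight_height_m``.  Categorical
values are case-insensitive; unknown columns are ignored with a logged
warning.

*Survey table* — columns ``name``, ``presence_count``,
``individual_count``.

Validation failures raise :class:`~windfauna.errors.ValidationError`
with the offending field (farm files: YAML line number; tables: row
number) and a stable error code.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import pandas as pd
import yaml

from .errors import ValidationError, WindfaunaError
from .farm_constant import (FarmDescriptor, LocationContext,
                            frontal_area_from_rows)
from .species_scoring import (COLLISION_RECORDS, FLOCK_CLASSES, PERIODS,
                              CommunitySurvey, SpeciesTraits)
from .turbine_geometry import TurbineSpec

logger = logging.getLogger(__name__)

SPECIES_COLUMNS = {
    "name", "size_class", "months_present", "periods", "flight_height_m",
    "flight_height_min_m", "flight_height_max_m", "modal_flight_height_m",
    "flight_type", "flock_class", "collision_record", "collision_study_pct",
    "strategy", "redbook", "socioeconomic",
}
SURVEY_COLUMNS = {"name", "presence_count", "individual_count"}


# ---------------------------------------------------------------------------
# farm descriptor (YAML)

def _key_lines(path) -> dict[str, int]:
    """Map dotted key paths of a YAML mapping to 1-based line numbers."""
    with open(path, "r", encoding="utf-8") as fh:
        root = yaml.compose(fh)
    lines: dict[str, int] = {}

    def walk(node, prefix):
        if isinstance(node, yaml.MappingNode):
            for key, value in node.value:
                dotted = f"{prefix}.{key.value}" if prefix else key.value
                lines[dotted] = key.start_mark.line + 1
                walk(value, dotted)
        elif isinstance(node, yaml.SequenceNode):
            for i, item in enumerate(node.value):
                walk(item, f"{prefix}[{i}]")

    if root is not None:
        walk(root, "")
    return lines


class _FarmFileErrors:
    """Collects field-level problems so one load reports them all."""

    def __init__(self, path, lines: dict[str, int]):
        self.path = path
        self.lines = lines
        self.problems: list[tuple[str, str, str]] = []

    def add(self, field: str, message: str, code: str) -> None:
        self.problems.append((field, message, code))

    def raise_if_any(self) -> None:
        if not self.problems:
            return
        parts = []
        for field, message, code in self.problems:
            line = self.lines.get(field)
            where = f"{self.path}:{line}" if line else str(self.path)
            parts.append(f"{where}: {field}: {message} [{code}]")
        raise ValidationError("\n".join(parts), code=self.problems[0][2])


def _require(mapping, field, report, dotted, types, code="missing-field"):
    if not isinstance(mapping, dict) or field not in mapping:
        report.add(dotted, "required field is missing", code)
        return None
    value = mapping[field]
    if not isinstance(value, types):
        report.add(dotted, f"expected {types}, got {type(value).__name__}",
                   "invalid-type")
        return None
    return value


def load_farm(path) -> tuple[FarmDescriptor, LocationContext]:
    """Load and validate a farm descriptor document.

    Returns the farm layout and its location context; raises
    :class:`ValidationError` listing every problem with file:line
    references and error codes.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: not valid YAML: {exc}",
                              code="parse-error") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: document must be a mapping",
                              code="invalid-type")
    report = _FarmFileErrors(path, _key_lines(path))

    farm_doc = _require(doc, "farm", report, "farm", dict)
    loc_doc = _require(doc, "location", report, "location", dict)
    report.raise_if_any()

    # --- turbines
    turbines: list[tuple[TurbineSpec, int]] = []
    raw_turbines = _require(farm_doc, "turbines", report, "farm.turbines",
                            list)
    if raw_turbines is not None:
        for i, entry in enumerate(raw_turbines):
            base = f"farm.turbines[{i}]"
            if not isinstance(entry, dict):
                report.add(base, "turbine entry must be a mapping",
                           "invalid-type")
                continue
            r = _require(entry, "blade_length_m", report,
                         f"{base}.blade_length_m", (int, float))
            L = _require(entry, "tower_height_m", report,
                         f"{base}.tower_height_m", (int, float))
            sb = _require(entry, "rotor_speed_rpm", report,
                          f"{base}.rotor_speed_rpm", (int, float))
            count = entry.get("count", 1)
            if not isinstance(count, int) or count < 1:
                report.add(f"{base}.count",
                           "count must be a positive integer",
                           "invalid-value")
                continue
            if None in (r, L, sb):
                continue
            try:
                turbines.append((TurbineSpec(float(r), float(L), float(sb)),
                                 count))
            except WindfaunaError as exc:
                report.add(base, str(exc), "unit-violation")

    rows = _require(farm_doc, "rows", report, "farm.rows", int)
    report.raise_if_any()

    # --- frontal area: direct, or derived from per-row widths
    if "frontal_area_m2" in farm_doc:
        awf = farm_doc["frontal_area_m2"]
        if not isinstance(awf, (int, float)) or not awf > 0:
            report.add("farm.frontal_area_m2",
                       "frontal area must be a positive number",
                       "unit-violation")
        awf = float(awf) if isinstance(awf, (int, float)) else None
    elif "row_widths_m" in farm_doc:
        widths = farm_doc["row_widths_m"]
        if (not isinstance(widths, list) or len(widths) != rows
                or not all(isinstance(w, (int, float)) for w in widths)):
            report.add("farm.row_widths_m",
                       f"expected one positive width per row ({rows})",
                       "invalid-value")
            awf = None
        else:
            tallest = max((t for t, _ in turbines),
                          key=lambda t: t.tower_height_m + t.blade_length_m)
            awf = frontal_area_from_rows(widths, tallest)
    else:
        report.add("farm", "one of frontal_area_m2 or row_widths_m required",
                   "missing-field")
        awf = None
    report.raise_if_any()

    # --- location context
    vis = _require(loc_doc, "low_visibility_days", report,
                   "location.low_visibility_days", int)
    obs = _require(loc_doc, "observation_days", report,
                   "location.observation_days", int)
    dist = loc_doc.get("sensitive_area_distance_km")
    if dist is not None and not isinstance(dist, (int, float)):
        report.add("location.sensitive_area_distance_km",
                   "distance must be a number or omitted", "invalid-type")
        dist = None
    on_pass = loc_doc.get("on_migratory_pass", False)
    if not isinstance(on_pass, bool):
        report.add("location.on_migratory_pass", "expected true/false",
                   "invalid-type")
        on_pass = False
    neighbours = loc_doc.get("neighbour_farm_distances_km", [])
    if (not isinstance(neighbours, list)
            or not all(isinstance(d, (int, float)) for d in neighbours)):
        report.add("location.neighbour_farm_distances_km",
                   "expected a list of distances in km", "invalid-type")
        neighbours = []
    report.raise_if_any()

    try:
        farm = FarmDescriptor(turbines=tuple(turbines), rows=rows,
                              frontal_area_m2=awf)
        context = LocationContext(
            low_visibility_days=vis,
            observation_days=obs,
            sensitive_area_distance_km=(
                float(dist) if dist is not None else None),
            on_migratory_pass=on_pass,
            neighbour_farm_distances_km=tuple(float(d) for d in neighbours),
        )
    except WindfaunaError as exc:
        raise ValidationError(f"{path}: {exc}", code=getattr(
            exc, "code", "invalid-value")) from exc
    return farm, context


def save_farm(farm: FarmDescriptor, context: LocationContext, path) -> None:
    """Serialise a farm descriptor back to the YAML schema of :func:`load_farm`."""
    doc = {
        "farm": {
            "turbines": [
                {
                    "blade_length_m": t.blade_length_m,
                    "tower_height_m": t.tower_height_m,
                    "rotor_speed_rpm": t.rotor_speed_rpm,
                    "count": n,
                }
                for t, n in farm.turbines
            ],
            "rows": farm.rows,
            "frontal_area_m2": farm.frontal_area_m2,
        },
        "location": {
            "low_visibility_days": context.low_visibility_days,
            "observation_days": context.observation_days,
            "on_migratory_pass": context.on_migratory_pass,
            "neighbour_farm_distances_km":
                list(context.neighbour_farm_distances_km),
        },
    }
    if context.sensitive_area_distance_km is not None:
        doc["location"]["sensitive_area_distance_km"] = (
            context.sensitive_area_distance_km)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# species table (CSV)

def _norm(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return text if text else None


def _parse_bool(value) -> bool:
    text = (_norm(value) or "0").lower()
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n"):
        return False
    raise ValidationError(f"expected a boolean flag, got {value!r}",
                          code="invalid-value")


def _species_from_row(row: pd.Series) -> SpeciesTraits:
    name = _norm(row.get("name"))
    if name is None:
        raise ValidationError("name is required", code="missing-field")

    if _norm(row.get("flight_height_m")) is not None:
        h = float(row["flight_height_m"])
        height = (h, h)
    else:
        lo = _norm(row.get("flight_height_min_m"))
        hi = _norm(row.get("flight_height_max_m"))
        if lo is None or hi is None:
            raise ValidationError(
                "flight_height_m or flight_height_min_m/"
                "flight_height_max_m required", code="missing-field")
        height = (float(lo), float(hi))

    periods_text = _norm(row.get("periods")) or ""
    periods = frozenset(
        p.strip().lower() for p in periods_text.replace("|", ";").split(";")
        if p.strip())

    record = _norm(row.get("collision_record"))
    pct = _norm(row.get("collision_study_pct"))
    modal = _norm(row.get("modal_flight_height_m"))
    months = _norm(row.get("months_present"))
    if months is None:
        raise ValidationError("months_present is required",
                              code="missing-field")

    return SpeciesTraits(
        name=name,
        size_class=(_norm(row.get("size_class")) or "").lower(),
        months_present=int(float(months)),
        periods=periods,
        flight_height_m=height,
        modal_flight_height_m=float(modal) if modal is not None else None,
        flight_type=(_norm(row.get("flight_type")) or "").lower(),
        flock_class=(_norm(row.get("flock_class")) or "").replace("–", "-"),
        collision_record=record.lower() if record is not None else None,
        collision_study_pct=float(pct) if pct is not None else None,
        strategy=(_norm(row.get("strategy")) or "").upper(),
        redbook=(_norm(row.get("redbook")) or "").upper(),
        socioeconomic=_parse_bool(row.get("socioeconomic")),
    )


def load_species_table(path) -> list[SpeciesTraits]:
    """Load a species-traits CSV; returns one validated record per row.

    Duplicate species names are rejected; problems are reported with the
    1-based data row number.
    """
    table = pd.read_csv(path)
    unknown = set(table.columns) - SPECIES_COLUMNS
    if unknown:
        logger.warning("%s: ignoring unknown column(s): %s", path,
                       ", ".join(sorted(unknown)))

    species: list[SpeciesTraits] = []
    problems: list[str] = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(table.iterrows(), start=1):
        try:
            s = _species_from_row(row)
        except (WindfaunaError, ValueError) as exc:
            problems.append(f"{path} row {i}: {exc}")
            continue
        if s.name in seen:
            problems.append(
                f"{path} row {i}: duplicate species {s.name!r} "
                f"[duplicate-species]")
            continue
        seen.add(s.name)
        species.append(s)
    if problems:
        raise ValidationError("\n".join(problems), code="invalid-row")
    if not species:
        raise ValidationError(f"{path}: species table is empty",
                              code="empty-table")
    return species


def save_species_table(species, path) -> None:
    """Write species traits to the CSV schema of :func:`load_species_table`."""
    rows = []
    for s in species:
        rows.append({
            "name": s.name,
            "size_class": s.size_class,
            "months_present": s.months_present,
            "periods": ";".join(sorted(s.periods)),
            "flight_height_min_m": s.flight_height_m[0],
            "flight_height_max_m": s.flight_height_m[1],
            "modal_flight_height_m": s.modal_flight_height_m,
            "flight_type": s.flight_type,
            "flock_class": s.flock_class,
            "collision_record": s.collision_record,
            "collision_study_pct": s.collision_study_pct,
            "strategy": s.strategy,
            "redbook": s.redbook,
            "socioeconomic": int(s.socioeconomic),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# survey table (CSV)

def load_survey(path) -> CommunitySurvey:
    """Load a community survey CSV (name, presence_count, individual_count)."""
    table = pd.read_csv(path)
    missing = SURVEY_COLUMNS - set(table.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing column(s): {', '.join(sorted(missing))}",
            code="missing-field")
    unknown = set(table.columns) - SURVEY_COLUMNS
    if unknown:
        logger.warning("%s: ignoring unknown column(s): %s", path,
                       ", ".join(sorted(unknown)))
    names = [(_norm(n) or "") for n in table["name"]]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate species in survey",
                              code="duplicate-species")
    try:
        return CommunitySurvey(
            presence_counts=dict(zip(names, (int(v) for v in
                                             table["presence_count"]))),
            individual_counts=dict(zip(names, (int(v) for v in
                                               table["individual_count"]))),
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}", code="invalid-value") from exc


def save_survey(survey: CommunitySurvey, path) -> None:
    """Write a community survey back to CSV."""
    pd.DataFrame({
        "name": list(survey.presence_counts),
        "presence_count": list(survey.presence_counts.values()),
        "individual_count": [survey.individual_counts[n]
                             for n in survey.presence_counts],
    }).to_csv(path, index=False)
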