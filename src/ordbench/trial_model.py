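"""Domain model for two-arm vascular prevention comparisons.

A *comparator dataset* is one treatment-vs-control comparison extracted from a
randomised trial; factorial and multi-arm trials contribute several.  Each
participant carries the covariates that are consistently available across
prevention trials (age, sex, history of diabetes), a binary event indicator,
and the attributes needed to place an event on an ordered severity scale
(fatality, a free-text severity tag, time to event or censoring).

An :class:`OrdinalScale` turns those attributes into an ordered categorical
outcome: level 0 is always "none" (no qualifying event) and the highest level
is always fatal, so that "higher = worse" holds uniformly for trend tests,
cumulative-logit models and the win ratio.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

TREATMENT = "treatment"
CONTROL = "control"

__all__ = [
    "ParticipantRecord",
    "OrdinalScale",
    "ComparatorDataset",
    "MappingError",
    "ordinalise",
    "collapse_to_binary",
    "expand_comparisons",
    "read_participants_csv",
    "write_participants_csv",
    "dataset_from_frame",
    "load_scale_yaml",
    "dump_scale_yaml",
    "DEFAULT_SCALES",
    "get_scale",
]


class MappingError(KeyError):
    """A severity attribute has no level on the requested scale."""


@dataclass
class ParticipantRecord:
    """One randomised participant.

    ``sex`` is 1 for female, 0 for male; ``diabetes`` is 1 for a history of
    diabetes.  ``time`` is days from randomisation to the event (if
    ``observed``) or to censoring; both are optional because some trials did
    not share time-to-event data, in which case proportional-hazards methods
    are skipped.
    """

    arm: str
    age: float
    sex: int
    diabetes: int
    event: int
    fatal: int = 0
    severity_attr: str | None = None
    time: float | None = None
    observed: int | None = None

    def __post_init__(self) -> None:
        if self.fatal and not self.event:
            raise ValueError("fatal=1 requires event=1")
        if self.severity_attr is not None and not self.event:
            raise ValueError("severity_attr requires event=1")
        if self.time is not None and self.time < 0:
            raise ValueError("time must be >= 0")
        if self.observed is not None and bool(self.observed) != bool(self.event):
            raise ValueError("observed=1 iff event=1")


@dataclass(frozen=True)
class OrdinalScale:
    """An ordered severity scale and the rule set mapping records to levels.

    ``levels`` runs from index 0 ("none") to the most severe (fatal) category.
    Non-fatal events are placed by looking up ``severity_attr`` in
    ``mapping``; events with an unmapped (or absent) attribute fall back to
    ``nonfatal_default`` when one is configured, otherwise a
    :class:`MappingError` naming the attribute is raised.
    """

    name: str
    levels: tuple[str, ...]
    mapping: Mapping[str, int] = field(default_factory=dict)
    nonfatal_default: int | None = None

    def __post_init__(self) -> None:
        k = len(self.levels)
        if not 3 <= k <= 9:
            raise ValueError(f"scale {self.name!r}: need 3..9 levels, got {k}")
        if self.levels[0] != "none":
            raise ValueError("level 0 must be labelled 'none'")
        for attr, lev in self.mapping.items():
            if not 1 <= lev <= k - 1:
                raise ValueError(f"mapping {attr!r} -> {lev} out of range")
        if self.nonfatal_default is not None and not (
            1 <= self.nonfatal_default <= k - 2 or k == 3
        ):
            # with k == 3 the only non-fatal event level is 1
            if not 1 <= self.nonfatal_default <= k - 1:
                raise ValueError("nonfatal_default out of range")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def fatal_level(self) -> int:
        return len(self.levels) - 1

    def level_of(self, record: ParticipantRecord) -> int:
        if not record.event:
            return 0
        if record.fatal:
            return self.fatal_level
        attr = record.severity_attr
        if attr is not None and attr in self.mapping:
            return self.mapping[attr]
        if self.nonfatal_default is not None:
            return self.nonfatal_default
        raise MappingError(
            f"scale {self.name!r} has no level for severity attribute {attr!r}"
        )

    def attributes_for_level(self, level: int) -> tuple[int, int, str | None]:
        """Inverse map: (event, fatal, severity_attr) producing ``level``.

        Used by the synthetic-data generator so that simulated records
        round-trip through :func:`ordinalise`.
        """
        if not 0 <= level <= self.fatal_level:
            raise IndexError(f"level {level} out of range for {self.name}")
        if level == 0:
            return 0, 0, None
        if level == self.fatal_level:
            return 1, 1, None
        for attr, lev in self.mapping.items():
            if lev == level:
                return 1, 0, attr
        if self.nonfatal_default == level:
            return 1, 0, None
        # fall back to the level label itself as the attribute tag
        return 1, 0, self.levels[level]


@dataclass
class ComparatorDataset:
    """One two-arm comparison, with metadata tags (prevention type, class)."""

    id: str
    records: list[ParticipantRecord]
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arms = sorted({r.arm for r in self.records})
        if len(arms) != 2:
            raise ValueError(f"dataset {self.id!r}: need exactly 2 arms, got {arms}")
        for arm in arms:
            if sum(r.arm == arm for r in self.records) < 2:
                raise ValueError(f"dataset {self.id!r}: arm {arm!r} has < 2 records")

    @property
    def arms(self) -> tuple[str, str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.arm, None)
        return tuple(seen)  # type: ignore[return-value]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self, scale: OrdinalScale | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "arm": [r.arm for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "diabetes": [r.diabetes for r in self.records],
                "event": [r.event for r in self.records],
                "fatal": [r.fatal for r in self.records],
                "severity_attr": [r.severity_attr for r in self.records],
                "time": [r.time for r in self.records],
                "observed": [r.observed for r in self.records],
            }
        )
        if scale is not None:
            df["level"] = [scale.level_of(r) for r in self.records]
        return df


def ordinalise(record: ParticipantRecord, scale: OrdinalScale) -> int:
    """Map a participant to a level index on ``scale`` (0 = none)."""
    return scale.level_of(record)


def collapse_to_binary(level: int, scale: OrdinalScale, mode: str = "any_event") -> int:
    """Collapse an ordinal level back to a dichotomy.

    ``any_event`` dichotomises at none-vs-anything; ``fatal_only`` keeps only
    the top (fatal) category as an event.
    """
    if not 0 <= level <= scale.fatal_level:
        raise IndexError(f"level {level} out of range for scale {scale.name!r}")
    if mode == "any_event":
        return int(level > 0)
    if mode == "fatal_only":
        return int(level == scale.fatal_level)
    raise ValueError(f"unknown collapse mode {mode!r}")


def expand_comparisons(
    records_by_arm: Mapping[str, Sequence[ParticipantRecord]],
    plan: Sequence[tuple[str, str]],
    id_prefix: str = "cmp",
    tags: Mapping[str, str] | None = None,
) -> list[ComparatorDataset]:
    """Expand a (possibly multi-arm) trial into two-arm comparator datasets.

    Each plan pair (treatment arm, control arm) yields one dataset with the
    arms relabelled ``treatment``/``control``.  Relabelled record lists are
    built once per (source arm, role) so a control arm shared by several
    comparisons is shared by reference, as in factorial trials.
    """
    for t_arm, c_arm in plan:
        if t_arm == c_arm:
            raise ValueError(f"degenerate comparison pair ({t_arm!r}, {t_arm!r})")
        for arm in (t_arm, c_arm):
            if arm not in records_by_arm:
                raise KeyError(f"unknown arm {arm!r} in comparison plan")

    relabelled: dict[tuple[str, str], list[ParticipantRecord]] = {}

    def _role_records(arm: str, role: str) -> list[ParticipantRecord]:
        key = (arm, role)
        if key not in relabelled:
            relabelled[key] = [replace(r, arm=role) for r in records_by_arm[arm]]
        return relabelled[key]

    out = []
    for i, (t_arm, c_arm) in enumerate(plan, start=1):
        recs = _role_records(t_arm, TREATMENT) + _role_records(c_arm, CONTROL)
        out.append(
            ComparatorDataset(
                id=f"{id_prefix}_{i}_{t_arm}_vs_{c_arm}",
                records=recs,
                tags=dict(tags or {}),
            )
        )
    return out


# ---------------------------------------------------------------------------
# File formats: participant CSV, scale YAML
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("arm", "age", "sex", "diabetes", "event")
_OPTIONAL_COLS = ("fatal", "severity_attr", "time", "observed")


def read_participants_csv(path) -> list[ParticipantRecord]:
    """Read participant records from a UTF-8 comma-delimited file.

    Booleans are coded 0/1.  ``time``/``observed`` may be absent (then
    time-to-event methods are skipped downstream).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"participant file missing required columns: {missing}")
    records = []
    has = {c: c in df.columns for c in _OPTIONAL_COLS}
    for row in df.itertuples(index=False):
        attr = getattr(row, "severity_attr", None) if has["severity_attr"] else None
        if pd.isna(attr):
            attr = None
        time = getattr(row, "time", None) if has["time"] else None
        if time is not None and pd.isna(time):
            time = None
        obs = getattr(row, "observed", None) if has["observed"] else None
        if obs is not None and pd.isna(obs):
            obs = None
        records.append(
            ParticipantRecord(
                arm=str(row.arm),
                age=float(row.age),
                sex=int(row.sex),
                diabetes=int(row.diabetes),
                event=int(row.event),
                fatal=int(getattr(row, "fatal", 0)) if has["fatal"] else 0,
                severity_attr=attr,
                time=float(time) if time is not None else None,
                observed=int(obs) if obs is not None else None,
            )
        )
    return records


def write_participants_csv(records: Iterable[ParticipantRecord], path) -> None:
    recs = list(records)
    df = pd.DataFrame(
        {
            "arm": [r.arm for r in recs],
            "age": [r.age for r in recs],
            "sex": [r.sex for r in recs],
            "diabetes": [r.diabetes for r in recs],
            "event": [r.event for r in recs],
            "fatal": [r.fatal for r in recs],
            "severity_attr": [r.severity_attr for r in recs],
            "time": [r.time for r in recs],
            "observed": [r.observed for r in recs],
        }
    )
    df.to_csv(path, index=False)


def dataset_from_frame(df: pd.DataFrame, id: str, tags=None) -> ComparatorDataset:
    import io as _io

    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return ComparatorDataset(id=id, records=read_participants_csv(buf), tags=dict(tags or {}))


def load_scale_yaml(path_or_stream) -> OrdinalScale:
    if hasattr(path_or_stream, "read"):
        spec = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            spec = yaml.safe_load(fh)
    return OrdinalScale(
        name=spec["name"],
        levels=tuple(spec["levels"]),
        mapping=dict(spec.get("mapping", {})),
        nonfatal_default=spec.get("nonfatal_default"),
    )


def dump_scale_yaml(scale: OrdinalScale, path) -> None:
    spec = {
        "name": scale.name,
        "levels": list(scale.levels),
        "mapping": dict(scale.mapping),
        "nonfatal_default": scale.nonfatal_default,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)


def _mk(name: str, levels: Sequence[str], mapping=None, default=None) -> OrdinalScale:
    return OrdinalScale(name, tuple(levels), dict(mapping or {}), default)


#: Built-in severity scales.  The intermediate labels of the 5+-level variants
#: are generic severity grades; real analyses can supply their own YAML
#: definitions instead.
DEFAULT_SCALES: dict[str, OrdinalScale] = {
    s.name: s
    for s in [
        _mk("stroke3", ["none", "nonfatal stroke", "fatal stroke"],
            {"nonfatal": 1}, default=1),
        _mk("strokeTIA4", ["none", "TIA", "nonfatal stroke", "fatal stroke"],
            {"TIA": 1, "nonfatal": 2}, default=2),
        _mk("stroke5", ["none", "mild", "moderate", "severe", "fatal stroke"],
            {"mild": 1, "moderate": 2, "severe": 3}, default=2),
        _mk("stroke8",
            ["none", "grade1", "grade2", "grade3", "grade4", "grade5", "grade6",
             "fatal stroke"],
            {f"grade{i}": i for i in range(1, 7)}, default=3),
        _mk("mi3", ["none", "nonfatal MI", "fatal MI"], {"nonfatal": 1}, default=1),
        _mk("bleed3", ["none", "major", "fatal bleed"], {"major": 1}, default=1),
        _mk("bleed4", ["none", "minor", "major", "fatal bleed"],
            {"minor": 1, "major": 2}, default=2),
        _mk("bleed5", ["none", "mild", "moderate", "severe", "fatal bleed"],
            {"mild": 1, "moderate": 2, "severe": 3}, default=2),
        _mk("vascular3", ["none", "nonfatal stroke or MI", "fatal stroke or MI"],
            {"nonfatal": 1}, default=1),
    ]
}


def get_scale(name_or_scale) -> OrdinalScale:
    """Resolve a scale name (built-in registry) or pass a scale through."""
    if isinstance(name_or_scale, OrdinalScale):
        return name_or_scale
    try:
        return DEFAULT_SCALES[name_or_scale]
    except KeyError:
        raise KeyError(
            f"unknown scale {name_or_scale!r}; built-ins: {sorted(DEFAULT_SCALES)}"
        ) from None
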