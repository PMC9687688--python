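"""Per-subject descriptive-statistic features from keystroke logs.

Each subject's event stream is reduced to a fixed-width numeric vector by
computing a family of descriptive statistics (mean, standard deviation,
excess kurtosis, skewness and seven percentiles) over each timing series
(hold, latency, flight), restricted to groups of events: hold times are
grouped by keyboard region (all / L / R / S), latency and flight times by
region transition (all / LL / LR / RL / RR).  Three left-right asymmetry
contrasts and the total event count complete the vector; motor asymmetry is
a recognised early sign of Parkinson's disease, which is what the
difference features target.

The schema is configuration-driven: the vector width is a pure function of
the grouping configuration, never of the log content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import json
import numpy as np
from scipy import stats as _sstats

from .tappy_io import FeatureMatrix, SubjectLog

__all__ = [
    "STATISTICS",
    "SchemaEntry",
    "FeatureSchema",
    "build_schema",
    "extract_features",
    "extract_matrix",
]

#: Statistic family applied to every (series, group) pair, in schema order.
STATISTICS = (
    "mean",
    "std",
    "kurtosis",
    "skew",
    "p10",
    "p20",
    "p40",
    "p60",
    "p70",
    "p80",
    "p90",
)

_SERIES_ATTR = {"hold": "hold_time", "latency": "latency", "flight": "flight"}

#: Contrast features: name -> (series, group_a, group_b); value is
#: mean(series | group_a) - mean(series | group_b).
_DIFFERENCES = {
    "diff_LR_hold_mean": ("hold", "L", "R"),
    "diff_LRRL_latency_mean": ("latency", "LR", "RL"),
    "diff_LLRR_latency_mean": ("latency", "LL", "RR"),
}


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    series: str | None  # None for special entries
    group: str | None  # "ALL", a region, a transition, or None
    statistic: str  # one of STATISTICS, "count" or "diff"


@dataclass(frozen=True)
class FeatureSchema:
    entries: tuple[SchemaEntry, ...]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        """Ordered name list as a JSON sidecar so CSVs are self-describing."""
        return json.dumps(self.names)


#: Default grouping: hold by region, latency/flight by the four L/R
#: transitions.  Space-bar transitions are rare enough that their statistics
#: would mostly be imputation noise, so they are not expanded by default.
_DEFAULT_GROUPS = {
    "hold": ("ALL", "L", "R", "S"),
    "latency": ("ALL", "LL", "LR", "RL", "RR"),
    "flight": ("ALL", "LL", "LR", "RL", "RR"),
}


def build_schema(groups: dict[str, Sequence[str]] | None = None) -> FeatureSchema:
    """Build the deterministic ordered feature schema.

    Parameters
    ----------
    groups
        Mapping series name -> group selectors.  Hold-time groups are
        regions, latency/flight groups are transitions; ``"ALL"`` selects
        every event.  Defaults to :data:`_DEFAULT_GROUPS`, which yields
        3 series x 11 statistics over 4+5+5 groups = 154 entries, plus
        the total event count and three asymmetry contrasts (158 total).
    """
    groups = dict(_DEFAULT_GROUPS if groups is None else groups)
    if not groups or any(len(g) == 0 for g in groups.values()):
        raise ValueError("group selection must be non-empty for every series")
    unknown = set(groups) - set(_SERIES_ATTR)
    if unknown:
        raise ValueError(f"unknown series {sorted(unknown)}")
    entries: list[SchemaEntry] = []
    for series in ("hold", "latency", "flight"):
        for grp in groups.get(series, ()):
            for stat in STATISTICS:
                entries.append(
                    SchemaEntry(f"{series}_{grp}_{stat}", series, grp, stat)
                )
    entries.append(SchemaEntry("total_count", None, None, "count"))
    for name in _DIFFERENCES:
        entries.append(SchemaEntry(name, None, None, "diff"))
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in schema")
    return FeatureSchema(entries=tuple(entries))


def _series_values(log: SubjectLog, series: str, group: str) -> np.ndarray:
    attr = _SERIES_ATTR[series]
    if group == "ALL":
        sel = log.events
    elif len(group) == 1:  # region selector
        sel = [ev for ev in log.events if ev.region == group]
    else:  # transition selector
        sel = [ev for ev in log.events if ev.transition == group]
    return np.array([getattr(ev, attr) for ev in sel], dtype=float)


def _statistic(values: np.ndarray, stat: str) -> float:
    """One descriptive statistic with defined degenerate-case conventions.

    Sample std (ddof=1, 0 if n < 2); Fisher excess kurtosis and standardised
    skewness are imputed to 0 for n < 4 or zero variance; percentiles use
    linear interpolation between order statistics.
    """
    n = values.size
    if n == 0:
        return 0.0
    if stat == "mean":
        return float(np.mean(values))
    if stat == "std":
        return float(np.std(values, ddof=1)) if n >= 2 else 0.0
    if stat in ("kurtosis", "skew"):
        if n < 4 or np.var(values) == 0.0:
            return 0.0
        if stat == "kurtosis":
            return float(_sstats.kurtosis(values, fisher=True, bias=True))
        return float(_sstats.skew(values, bias=True))
    if stat.startswith("p"):
        return float(np.percentile(values, int(stat[1:]), method="linear"))
    raise ValueError(f"unknown statistic {stat!r}")


def extract_features(log: SubjectLog, schema: FeatureSchema) -> np.ndarray:
    """Compute one subject's feature vector under ``schema``.

    Empty groups produce 0-imputed statistics so the vector width never
    depends on which regions a subject happened to use.
    """
    if not log.events:
        raise ValueError("log has no events")
    out = np.empty(len(schema), dtype=float)
    cache: dict[tuple[str, str], np.ndarray] = {}

    def values_for(series: str, group: str) -> np.ndarray:
        key = (series, group)
        if key not in cache:
            cache[key] = _series_values(log, series, group)
        return cache[key]

    for i, entry in enumerate(schema.entries):
        if entry.statistic == "count":
            out[i] = float(len(log.events))
        elif entry.statistic == "diff":
            series, ga, gb = _DIFFERENCES[entry.name]
            va, vb = values_for(series, ga), values_for(series, gb)
            ma = float(np.mean(va)) if va.size else 0.0
            mb = float(np.mean(vb)) if vb.size else 0.0
            out[i] = ma - mb
        else:
            out[i] = _statistic(values_for(entry.series, entry.group), entry.statistic)
    return out


def extract_matrix(
    logs: Sequence[SubjectLog], schema: FeatureSchema | None = None
) -> FeatureMatrix:
    """Stack per-subject feature vectors into a :class:`FeatureMatrix`.

    Row order equals input order; labels and subject ids stay aligned.
    """
    if len(logs) == 0:
        raise ValueError("need at least one log")
    if schema is None:
        schema = build_schema()
    values = np.vstack([extract_features(log, schema) for log in logs])
    return FeatureMatrix(
        values=values,
        column_names=schema.names,
        labels=np.array([log.label for log in logs], dtype=object),
        subject_ids=np.array([log.subject_id for log in logs], dtype=object),
    )
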