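"""Group-wise trait workflow: load, filter, invert, exclude outliers, compare.

The workflow mirrors a standard intraspecific-trait-variation (ITV)
analysis of a ratio-type trait such as specific leaf area (SLA): a
long-format table of (species, value) records is filtered to species
with enough records, the reciprocal trait (e.g. LMA = 1/SLA) is derived
record-wise, the four relative-variation measures are computed per
species for both orientations, and the two orientations are compared in
absolute value and in species rank.  A Tukey-fence outlier pass allows
repeating the analysis without extreme records, and a correlation table
summarises how much each measure is perturbed by the exclusion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DomainError,
    EmptyResultError,
    InsufficientDataError,
)
from .measures import (
    DEFAULT_QUANTILE_METHOD,
    MEASURE_NAMES,
    MeasureSet,
    measure_set,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TraitTable",
    "GroupMeasures",
    "InverseComparisonReport",
    "OutlierRule",
    "CorrelationTable",
    "load_trait_table",
    "filter_min_n",
    "invert_values",
    "complement_proportion",
    "exclude_outliers",
    "group_measures",
    "measures_frame",
    "rank_groups",
    "compare_with_inverse",
    "correlation_table",
]

GROUP_COL = "group"
VALUE_COL = "value"


@dataclass(frozen=True)
class TraitTable:
    """Long-format trait records: one row per (group, positive value)."""

    data: pd.DataFrame = field(repr=False)
    trait_name: str = "trait"
    unit: str = ""

    def __post_init__(self) -> None:
        missing = {GROUP_COL, VALUE_COL} - set(self.data.columns)
        if missing:
            raise ConfigurationError(f"trait table missing columns {missing}")
        if len(self.data) and not (self.data[VALUE_COL] > 0).all():
            raise DomainError("trait table contains non-positive values")

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data[GROUP_COL].unique())

    @property
    def n_groups(self) -> int:
        return self.data[GROUP_COL].nunique()

    def group_sizes(self) -> pd.Series:
        return self.data.groupby(GROUP_COL, sort=True)[VALUE_COL].size()

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, float]],
                     trait_name: str = "trait", unit: str = "") -> "TraitTable":
        df = pd.DataFrame(records, columns=[GROUP_COL, VALUE_COL])
        return cls(data=df, trait_name=trait_name, unit=unit)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=True, index_label="record_id")


@dataclass(frozen=True)
class GroupMeasures:
    """Per-group measures for a trait and its record-wise reciprocal."""

    group_id: str
    n: int
    measures: MeasureSet
    measures_inverse: MeasureSet


@dataclass(frozen=True)
class OutlierRule:
    """Per-group outlier exclusion rule.

    ``tukey-fences`` removes records outside [Q1 - k*IQR, Q3 + k*IQR]
    computed on the group's raw primary-trait values; ``none`` is a
    no-op.  The reciprocal trait is always recomputed from the retained
    records, never screened independently, so both orientations see the
    same record set.
    """

    method: str = "tukey-fences"
    k: float = 1.5

    def __post_init__(self) -> None:
        if self.method not in ("tukey-fences", "none"):
            raise ConfigurationError(f"unknown outlier method {self.method!r}")
        if self.k <= 0:
            raise ConfigurationError("fence multiplier k must be > 0")


def load_trait_table(source, group_column: str, value_column: str,
                     trait_name: str | None = None,
                     unit: str = "") -> TraitTable:
    """Read a long-format CSV into a validated :class:`TraitTable`.

    Missing values (empty cells / NA tokens) and non-positive values are
    dropped with a logged count.  A non-numeric token in the value column
    is an error naming the offending row.
    """
    df = pd.read_csv(source)
    missing = {group_column, value_column} - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"input is missing column(s) {sorted(missing)}; "
            f"available: {list(df.columns)}"
        )
    raw = df[value_column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & values.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise DomainError(
            f"value column {value_column!r} has non-numeric token "
            f"{raw[row]!r} at row {row}"
        )
    out = pd.DataFrame({
        GROUP_COL: df[group_column].astype(str),
        VALUE_COL: values,
    })
    n_missing = int(out[VALUE_COL].isna().sum())
    out = out.dropna(subset=[VALUE_COL])
    n_nonpos = int((out[VALUE_COL] <= 0).sum())
    out = out[out[VALUE_COL] > 0]
    if n_missing or n_nonpos:
        logger.warning(
            "load_trait_table: dropped %d missing and %d non-positive values",
            n_missing, n_nonpos,
        )
    if out.empty:
        raise EmptyResultError("no usable records after validation")
    logger.info("load_trait_table: %d records, %d groups",
                len(out), out[GROUP_COL].nunique())
    return TraitTable(data=out.reset_index(drop=True),
                      trait_name=trait_name or value_column, unit=unit)


def filter_min_n(table: TraitTable, min_n: int = 10) -> TraitTable:
    """Keep only groups with at least ``min_n`` records (default 10)."""
    if min_n < 2:
        raise ConfigurationError("min_n must be at least 2")
    sizes = table.group_sizes()
    keep = sizes.index[sizes >= min_n]
    out = table.data[table.data[GROUP_COL].isin(keep)]
    logger.info("filter_min_n(%d): kept %d of %d groups",
                min_n, len(keep), len(sizes))
    if out.empty:
        raise EmptyResultError(
            f"no group has at least {min_n} records (max is {sizes.max()})"
        )
    return TraitTable(data=out, trait_name=table.trait_name, unit=table.unit)


def _invert_unit(unit: str) -> str:
    if not unit:
        return unit
    if "/" in unit:
        num, _, den = unit.partition("/")
        return f"{den.strip()}/{num.strip()}"
    return f"1/{unit}"


def invert_values(table: TraitTable) -> TraitTable:
    """Record-wise reciprocal trait (e.g. LMA_i = 1/SLA_i)."""
    data = table.data.copy()
    data[VALUE_COL] = 1.0 / data[VALUE_COL]
    return TraitTable(data=data,
                      trait_name=f"{table.trait_name}_inverse",
                      unit=_invert_unit(table.unit))


def complement_proportion(table: TraitTable) -> TraitTable:
    """Record-wise complement 1 - p of a proportion-valued trait.

    The complement has the same SD and IQR as the proportion itself, but
    a different mean and quartile sum — so every relative-variation
    measure, including cv_q, legitimately differs between a proportion
    and its complement.  Requires all values strictly inside (0, 1).
    """
    v = table.data[VALUE_COL]
    if not ((v > 0) & (v < 1)).all():
        raise DomainError("complement requires all values strictly in (0, 1)")
    data = table.data.copy()
    data[VALUE_COL] = 1.0 - v
    return TraitTable(data=data,
                      trait_name=f"{table.trait_name}_complement",
                      unit=table.unit)


def exclude_outliers(table: TraitTable,
                     rule: OutlierRule = OutlierRule()) -> TraitTable:
    """Remove per-group outliers by Tukey fences on the raw trait values.

    Groups left with fewer than 2 records are dropped with a warning.
    """
    if rule.method == "none":
        return table
    kept_parts: list[pd.DataFrame] = []
    n_removed = 0
    n_dropped_groups = 0
    for gid, sub in table.data.groupby(GROUP_COL, sort=True):
        v = sub[VALUE_COL].to_numpy()
        q1, q3 = np.quantile(v, [0.25, 0.75], method=DEFAULT_QUANTILE_METHOD)
        iqr = q3 - q1
        lo, hi = q1 - rule.k * iqr, q3 + rule.k * iqr
        inside = (v >= lo) & (v <= hi)
        n_removed += int((~inside).sum())
        retained = sub[inside]
        if len(retained) < 2:
            n_dropped_groups += 1
            logger.warning(
                "exclude_outliers: group %r reduced to %d record(s); dropped",
                gid, len(retained),
            )
            continue
        kept_parts.append(retained)
    if not kept_parts:
        raise EmptyResultError("outlier exclusion removed every group")
    if n_removed:
        logger.info("exclude_outliers: removed %d record(s), dropped %d group(s)",
                    n_removed, n_dropped_groups)
    return TraitTable(data=pd.concat(kept_parts),
                      trait_name=table.trait_name, unit=table.unit)


def group_measures(table: TraitTable,
                   method: str = DEFAULT_QUANTILE_METHOD
                   ) -> list[GroupMeasures]:
    """All four measures per group, for the trait and its reciprocal."""
    out: list[GroupMeasures] = []
    for gid, sub in table.data.groupby(GROUP_COL, sort=True):
        v = sub[VALUE_COL].to_numpy()
        try:
            out.append(GroupMeasures(
                group_id=str(gid),
                n=len(v),
                measures=measure_set(v, method=method),
                measures_inverse=measure_set(1.0 / v, method=method),
            ))
        except (DomainError, InsufficientDataError) as exc:
            raise type(exc)(f"group {gid!r}: {exc}") from exc
    return out


def measures_frame(gms: list[GroupMeasures]) -> pd.DataFrame:
    """Flatten group measures to a frame indexed by group.

    Columns: ``n``, the four measures, and the four ``*_inverse``
    counterparts computed on the record-wise reciprocals.
    """
    rows = {}
    for gm in gms:
        row: dict[str, float] = {"n": gm.n}
        row.update(gm.measures.as_dict())
        row.update({f"{k}_inverse": v
                    for k, v in gm.measures_inverse.as_dict().items()})
        rows[gm.group_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = GROUP_COL
    return df


def rank_groups(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Ascending ranks (1..n); ties get the average rank."""
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise InsufficientDataError("nothing to rank")
    return pd.Series(stats.rankdata(s.to_numpy(), method="average"),
                     index=s.index)


@dataclass(frozen=True)
class InverseComparisonReport:
    """Per-measure comparison of a trait against its reciprocal.

    ``per_measure[m]`` has one row per group with columns ``value``,
    ``value_inverse``, ``abs_diff``, ``rank``, ``rank_inverse``,
    ``abs_rank_diff``; ``aggregates[m]`` summarises them.
    """

    per_measure: dict[str, pd.DataFrame] = field(repr=False)
    aggregates: dict[str, dict[str, float]]
    n_groups: int

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {"n_groups": self.n_groups, "aggregates": self.aggregates},
            indent=indent, sort_keys=True,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat frame: one row per group x measure."""
        parts = []
        for name, df in self.per_measure.items():
            part = df.copy()
            part.insert(0, "measure", name)
            parts.append(part.reset_index())
        return pd.concat(parts, ignore_index=True)


def compare_with_inverse(gms: list[GroupMeasures]) -> InverseComparisonReport:
    """Compare each measure between the trait and its reciprocal.

    For every measure: per-group absolute difference, group ranks under
    both orientations (ascending, average ties) and absolute rank
    difference; aggregated into the maximum absolute difference, the
    maximum rank shift, and the number of groups whose rank is unchanged.
    """
    if len(gms) < 2:
        raise InsufficientDataError("need at least 2 groups to compare")
    frame = measures_frame(gms)
    per_measure: dict[str, pd.DataFrame] = {}
    aggregates: dict[str, dict[str, float]] = {}
    for name in MEASURE_NAMES:
        value = frame[name]
        value_inv = frame[f"{name}_inverse"]
        rank = rank_groups(value)
        rank_inv = rank_groups(value_inv)
        df = pd.DataFrame({
            "value": value,
            "value_inverse": value_inv,
            "abs_diff": (value - value_inv).abs(),
            "rank": rank,
            "rank_inverse": rank_inv,
            "abs_rank_diff": (rank - rank_inv).abs(),
        })
        per_measure[name] = df
        aggregates[name] = {
            "max_abs_diff": float(df["abs_diff"].max()),
            "max_abs_rank_diff": float(df["abs_rank_diff"].max()),
            "n_same_rank": int((df["abs_rank_diff"] == 0).sum()),
            "n_groups": len(df),
        }
    return InverseComparisonReport(per_measure=per_measure,
                                   aggregates=aggregates,
                                   n_groups=len(frame))


@dataclass(frozen=True)
class CorrelationTable:
    """Correlations among measures, with and without outlier exclusion.

    ``pearson_with`` etc. are measure-by-measure matrices computed across
    groups; ``with_vs_without`` correlates, per measure, the group values
    obtained with and without exclusion (a robustness summary: a measure
    insensitive to outliers correlates near 1 with itself across the two
    regimes).
    """

    pearson_with: pd.DataFrame
    pearson_without: pd.DataFrame
    spearman_with: pd.DataFrame
    spearman_without: pd.DataFrame
    with_vs_without: pd.DataFrame
    n_groups: int


def correlation_table(with_excl: pd.DataFrame,
                      without_excl: pd.DataFrame) -> CorrelationTable:
    """Build the correlation summary from two group-by-measure frames.

    Inputs are frames indexed by group with (at least) the four measure
    columns, e.g. from :func:`measures_frame`; the group intersection is
    used, and fewer than 3 common groups is an error.
    """
    common = with_excl.index.intersection(without_excl.index)
    n_lost = max(len(with_excl), len(without_excl)) - len(common)
    if n_lost:
        logger.warning("correlation_table: %d group(s) not in both inputs",
                       n_lost)
    if len(common) < 3:
        raise InsufficientDataError(
            f"need at least 3 common groups, got {len(common)}"
        )
    w = with_excl.loc[common, list(MEASURE_NAMES)]
    wo = without_excl.loc[common, list(MEASURE_NAMES)]
    wvw = pd.DataFrame(
        {
            "pearson": {m: float(stats.pearsonr(w[m], wo[m])[0])
                        for m in MEASURE_NAMES},
            "spearman": {m: float(stats.spearmanr(w[m], wo[m])[0])
                         for m in MEASURE_NAMES},
        }
    ).loc[list(MEASURE_NAMES)]
    return CorrelationTable(
        pearson_with=w.corr(method="pearson"),
        pearson_without=wo.corr(method="pearson"),
        spearman_with=w.corr(method="spearman"),
        spearman_without=wo.corr(method="spearman"),
        with_vs_without=wvw,
        n_groups=len(common),
    )
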