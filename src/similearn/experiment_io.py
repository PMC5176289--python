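"""Reading and validating choice-record tables.

The canonical in-memory object is a tidy :class:`pandas.DataFrame` with the
columns in :data:`similearn.experiment_sim.TRIAL_COLUMNS`. Deposited raw
files may use other column names, delimiters and codes, so reading goes
through a small declarative :class:`RawDataDialect` (a column map plus value
recodings) followed by strict validation — unmappable content raises a
descriptive :class:`ParseError` naming the offending row/column rather than
being coerced silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .experiment_sim import TRIAL_COLUMNS, URNS

__all__ = ["ParseError", "RawDataDialect", "read_raw", "write_trials", "validate_trials"]

REQUIRED_COLUMNS = TRIAL_COLUMNS
ROLES = ("demonstrator", "social_learner")
SIMILARITIES = ("discordant", "concordant")
DESIGNS = ("within", "between", "opaque_prior", "opaque_noprior")


class ParseError(ValueError):
    """Raised when a raw table cannot be mapped onto the canonical schema."""


@dataclass(frozen=True)
class RawDataDialect:
    """How to interpret a raw delimited text file.

    ``column_map`` maps source column names to canonical names (must cover
    every canonical column); ``value_maps`` maps canonical column names to
    {source value -> canonical value} recodings applied after renaming.
    The default dialect is the identity: canonical names, tab-separated.
    """

    delimiter: str = "\t"
    column_map: Mapping[str, str] = field(default_factory=dict)
    value_maps: Mapping[str, Mapping[object, object]] = field(default_factory=dict)

    def missing_targets(self, columns: list[str]) -> list[str]:
        renamed = [self.column_map.get(c, c) for c in columns]
        return [c for c in REQUIRED_COLUMNS if c not in renamed]


DEFAULT_DIALECT = RawDataDialect()


def read_raw(
    path: str | Path, dialect: RawDataDialect = DEFAULT_DIALECT
) -> pd.DataFrame:
    """Read a raw delimited text file into the validated canonical table."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: cannot parse as delimited text: {exc}") from exc
    missing = dialect.missing_targets(list(raw.columns))
    if missing:
        raise ParseError(
            f"{path}: columns {missing} are not provided by the file under the "
            f"given dialect (source columns: {list(raw.columns)})"
        )
    df = raw.rename(columns=dict(dialect.column_map))
    for col, mapping in dialect.value_maps.items():
        unmapped = set(df[col].unique()) - set(mapping)
        if unmapped:
            bad = sorted(map(str, unmapped))[0]
            row = int(df.index[df[col].astype(str) == bad][0]) if bad else 0
            raise ParseError(
                f"{path}: column {col!r} has unmappable code(s) {sorted(map(str, unmapped))} "
                f"(first at row {row})"
            )
        df[col] = df[col].map(mapping)
    df = df[list(REQUIRED_COLUMNS)]
    validate_trials(df, source=str(path))
    return df


def write_trials(table: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a canonical table as delimited UTF-8 text (default CSV)."""
    validate_trials(table)
    table[list(REQUIRED_COLUMNS)].to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def _fail(source: str, message: str) -> None:
    raise ParseError(f"{source}: {message}")


def validate_trials(table: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a canonical table against the experimental design.

    Checks schema, category codes, per-role row counts (5 trials per
    demonstrator-block, 1 per social-learner-block, 20 block rows per social
    learner in within-subjects-style sessions) and that urn assignments are
    constant within a group-block with the discordant/concordant relation
    between the demonstrator and social optima. Returns the table.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        _fail(source, f"missing required columns {missing}")
    for col, allowed in (
        ("role", ROLES),
        ("similarity", SIMILARITIES),
        ("design", DESIGNS),
        ("urn_chosen", URNS),
        ("demo_optimal_urn", URNS),
        ("social_optimal_urn", URNS),
    ):
        bad = set(table[col].unique()) - set(allowed)
        if bad:
            row = table.index[table[col].isin(bad)][0]
            _fail(source, f"column {col!r}: invalid code(s) {sorted(map(str, bad))} (first at row {row})")

    grouped = table.groupby(["session", "group", "block"], sort=False)
    for (sess, grp, blk), sub in grouped:
        where = f"session {sess}, group {grp}, block {blk}"
        for col in ("demo_optimal_urn", "social_optimal_urn", "similarity"):
            if sub[col].nunique() != 1:
                _fail(source, f"{where}: column {col!r} varies within a block")
        concordant = sub["similarity"].iloc[0] == "concordant"
        same_urn = sub["demo_optimal_urn"].iloc[0] == sub["social_optimal_urn"].iloc[0]
        if concordant != same_urn:
            _fail(source, f"{where}: similarity label inconsistent with optimal urns")
        demo = sub[sub["role"] == "demonstrator"]
        n_trials = demo["trial"].nunique()
        per_demo = demo.groupby("subject").size()
        if len(per_demo) and not (per_demo == n_trials).all():
            _fail(source, f"{where}: demonstrators do not have one row per trial")
        social = sub[sub["role"] == "social_learner"]
        per_social = social.groupby("subject").size()
        if len(per_social) and not (per_social == 1).all():
            _fail(source, f"{where}: social learners must have exactly one row per block")

    # within-subjects-style sessions: every social learner sees all 20 blocks
    social = table[table["role"] == "social_learner"]
    for design in ("within", "opaque_prior", "opaque_noprior"):
        sub = social[social["design"] == design]
        if len(sub) == 0:
            continue
        counts = sub.groupby(["session", "group", "subject"])["block"].nunique()
        per_group_blocks = sub.groupby(["session", "group"])["block"].nunique()
        for (sess, grp), nb in per_group_blocks.items():
            c = counts.loc[sess, grp]
            short = c[c != nb]
            if len(short):
                _fail(
                    source,
                    f"session {sess}, group {grp}: social learner(s) "
                    f"{list(short.index)} have {sorted(set(short))} block rows, expected {nb}",
                )
    return table
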