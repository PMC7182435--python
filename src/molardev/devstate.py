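"""The four-character developmental scoring system and its state space.

Each tooth-germ sample is scored for four ordinal characters — Shh
expression at the rudimentary premolar bud R2, Shh expression at the first
molar (M1) signaling center, progression of the bud-to-cap transition, and
the epithelial protuberance at the R2 site. The first three admit three
states and the last two, so combining them spans a theoretical space of
3*3*3*2 = 54 developmental states, of which real cohorts occupy only a
small subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ScoringSchema",
    "DevState",
    "StateCensus",
    "DEFAULT_SCHEMA",
    "SCORE_COLUMNS",
    "enumerate_state_space",
    "census_states",
    "exclusive_states",
    "parse_state_name",
]

# CSV column carrying each character's score
SCORE_COLUMNS = {
    "r2_shh": "score_r2shh",
    "m1_shh": "score_m1shh",
    "cap_transition": "score_cap",
    "r2_protuberance": "score_protub",
}


@dataclass(frozen=True)
class ScoringSchema:
    """Ordered characters with their allowed state counts (2 or 3 each)."""

    characters: tuple[tuple[str, int], ...] = (
        ("r2_shh", 3),
        ("m1_shh", 3),
        ("cap_transition", 3),
        ("r2_protuberance", 2),
    )

    def __post_init__(self) -> None:
        if len(self.characters) == 0:
            raise ValueError("schema must have at least one character")
        for name, size in self.characters:
            if size not in (2, 3):
                raise ValueError(f"character {name!r}: size must be 2 or 3, got {size}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.characters)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(size for _, size in self.characters)

    @property
    def columns(self) -> tuple[str, ...]:
        """Score column names, falling back to score_<name> for custom characters."""
        return tuple(SCORE_COLUMNS.get(name, f"score_{name}") for name in self.names)

    @property
    def n_states(self) -> int:
        n = 1
        for s in self.sizes:
            n *= s
        return n

    @property
    def max_distance(self) -> int:
        return sum(s - 1 for s in self.sizes)


DEFAULT_SCHEMA = ScoringSchema()


@dataclass(frozen=True, order=True)
class DevState:
    """One point of the developmental state space: a tuple of ordinal scores."""

    scores: tuple[int, ...]

    def validate(self, schema: ScoringSchema) -> None:
        if len(self.scores) != len(schema.characters):
            raise ValueError(
                f"state has {len(self.scores)} scores, schema has "
                f"{len(schema.characters)} characters"
            )
        for s, (name, size) in zip(self.scores, schema.characters):
            if not 0 <= s < size:
                raise ValueError(f"score {s} out of range for character {name!r}")


@dataclass
class StateCensus:
    """Observed states of one cohort, ordered by mean embryo weight.

    ``table`` has one row per observed state with columns: name, count,
    mean_weight_mg, the score columns, and strains (comma-joined set of
    strains exhibiting the state).
    """

    schema: ScoringSchema
    table: pd.DataFrame

    @property
    def states(self) -> set[DevState]:
        cols = list(self.schema.columns)
        return {
            DevState(tuple(int(v) for v in row)) for row in self.table[cols].to_numpy()
        }


def enumerate_state_space(schema: ScoringSchema) -> list[DevState]:
    """All theoretically possible states, in lexicographic order."""
    return [
        DevState(scores)
        for scores in itertools.product(*(range(s) for s in schema.sizes))
    ]


def state_name(mean_weight: float, scores: tuple[int, ...]) -> str:
    """Canonical state name: zero-padded integer mean weight then the scores,
    e.g. ``097_0_0_0_0``."""
    return "_".join([f"{round(mean_weight):03d}", *(str(s) for s in scores)])


def parse_state_name(name: str) -> tuple[int, tuple[int, ...]]:
    """Invert :func:`state_name`: (mean weight mg, score tuple)."""
    parts = name.split("_")
    return int(parts[0]), tuple(int(p) for p in parts[1:])


def census_states(embryos: pd.DataFrame, schema: ScoringSchema = DEFAULT_SCHEMA) -> StateCensus:
    """Group scored embryos by developmental state.

    States are named by the mean weight of their embryos followed by the
    four scores, and ordered by mean weight ascending (ties broken
    lexicographically by score tuple).
    """
    cols = list(schema.columns)
    missing = [c for c in cols if c not in embryos.columns] + (
        [] if "weight_mg" in embryos.columns else ["weight_mg"]
    )
    if missing:
        raise ValueError(f"embryo table lacks columns: {missing}")
    for _, row in embryos.iterrows():
        for c, (name, size) in zip(cols, schema.characters):
            v = int(row[c])
            if not 0 <= v < size:
                eid = row.get("embryo_id", "<unknown>")
                raise ValueError(
                    f"embryo {eid}: score {v} out of range for character {name!r}"
                )
    grouped = (
        embryos.groupby(cols, as_index=False)
        .agg(count=("weight_mg", "size"), mean_weight_mg=("weight_mg", "mean"))
    )
    strains = (
        embryos.groupby(cols)["strain"].agg(lambda s: ",".join(sorted(set(s))))
        if "strain" in embryos.columns
        else None
    )
    if strains is not None:
        grouped = grouped.merge(
            strains.rename("strains").reset_index(), on=cols, how="left"
        )
    else:
        grouped["strains"] = ""
    grouped["name"] = [
        state_name(w, tuple(int(v) for v in row))
        for w, row in zip(grouped["mean_weight_mg"], grouped[cols].to_numpy())
    ]
    grouped = grouped.sort_values(
        ["mean_weight_mg", *cols], kind="mergesort"
    ).reset_index(drop=True)
    order = ["name", "count", "mean_weight_mg", *cols, "strains"]
    return StateCensus(schema=schema, table=grouped[order])


def exclusive_states(
    census_a: StateCensus, census_b: StateCensus
) -> tuple[set[DevState], set[DevState], set[DevState]]:
    """Partition the two censuses' states into (A-only, B-only, shared)."""
    if census_a.schema != census_b.schema:
        raise ValueError("censuses were built under different schemas")
    a, b = census_a.states, census_b.states
    return a - b, b - a, a & b
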