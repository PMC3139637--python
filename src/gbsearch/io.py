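"""Readers and writers for the game-log CSV schema, configs and manifests.

Log schema: one CSV row per (game, round, member) with columns
``group_id, group_size, game_index, feedback_mode, target, round, member_id,
guess, group_sum, direction, magnitude`` (magnitude empty when absent),
UTF-8, comma-separated, header row, no index column.  A JSON session header
(:class:`RunManifest`) records configs, seeds and software version so any
run can be replayed bit-exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import (
    Direction,
    FeedbackMode,
    FeedbackSignal,
    GameConfig,
    GameLog,
    RoundRecord,
    SessionConfig,
)

__all__ = [
    "SCHEMA_VERSION",
    "LOG_COLUMNS",
    "SchemaError",
    "write_logs",
    "read_logs",
    "RunManifest",
    "load_config",
    "game_config_from_dict",
    "session_config_from_dict",
]

SCHEMA_VERSION = 1

LOG_COLUMNS = (
    "group_id",
    "group_size",
    "game_index",
    "feedback_mode",
    "target",
    "round",
    "member_id",
    "guess",
    "group_sum",
    "direction",
    "magnitude",
)


class SchemaError(ValueError):
    """A malformed or inconsistent log file; the message names the line."""


def write_logs(logs: list[GameLog], path: str | Path) -> None:
    """Write logs in the flat CSV schema (one row per game, round, member)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for log in logs:
            for rec in log.rounds:
                mag = rec.feedback.magnitude
                for member_id, guess in zip(log.member_ids, rec.guesses):
                    writer.writerow(
                        [
                            log.group_id,
                            log.group_size,
                            log.game_index,
                            str(log.feedback_mode),
                            log.target,
                            rec.round_index,
                            member_id,
                            guess,
                            rec.group_sum,
                            str(rec.feedback.direction),
                            "" if mag is None else mag,
                        ]
                    )


def _parse_row(row: dict, line: int) -> dict:
    try:
        return {
            "group_id": row["group_id"],
            "group_size": int(row["group_size"]),
            "game_index": int(row["game_index"]),
            "feedback_mode": FeedbackMode(row["feedback_mode"]),
            "target": int(row["target"]),
            "round": int(row["round"]),
            "member_id": row["member_id"],
            "guess": int(row["guess"]),
            "group_sum": int(row["group_sum"]),
            "direction": Direction(row["direction"]),
            "magnitude": int(row["magnitude"]) if row["magnitude"] not in ("", None) else None,
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"line {line}: malformed row ({exc})") from exc


def read_logs(path: str | Path) -> list[GameLog]:
    """Read logs from the CSV schema, validating sums and feedback per row.

    Raises :class:`SchemaError` naming the offending line on malformed rows
    or sum mismatches; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty log file", stacklevel=2)
            return []
        missing = set(LOG_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        rows = [_parse_row(row, line) for line, row in enumerate(reader, start=2)]
    if not rows:
        warnings.warn(f"{path}: no log rows", stacklevel=2)
        return []

    logs: list[GameLog] = []
    # Rows arrive grouped by (group, game, round) in writing order; rebuild
    # games in first-appearance order so read(write(x)) == x.
    games: dict[tuple, list[dict]] = {}
    for row in rows:
        games.setdefault((row["group_id"], row["game_index"]), []).append(row)
    line_of = {id(row): line for line, row in zip(range(2, 2 + len(rows)), rows)}
    for (group_id, game_index), game_rows in games.items():
        rounds_map: dict[int, list[dict]] = {}
        for row in game_rows:
            rounds_map.setdefault(row["round"], []).append(row)
        first = game_rows[0]
        records = []
        for r in sorted(rounds_map):
            members = rounds_map[r]
            guesses = tuple(row["guess"] for row in members)
            declared = members[0]["group_sum"]
            if sum(guesses) != declared:
                raise SchemaError(
                    f"line {line_of[id(members[0])]}: group_sum {declared} != "
                    f"sum of guesses {sum(guesses)} "
                    f"(group {group_id}, game {game_index}, round {r})"
                )
            direction = members[0]["direction"]
            magnitude = members[0]["magnitude"]
            expected = first["target"] - declared
            ok = (
                (expected == 0 and direction is Direction.CORRECT)
                or (expected > 0 and direction is Direction.TOO_LOW)
                or (expected < 0 and direction is Direction.TOO_HIGH)
            )
            if not ok:
                raise SchemaError(
                    f"line {line_of[id(members[0])]}: feedback direction "
                    f"{direction} inconsistent with target and sum"
                )
            if magnitude is not None and magnitude != abs(expected):
                raise SchemaError(
                    f"line {line_of[id(members[0])]}: magnitude {magnitude} != "
                    f"|target - sum| = {abs(expected)}"
                )
            records.append(
                RoundRecord(r, guesses, declared, FeedbackSignal(direction, magnitude))
            )
        solved = records[-1].feedback.direction is Direction.CORRECT
        logs.append(
            GameLog(
                group_id=group_id,
                group_size=first["group_size"],
                game_index=game_index,
                feedback_mode=first["feedback_mode"],
                target=first["target"],
                member_ids=tuple(row["member_id"] for row in rounds_map[min(rounds_map)]),
                rounds=tuple(records),
                solved=solved,
                rounds_to_solution=len(records),
            )
        )
    return logs


@dataclass
class RunManifest:
    """Everything needed to replay a run bit-exactly."""

    command: str
    config: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION
    software_version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__

            self.software_version = __version__
        if not self.created:
            self.created = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return data


def game_config_from_dict(data: dict) -> GameConfig:
    allowed = {f.name for f in dataclasses.fields(GameConfig)}
    return GameConfig(**{k: v for k, v in data.items() if k in allowed})


def session_config_from_dict(data: dict) -> SessionConfig:
    data = dict(data)
    if "game" in data and isinstance(data["game"], dict):
        data["game"] = game_config_from_dict(data["game"])
    if "schedule" in data and data["schedule"] is not None:
        data["schedule"] = tuple(FeedbackMode(m) for m in data["schedule"])
    allowed = {f.name for f in dataclasses.fields(SessionConfig)}
    return SessionConfig(**{k: v for k, v in data.items() if k in allowed})
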