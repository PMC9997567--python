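"""Plate-table file format and run manifests.

Plate tables are tab-separated text: a header row ``culture_id  plate_id
day_1 ... day_N`` followed by one row per plate holding cumulative
(non-decreasing) integer colony counts.  Every CLI run writes a JSON
manifest (config snapshot, seed, package version, outputs) sufficient to
reproduce its outputs bit for bit.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RateConfig
from .experiments import PlateCountTable

__all__ = ["read_plate_table", "write_plate_table", "RunManifest"]


def write_plate_table(table: PlateCountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.columns = [f"day_{d}" for d in table.days]
    df.insert(0, "plate_id", table.counts.index)
    df.insert(0, "culture_id", table.culture_ids)
    df.to_csv(path, sep="\t", index=False)


def read_plate_table(path: str | Path) -> PlateCountTable:
    """Parse and validate a tab-separated plate table.

    Raises ``ValueError`` naming the offending row and column for ragged
    rows, non-integer or negative counts, and cumulative counts that
    decrease over days.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["culture_id", "plate_id"]:
            raise ValueError(
                f"{path}: header must start with culture_id, plate_id"
            )
        day_cols = header[2:]
        try:
            days = [int(c.removeprefix("day_")) for c in day_cols]
        except ValueError as exc:
            raise ValueError(f"{path}: malformed day column in header") from exc
        culture_ids: list[str] = []
        plate_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(fields)} fields, "
                    f"expected {len(header)}"
                )
            culture_ids.append(fields[0])
            plate_ids.append(fields[1])
            row: list[int] = []
            prev = -1
            for col_name, raw in zip(day_cols, fields[2:]):
                try:
                    value = int(raw)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: row {lineno}, column {col_name}: "
                        f"{raw!r} is not an integer count"
                    ) from exc
                if value < 0:
                    raise ValueError(
                        f"{path}: row {lineno}, column {col_name}: "
                        f"negative count {value}"
                    )
                if value < prev:
                    raise ValueError(
                        f"{path}: row {lineno}, column {col_name}: cumulative "
                        f"count decreases ({prev} -> {value})"
                    )
                prev = value
                row.append(value)
            rows.append(row)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64) if rows else np.empty((0, len(days)), np.int64),
        columns=days,
        index=plate_ids,
    )
    return PlateCountTable(counts=counts, culture_ids=culture_ids)


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    seed: int | None
    config: dict
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls, command: str, config: RateConfig, seed: int | None, outputs: list[str]
    ) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            seed=seed,
            config=config.to_dict(),
            outputs=list(outputs),
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
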