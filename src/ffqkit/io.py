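"""Delimited-text I/O for responses and derived nutrient files.

All artifacts are comma-separated UTF-8 with a header row; missing values
are empty cells or "NA".  Response files have one row per participant,
columns keyed by variable code.  Nutrient files have one column per slot
in a fixed deterministic order; excluded participants go to a companion
exclusion log naming the violated rules, never to the main file.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .nutrients import ALL_SLOTS, NutrientVector
from .schema import FfqResponse, FfqSchema, SchemaError

log = logging.getLogger(__name__)

__all__ = ["load_responses", "write_responses", "write_nutrients",
           "load_nutrients", "exclusion_log_path"]


def load_responses(path: str | Path, schema: FfqSchema) -> list[FfqResponse]:
    """Read a response CSV against a schema.

    Unknown column codes are a schema error naming the column; duplicate
    participant ids are a load error; unparseable cells degrade to missing
    with a logged warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "participant_id" not in df.columns:
        raise SchemaError("response file lacks a participant_id column")
    unknown = [c for c in df.columns if c != "participant_id" and c not in schema]
    if unknown:
        raise SchemaError(f"unknown variable code column(s): {unknown}")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"duplicate participant_id values: {sorted(set(dupes))}")
    responses = []
    for _, row in df.iterrows():
        answers: dict[str, object] = {}
        for code in df.columns:
            if code == "participant_id":
                continue
            try:
                answers[code] = schema.parse_answer(code, row[code])
            except SchemaError as exc:
                log.warning("participant %s: %s; treated as missing",
                            row["participant_id"], exc)
                answers[code] = None
        responses.append(FfqResponse(participant_id=row["participant_id"],
                                     answers=answers))
    return responses


def write_responses(
    responses: list[FfqResponse], schema: FfqSchema, path: str | Path
) -> None:
    """Write responses with one column per schema code (stable order)."""
    codes = schema.codes
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", *codes])
        for resp in responses:
            row = [resp.participant_id]
            for code in codes:
                v = resp.answers.get(code)
                if v is None:
                    row.append("")
                elif v is True:
                    row.append("Yes")
                elif v is False:
                    row.append("No")
                elif isinstance(v, (int, float)) and float(v) == int(v):
                    row.append(str(int(v)))  # canonical form for counts
                else:
                    row.append(str(v))
            writer.writerow(row)


def exclusion_log_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".exclusions.csv")


def write_nutrients(
    records: list[tuple[str, NutrientVector]],
    path: str | Path,
    exclusions: dict[str, list[str]] | None = None,
    keep_excluded: bool = False,
) -> None:
    """Write derived nutrient vectors to CSV (deterministic column order).

    All vectors must share a basis.  Participants flagged in
    ``exclusions`` are written to a companion ``*.exclusions.csv`` log
    with the violated rule names and (unless ``keep_excluded``) left out
    of the main file.
    """
    exclusions = exclusions or {}
    bases = {vec.basis for _, vec in records}
    if len(bases) > 1:
        raise ValueError(f"records mix bases {sorted(bases)}; convert first")
    basis = bases.pop() if bases else "daily"
    cols = list(ALL_SLOTS) + (["energy_mj"] if basis == "daily" else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", *cols])
        for pid, vec in records:
            if pid in exclusions and not keep_excluded:
                continue
            row = [pid] + [repr(vec[s]) for s in ALL_SLOTS]
            if basis == "daily":
                row.append(repr(vec.energy_mj))
            writer.writerow(row)
    with open(exclusion_log_path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "violated_rules"])
        for pid, names in exclusions.items():
            writer.writerow([pid, ";".join(names)])


def load_nutrients(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")
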