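"""Readers and writers for the package's plain-text dialects.

Response matrices travel as CSV with mandatory header ``person_id,age,sex``
followed by one 0/1 column per item; item banks as JSON arrays (with a CSV
mirror using identical column names); CAT transcripts and reports as JSON.
All writers are deterministic: stable column order and floats at 6 decimals.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cat import CatSession
from .irt import Item, ItemBank, ResponseMatrix

log = logging.getLogger("vocat")

FLOAT_FMT = "%.6f"
_META_COLS = ["person_id", "age", "sex"]


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    """Read a response-matrix CSV; validates the 0/1 contract cell by cell."""
    df = pd.read_csv(path, dtype={"person_id": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    item_cols = [c for c in df.columns if c not in _META_COLS]
    if not item_cols:
        raise ValueError(f"{path}: no item columns found")
    for col in item_cols:
        vals = df[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-binary cell at row {row} (person "
                f"{df['person_id'].iloc[row]!r}), column {col!r}: "
                f"{vals.iloc[row]!r}")
    age = df["age"].to_numpy(dtype=float) if df["age"].notna().all() else None
    sex = df["sex"].astype(object).to_numpy() if df["sex"].notna().all() else None
    data = ResponseMatrix(
        person_ids=list(df["person_id"]),
        item_ids=item_cols,
        responses=df[item_cols].to_numpy(),
        age=age,
        group=sex,
    )
    log.info("read %d persons x %d items from %s (%.1f%% yes)",
             data.n_persons, data.n_items, path,
             100 * data.responses.mean())
    return data


def write_response_matrix(data: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(data.responses, columns=data.item_ids)
    df.insert(0, "sex", data.group if data.group is not None else "")
    df.insert(0, "age", np.round(data.age, 6) if data.age is not None else "")
    df.insert(0, "person_id", data.person_ids)
    df.to_csv(path, index=False)


def _item_record(it: Item) -> dict:
    return {
        "item_id": it.item_id,
        "word": it.word,
        "word_type": it.word_type,
        "difficulty": round(float(it.difficulty), 6),
        "discrimination": round(float(it.discrimination), 6),
        "difficulty_se": (None if it.difficulty_se is None
                          else round(float(it.difficulty_se), 6)),
    }


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank as JSON (``.json``) or its CSV mirror (anything else)."""
    path = Path(path)
    records = [_item_record(it) for it in bank]
    if path.suffix == ".json":
        payload = {"model_tag": bank.model_tag, "items": records}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        pd.DataFrame(records).to_csv(path, index=False,
                                     float_format=FLOAT_FMT)


def read_item_bank(path: str | Path) -> ItemBank:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        model_tag = payload.get("model_tag", "rasch")
        records = payload["items"] if isinstance(payload, dict) else payload
    else:
        model_tag = "rasch"
        records = pd.read_csv(path).to_dict("records")
        for r in records:
            if pd.isna(r.get("difficulty_se")):
                r["difficulty_se"] = None
    items = [Item(item_id=str(r["item_id"]), word=str(r.get("word", "")),
                  word_type=str(r.get("word_type", "noun")),
                  difficulty=float(r["difficulty"]),
                  discrimination=float(r.get("discrimination", 1.0)),
                  difficulty_se=(None if r.get("difficulty_se") is None
                                 else float(r["difficulty_se"])))
             for r in records]
    if any(it.discrimination != 1.0 for it in items):
        model_tag = "2pl"
    return ItemBank(items=items, model_tag=model_tag)


def write_session(session: CatSession, path: str | Path) -> None:
    """Write a CAT transcript as JSON (the downloadable record)."""
    d = session.to_dict()
    Path(path).write_text(json.dumps(d, indent=2, default=float) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return o.__dict__
    return str(o)
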