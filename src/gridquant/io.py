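"""File round-tripping: counts tables, score tables, reports, images."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .agreement import RatingPair
from .errors import InputFormatError
from .quantify import CaseReport, FieldCounts

COUNTS_COLUMNS = ["case_id", "field_id", "n_T", "n_S", "n_L", "n_NA"]
SCORES_COLUMNS = ["case_id", "rater_a_score", "rater_b_score"]


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB image (PNG/JPEG/TIFF) as an (H, W, 3) uint8 array."""
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise InputFormatError(f"unreadable image {path}: {exc}") from exc


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.ascontiguousarray(image)).save(path)


def read_counts_csv(path) -> dict:
    """Read a per-field counts table; returns {case_id: [FieldCounts, ...]}
    with fields in file order."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise InputFormatError(f"cannot parse counts CSV {path}: {exc}") from exc
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"counts CSV {path} is missing columns {missing}")
    cases: dict = {}
    for i, row in df.iterrows():
        try:
            counts = FieldCounts(
                n_T=int(row["n_T"]), n_S=int(row["n_S"]),
                n_L=int(row["n_L"]), n_NA=int(row["n_NA"]),
            )
        except (ValueError, TypeError) as exc:
            raise InputFormatError(f"counts CSV {path}, row {i + 2}: {exc}") from exc
        cases.setdefault(str(row["case_id"]), []).append(counts)
    if not cases:
        raise InputFormatError(f"counts CSV {path} contains no rows")
    return cases


def write_counts_csv(path, cases: dict) -> None:
    rows = []
    for case_id, counts_list in cases.items():
        for i, c in enumerate(counts_list):
            rows.append(
                {"case_id": case_id, "field_id": i,
                 "n_T": c.n_T, "n_S": c.n_S, "n_L": c.n_L, "n_NA": c.n_NA}
            )
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, index=False)


def read_scores_csv(path) -> RatingPair:
    """Read a two-rater case-score table into a RatingPair."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise InputFormatError(f"cannot parse scores CSV {path}: {exc}") from exc
    missing = [c for c in SCORES_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"scores CSV {path} is missing columns {missing}")
    if len(df) < 2:
        raise InputFormatError(f"scores CSV {path} needs at least 2 cases, has {len(df)}")
    try:
        a = [int(v) for v in df["rater_a_score"]]
        b = [int(v) for v in df["rater_b_score"]]
    except (ValueError, TypeError) as exc:
        raise InputFormatError(f"scores CSV {path} has non-integer scores: {exc}") from exc
    categories = tuple(sorted(set(a) | set(b)))
    return RatingPair(ratings_a=tuple(a), ratings_b=tuple(b), categories=categories)


def write_report_json(path, report: CaseReport, extra: dict | None = None) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_report_json(path) -> CaseReport:
    return CaseReport.from_dict(json.loads(Path(path).read_text()))


def write_cell_table_csv(path, rows: list) -> None:
    """Per-cell composition table: field_id, row, col, fractions, count, label."""
    cols = ["field_id", "row", "col", "tumor_fraction", "stroma_fraction",
            "lymph_fraction", "background_fraction", "lymph_count", "label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_exclusion_csv(path) -> set:
    """Exclusion mask CSV of (row, col) pairs forced to NA."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputFormatError(f"cannot parse exclusion CSV {path}: {exc}") from exc
    if not {"row", "col"} <= set(df.columns):
        raise InputFormatError(f"exclusion CSV {path} needs 'row' and 'col' columns")
    return {(int(r), int(c)) for r, c in zip(df["row"], df["col"])}
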