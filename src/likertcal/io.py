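"""Survey and correction-table input/output.

Survey CSV schema::

    site_id,respondent_id,pleasant,annoying,vibrant,monotonous,calm,chaotic,eventful,uneventful

Responses are converted on read to the canonical coding
(1 = strongly disagree ... 5 = strongly agree).  Extra columns are ignored
with a logged notice; demographic fields are accepted but never analyzed.

Correction tables are serialized as JSON with one object per attribute
carrying the keys ``a0, d0, n0, b, z, dd, d, n, a, aa, n0_fallback_used``
(``n0`` may be null).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Union

import pandas as pd

from .attributes import ATTRIBUTE_ORDER, GROUPS
from .errors import (
    CategoryRangeError,
    EmptyFileError,
    MissingColumnError,
    MissingFieldError,
    SurveyValidationError,
    UnknownLabelError,
)
from .tables import CorrectionRow, CorrectionTable

logger = logging.getLogger(__name__)

__all__ = [
    "CodingConfig",
    "SurveyRecord",
    "SurveyTable",
    "read_survey_table",
    "write_survey_table",
    "read_correction_table",
    "write_correction_table",
]

ID_COLUMNS = ("site_id", "respondent_id")

#: Default label map for fully labeled five-point scales (canonical direction).
DEFAULT_LABELS: Dict[str, int] = {
    "strongly disagree": 1,
    "somewhat disagree": 2,
    "disagree": 2,
    "neither agree nor disagree": 3,
    "neutral": 3,
    "agree": 4,
    "somewhat agree": 4,
    "strongly agree": 5,
}


@dataclass(frozen=True)
class CodingConfig:
    """How raw survey cells map to canonical categories and groups.

    ``input_coding`` is either a direction ("agree_high": 5 already means
    strongly agree; "agree_low": 1 means strongly agree, values are reversed
    as 6 - raw) or a label-to-canonical-category map.  ``grouping_map`` sends
    each canonical category to one of the grouped categories D/N/A; exactly
    one category must map to N.
    """

    input_coding: Union[str, Mapping[str, int]] = "agree_high"
    grouping_map: Mapping[int, str] = field(
        default_factory=lambda: {1: "D", 2: "D", 3: "N", 4: "A", 5: "A"}
    )

    def __post_init__(self) -> None:
        if isinstance(self.input_coding, str):
            if self.input_coding not in ("agree_high", "agree_low"):
                raise SurveyValidationError(
                    f"unknown input_coding {self.input_coding!r}"
                )
        if set(self.grouping_map) != {1, 2, 3, 4, 5}:
            raise SurveyValidationError("grouping_map must cover categories 1..5")
        if any(g not in GROUPS for g in self.grouping_map.values()):
            raise SurveyValidationError("grouping_map values must be D, N or A")
        if sum(1 for g in self.grouping_map.values() if g == "N") != 1:
            raise SurveyValidationError("exactly one category must map to N")

    def canonicalize(self, raw: object, *, context: str = "") -> int:
        """Convert one raw cell to the canonical 1..5 coding."""
        if isinstance(self.input_coding, str):
            try:
                value = int(str(raw).strip())
            except (TypeError, ValueError):
                raise CategoryRangeError(
                    f"non-integer category {raw!r} {context}".strip()
                ) from None
            if not 1 <= value <= 5:
                raise CategoryRangeError(
                    f"category {value} outside [1, 5] {context}".strip()
                )
            return value if self.input_coding == "agree_high" else 6 - value
        label = str(raw).strip().lower()
        try:
            return int(self.input_coding[label])
        except KeyError:
            raise UnknownLabelError(f"unknown label {raw!r} {context}".strip()) from None

    def group_of(self, category: int) -> str:
        return self.grouping_map[int(category)]


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent's eight canonical-coded responses."""

    site_id: str
    respondent_id: str
    responses: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [a for a in ATTRIBUTE_ORDER if a not in self.responses]
        if missing:
            raise MissingColumnError(
                f"record {self.respondent_id!r} missing attribute(s): "
                + ", ".join(missing)
            )
        for attr in ATTRIBUTE_ORDER:
            v = self.responses[attr]
            iv = int(v)
            if iv != v or not 1 <= iv <= 5:
                raise CategoryRangeError(
                    f"record {self.respondent_id!r}, {attr}: "
                    f"category {v!r} outside [1, 5]"
                )


class SurveyTable:
    """Ordered collection of survey records, backed by a DataFrame.

    The frame holds ``site_id``, ``respondent_id`` and the eight attribute
    columns in canonical coding and canonical column order.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in (*ID_COLUMNS, *ATTRIBUTE_ORDER) if c not in frame.columns]
        if missing:
            raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
        if len(frame) == 0:
            raise EmptyFileError("survey table has no records")
        frame = frame.loc[:, list(ID_COLUMNS) + list(ATTRIBUTE_ORDER)].reset_index(
            drop=True
        )
        values = frame[list(ATTRIBUTE_ORDER)]
        bad = ~values.isin([1, 2, 3, 4, 5]).all(axis=None)
        if bad:
            raise CategoryRangeError("survey table contains categories outside [1, 5]")
        frame = frame.astype({a: int for a in ATTRIBUTE_ORDER})
        frame["site_id"] = frame["site_id"].astype(str)
        frame["respondent_id"] = frame["respondent_id"].astype(str)
        self._frame = frame

    @classmethod
    def from_records(cls, records: List[SurveyRecord]) -> "SurveyTable":
        if not records:
            raise EmptyFileError("no survey records")
        rows = [
            {
                "site_id": r.site_id,
                "respondent_id": r.respondent_id,
                **{a: int(r.responses[a]) for a in ATTRIBUTE_ORDER},
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def sites(self) -> List[str]:
        """Unique site ids in order of first appearance."""
        return list(dict.fromkeys(self._frame["site_id"]))

    @property
    def records(self) -> List[SurveyRecord]:
        return list(self)

    def __iter__(self) -> Iterator[SurveyRecord]:
        for row in self._frame.itertuples(index=False):
            d = row._asdict()
            yield SurveyRecord(
                site_id=d["site_id"],
                respondent_id=d["respondent_id"],
                responses={a: d[a] for a in ATTRIBUTE_ORDER},
            )

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyTable):
            return NotImplemented
        return self._frame.equals(other._frame)


def read_survey_table(
    path: Union[str, Path], coding: Optional[CodingConfig] = None
) -> SurveyTable:
    """Read a survey CSV and convert responses to canonical coding.

    Raises a distinct, named error for each failure mode: missing columns,
    non-integer or out-of-range categories, unknown labels, empty files.
    """
    coding = coding or CodingConfig()
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyFileError(f"{path} is empty") from None
    missing = [c for c in (*ID_COLUMNS, *ATTRIBUTE_ORDER) if c not in raw.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise EmptyFileError(f"{path} has a header but no records")
    extra = [c for c in raw.columns if c not in (*ID_COLUMNS, *ATTRIBUTE_ORDER)]
    if extra:
        logger.info("ignoring extra column(s): %s", ", ".join(extra))
    out = raw.loc[:, list(ID_COLUMNS)].copy()
    for attr in ATTRIBUTE_ORDER:
        out[attr] = [
            coding.canonicalize(v, context=f"(row {i}, column {attr!r})")
            for i, v in enumerate(raw[attr])
        ]
    return SurveyTable(out)


def write_survey_table(table: SurveyTable, path: Union[str, Path]) -> None:
    """Write a canonical-coded survey table as CSV."""
    table.frame.to_csv(path, index=False)


_ROW_KEYS = ("a0", "d0", "n0", "b", "z", "dd", "d", "n", "a", "aa", "n0_fallback_used")


def write_correction_table(table: CorrectionTable, path: Union[str, Path]) -> None:
    payload: dict = {attr: table.rows[attr].to_dict() for attr in ATTRIBUTE_ORDER}
    if table.anchor_node is not None:
        payload["provenance"] = {
            "anchor_node": list(table.anchor_node),
            "anchor_value": table.anchor_value,
            "edges_used": table.edges_used,
            "warnings": table.warnings,
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def read_correction_table(path: Union[str, Path]) -> CorrectionTable:
    """Read a correction-table JSON file.

    A missing attribute or missing per-attribute key raises
    :class:`MissingFieldError` naming the field.  Rows whose ``aa`` does not
    exceed ``dd`` (reversed orientation, as negative-polarity attributes
    naturally acquire) are recorded as warnings, not errors.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MissingFieldError(f"{path}: malformed JSON: {exc}") from None
    rows: Dict[str, CorrectionRow] = {}
    warnings: List[str] = []
    for attr in ATTRIBUTE_ORDER:
        if attr not in payload:
            raise MissingFieldError(f"{path}: missing attribute {attr!r}")
        obj = payload[attr]
        missing = [k for k in _ROW_KEYS if k not in obj]
        if missing:
            raise MissingFieldError(
                f"{path}: attribute {attr!r} missing key(s): {', '.join(missing)}"
            )
        row = CorrectionRow(
            a0=float(obj["a0"]),
            d0=float(obj["d0"]),
            n0=None if obj["n0"] is None else float(obj["n0"]),
            b=float(obj["b"]),
            z=int(obj["z"]),
            dd=float(obj["dd"]),
            d=float(obj["d"]),
            n=float(obj["n"]),
            a=float(obj["a"]),
            aa=float(obj["aa"]),
            n0_fallback_used=bool(obj["n0_fallback_used"]),
        )
        if row.aa < row.dd:
            warnings.append(f"{attr}: reversed orientation (aa < dd)")
        rows[attr] = row
    prov = payload.get("provenance") or {}
    table = CorrectionTable(
        rows=rows,
        anchor_node=tuple(prov["anchor_node"]) if "anchor_node" in prov else None,
        anchor_value=prov.get("anchor_value"),
        edges_used=prov.get("edges_used", []),
        warnings=list(prov.get("warnings", [])),
    )
    for w in warnings:
        if w not in table.warnings:
            table.warnings.append(w)
            logger.warning("correction table %s: %s", path, w)
    return table
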