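"""Spreadsheet import of externally supplied per-respondent utilities.

Published conjoint studies sometimes ship their per-respondent part-worth
utilities inside an Excel simulator workbook rather than as raw data. This
module loads such a workbook given a user-supplied column mapping (the
internal layout of third-party workbooks cannot be assumed) and re-centers
the utilities within attribute so they satisfy the package's zero-sum
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .partworths import PartWorthSet

__all__ = ["WorkbookMapping", "read_supplementary_utilities"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkbookMapping:
    """Where the utilities live inside a workbook.

    ``columns`` maps a spreadsheet column header to an
    ``(attribute, level_value)`` pair; ``id_column`` names the respondent
    identifier column (``None`` auto-numbers rows).
    """

    sheet: str
    columns: dict
    id_column: str | None = None
    header_row: int = 0


def read_supplementary_utilities(path, mapping: WorkbookMapping) -> PartWorthSet:
    """Load per-respondent part-worth utilities from an XLSX workbook.

    Raises a descriptive error listing the discovered sheets/columns when
    the mapping does not match, and re-centers utilities within attribute
    after loading.
    """
    path = Path(path)
    xls = pd.ExcelFile(path, engine="openpyxl")
    if mapping.sheet not in xls.sheet_names:
        raise ValueError(
            f"sheet {mapping.sheet!r} not found in {path.name}; "
            f"available sheets: {xls.sheet_names}"
        )
    frame = xls.parse(mapping.sheet, header=mapping.header_row)
    missing = [c for c in mapping.columns if c not in frame.columns]
    if mapping.id_column is not None and mapping.id_column not in frame.columns:
        missing.append(mapping.id_column)
    if missing:
        raise ValueError(
            f"columns {missing} not found on sheet {mapping.sheet!r}; "
            f"available columns: {list(frame.columns)}"
        )

    if mapping.id_column is not None:
        ids = frame[mapping.id_column].tolist()
    else:
        ids = [f"R{i:04d}" for i in range(len(frame))]

    by_attr: dict[str, list[tuple[float, str]]] = {}
    for col, (attr, level) in mapping.columns.items():
        by_attr.setdefault(attr, []).append((float(level), col))

    levels = {}
    utilities = {}
    for attr, pairs in by_attr.items():
        pairs.sort()
        levels[attr] = np.array([lev for lev, _ in pairs])
        utilities[attr] = frame[[col for _, col in pairs]].to_numpy(dtype=float)

    logger.info(
        "loaded %d respondents x %d attributes from %s!%s",
        len(ids), len(by_attr), path.name, mapping.sheet,
    )
    return PartWorthSet(respondent_ids=ids, levels=levels, utilities=utilities)
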