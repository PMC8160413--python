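"""Zero-centered per-respondent part-worth utilities.

The central data container of the analysis: for every respondent and every
(attribute, level) cell, the utility that level contributes to a product.
Within each attribute a respondent's level utilities sum to zero, so a
positive part-worth marks a level that raises the chance the respondent
picks a product carrying it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PartWorthSet"]


@dataclass
class PartWorthSet:
    """Per-respondent part-worth utilities for every (attribute, level).

    Parameters
    ----------
    respondent_ids
        Length-n sequence of respondent identifiers.
    levels
        Attribute name -> numeric level values (length L_a each).
    utilities
        Attribute name -> array of shape (n, L_a). Re-centered on
        construction so each row sums to zero exactly.
    """

    respondent_ids: list
    levels: dict[str, np.ndarray]
    utilities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.respondent_ids = list(self.respondent_ids)
        n = len(self.respondent_ids)
        if set(self.levels) != set(self.utilities):
            raise ValueError("levels and utilities must cover the same attributes")
        for name in self.levels:
            self.levels[name] = np.asarray(self.levels[name], dtype=float)
            u = np.atleast_2d(np.asarray(self.utilities[name], dtype=float))
            if u.shape != (n, len(self.levels[name])):
                raise ValueError(
                    f"attribute {name!r}: utilities shape {u.shape} != "
                    f"({n}, {len(self.levels[name])})"
                )
            # exact zero-centering within attribute
            self.utilities[name] = u - u.mean(axis=1, keepdims=True)

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def attributes(self) -> list[str]:
        return list(self.levels)

    def population_mean(self) -> dict[str, np.ndarray]:
        """Across-respondent mean utility per (attribute, level)."""
        return {name: u.mean(axis=0) for name, u in self.utilities.items()}

    def ranges(self) -> pd.DataFrame:
        """Per-respondent utility range (max - min) per attribute."""
        data = {
            name: u.max(axis=1) - u.min(axis=1) for name, u in self.utilities.items()
        }
        return pd.DataFrame(data, index=pd.Index(self.respondent_ids, name="respondent_id"))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: respondent_id, attribute, level_value, utility."""
        rows = []
        for name in self.attributes:
            levs = self.levels[name]
            u = self.utilities[name]
            for i, rid in enumerate(self.respondent_ids):
                for j, lev in enumerate(levs):
                    rows.append((rid, name, lev, u[i, j]))
        return pd.DataFrame(
            rows, columns=["respondent_id", "attribute", "level_value", "utility"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PartWorthSet":
        required = {"respondent_id", "attribute", "level_value", "utility"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"part-worth frame missing columns {sorted(missing)}")
        rids = list(pd.unique(frame["respondent_id"]))
        levels: dict[str, np.ndarray] = {}
        utilities: dict[str, np.ndarray] = {}
        for name, grp in frame.groupby("attribute", sort=False):
            levs = np.sort(pd.unique(grp["level_value"]))
            levels[name] = levs
            wide = grp.pivot_table(
                index="respondent_id", columns="level_value", values="utility"
            ).reindex(index=rids, columns=levs)
            if wide.isna().any().any():
                raise ValueError(f"attribute {name!r}: missing utility cells")
            utilities[name] = wide.to_numpy()
        return cls(respondent_ids=rids, levels=levels, utilities=utilities)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PartWorthSet":
        return cls.from_frame(pd.read_csv(path))

    def subset(self, respondent_ids) -> "PartWorthSet":
        pos = {rid: i for i, rid in enumerate(self.respondent_ids)}
        idx = [pos[r] for r in respondent_ids]
        return PartWorthSet(
            respondent_ids=list(respondent_ids),
            levels={k: v.copy() for k, v in self.levels.items()},
            utilities={k: v[idx].copy() for k, v in self.utilities.items()},
        )
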