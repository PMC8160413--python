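"""Choice-response data: validated long-format records plus covariates.

Canonical interchange is a tidy long table with one row per
(respondent, task, alternative): columns ``respondent_id``, ``task_id``,
``alternative_id``, one numeric column per attribute holding the level
value shown, and ``chosen`` (0/1). Exactly one alternative may be chosen
per task — respondents picked a single product per question.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attributes import AttributeSpec, attribute_index

__all__ = ["ResponseSet", "read_responses", "write_responses", "ResponseValidationError"]

META_COLUMNS = ("respondent_id", "task_id", "alternative_id", "chosen")


class ResponseValidationError(ValueError):
    """Malformed response data; the message names the offending rows/fields."""


@dataclass
class ResponseSet:
    """Long-format choice records plus an optional covariate table.

    ``data`` columns: respondent_id, task_id, alternative_id, one column per
    attribute (numeric level values), chosen. ``covariates`` is indexed by
    respondent_id.
    """

    data: pd.DataFrame
    covariates: pd.DataFrame | None = None
    attribute_space: tuple[AttributeSpec, ...] | None = None

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ResponseValidationError(f"response table missing columns {missing}")
        if not self.attribute_columns:
            raise ResponseValidationError("response table has no attribute columns")
        chosen = self.data["chosen"].astype(int)
        if not chosen.isin((0, 1)).all():
            bad = self.data.index[~chosen.isin((0, 1))].tolist()[:5]
            raise ResponseValidationError(f"chosen must be 0/1; bad rows {bad}")
        per_task = self.data.groupby(["respondent_id", "task_id"])["chosen"].sum()
        bad = per_task[per_task != 1]
        if len(bad):
            key = bad.index[0]
            raise ResponseValidationError(
                f"each (respondent, task) needs exactly one chosen alternative; "
                f"respondent {key[0]!r} task {key[1]!r} has {int(bad.iloc[0])}"
            )
        if self.attribute_space is not None:
            self._check_levels()
        if self.covariates is not None:
            self.covariates = self.covariates.copy()
            if self.covariates.index.name != "respondent_id":
                if "respondent_id" in self.covariates.columns:
                    self.covariates = self.covariates.set_index("respondent_id")
                else:
                    raise ResponseValidationError(
                        "covariate table needs a respondent_id index or column"
                    )

    def _check_levels(self) -> None:
        idx = attribute_index(list(self.attribute_space))
        for name, spec in idx.items():
            if name not in self.data.columns:
                raise ResponseValidationError(f"missing attribute column {name!r}")
            vals = self.data[name].to_numpy(dtype=float)
            levels = np.asarray(spec.levels)
            ok = np.isclose(vals[:, None], levels[None, :]).any(axis=1)
            if not ok.all():
                row = int(np.flatnonzero(~ok)[0])
                raise ResponseValidationError(
                    f"row {row}: value {vals[row]} is not a level of {name!r}"
                )

    @property
    def attribute_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def respondent_ids(self) -> list:
        return list(pd.unique(self.data["respondent_id"]))

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def tasks_per_respondent(self) -> pd.Series:
        return self.data.groupby("respondent_id")["task_id"].nunique()

    def to_arrays(self, attribute_space: list[AttributeSpec]):
        """Dense arrays for the sampler.

        Returns ``(ids, X, y, mask)`` where X is
        (n_resp, max_tasks, n_alts, n_params) effects-coded, y is
        (n_resp, max_tasks) chosen alternative indices, and mask flags valid
        tasks (False rows are padding for respondents with fewer tasks).
        """
        from .coding import _make_blocks, effects_row

        idx = attribute_index(list(attribute_space))
        blocks = _make_blocks(list(attribute_space))
        p = sum(b.n_free for b in blocks)
        ids = self.respondent_ids

        level_maps = {}
        for name, spec in idx.items():
            level_maps[name] = np.asarray(spec.levels)

        df = self.data.sort_values(["respondent_id", "task_id", "alternative_id"])
        grouped = {rid: g for rid, g in df.groupby("respondent_id", sort=False)}
        n_tasks_max = max((g["task_id"].nunique() for g in grouped.values()), default=0)
        n_alts = int(df.groupby(["respondent_id", "task_id"]).size().max())

        n = len(ids)
        X = np.zeros((n, n_tasks_max, n_alts, p))
        y = np.zeros((n, n_tasks_max), dtype=np.int64)
        mask = np.zeros((n, n_tasks_max), dtype=bool)

        # Precompute effects rows per attribute level for speed.
        rows_cache = {
            name: np.array([effects_row(l, spec.n_levels) for l in range(spec.n_levels)])
            for name, spec in idx.items()
        }

        for i, rid in enumerate(ids):
            g = grouped[rid]
            for t, (_, task) in enumerate(g.groupby("task_id", sort=True)):
                mask[i, t] = True
                task = task.sort_values("alternative_id")
                for a, (_, row) in enumerate(task.iterrows()):
                    vec = np.zeros(p)
                    for spec, block in zip(attribute_space, blocks):
                        val = row[spec.name]
                        if pd.isna(val):
                            continue  # attribute not shown
                        lev = int(np.argmin(np.abs(level_maps[spec.name] - float(val))))
                        if not np.isclose(level_maps[spec.name][lev], float(val)):
                            raise ResponseValidationError(
                                f"respondent {rid!r}: {val} not a level of {spec.name!r}"
                            )
                        vec[block.offset : block.offset + block.n_free] = rows_cache[
                            spec.name
                        ][lev]
                    X[i, t, a] = vec
                    if int(row["chosen"]) == 1:
                        y[i, t] = a
        return ids, X, y, mask


def read_responses(
    path,
    covariates_path=None,
    attribute_space: list[AttributeSpec] | None = None,
) -> ResponseSet:
    """Read a long-format response CSV (and optional covariate CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = pd.read_json(path)
    else:
        data = pd.read_csv(path)
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
    return ResponseSet(
        data=data,
        covariates=cov,
        attribute_space=tuple(attribute_space) if attribute_space else None,
    )


def write_responses(responses: ResponseSet, path, covariates_path=None) -> None:
    responses.data.to_csv(path, index=False)
    if covariates_path is not None and responses.covariates is not None:
        responses.covariates.to_csv(covariates_path)
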