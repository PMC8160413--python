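"""Effects coding of categorical attribute levels.

An attribute with L levels contributes L-1 free coefficients. Level
l < L-1 is coded as the indicator basis vector e_l; the last level is coded
as (-1, ..., -1). Under this coding the implied utilities of all L levels
sum to zero, which is exactly the zero-centering convention used to report
part-worths: positive values raise the likelihood of selection, negative
values lower it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attributes import AttributeSpec
from .design import ChoiceDesign

__all__ = ["CodedDesign", "encode_design", "encode_levels", "expand_partworths"]


@dataclass(frozen=True)
class AttributeBlock:
    """Column block for one attribute within the coded parameter vector."""

    name: str
    levels: tuple[float, ...]
    offset: int  # first column index

    @property
    def n_free(self) -> int:
        return len(self.levels) - 1


@dataclass(frozen=True)
class CodedDesign:
    """Effects-coded design matrix with a reversible column mapping.

    ``X`` has shape (n_tasks, n_alts, n_params); entries are zero for
    attributes not shown in a task. ``blocks`` maps each attribute to its
    column block so coded coefficient vectors can be expanded back to
    full per-level utilities.
    """

    X: np.ndarray
    blocks: tuple[AttributeBlock, ...]
    shown: np.ndarray  # (n_tasks, n_attrs) bool

    @property
    def n_params(self) -> int:
        return self.X.shape[2]

    def decode(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Expand coded coefficients to full zero-sum level utilities.

        ``theta`` may be (n_params,) or (..., n_params); the per-attribute
        result gains the same leading dimensions.
        """
        theta = np.asarray(theta, dtype=float)
        out: dict[str, np.ndarray] = {}
        for block in self.blocks:
            free = theta[..., block.offset : block.offset + block.n_free]
            last = -free.sum(axis=-1, keepdims=True)
            out[block.name] = np.concatenate([free, last], axis=-1)
        return out

    def encode_utilities(self, utilities: dict[str, np.ndarray]) -> np.ndarray:
        """Inverse of :meth:`decode` for zero-sum level utilities."""
        parts = []
        for block in self.blocks:
            u = np.asarray(utilities[block.name], dtype=float)
            parts.append(u[..., : block.n_free])
        return np.concatenate(parts, axis=-1)


def _make_blocks(space: list[AttributeSpec]) -> tuple[AttributeBlock, ...]:
    blocks = []
    offset = 0
    for spec in space:
        if spec.n_levels < 2:
            raise ValueError(f"attribute {spec.name!r} has <2 levels; cannot effects-code")
        blocks.append(AttributeBlock(spec.name, spec.levels, offset))
        offset += spec.n_levels - 1
    return tuple(blocks)


def effects_row(level: int, n_levels: int) -> np.ndarray:
    """Effects-coding row for one level of one attribute."""
    row = np.zeros(n_levels - 1)
    if level == n_levels - 1:
        row[:] = -1.0
    else:
        row[level] = 1.0
    return row


def encode_levels(
    space: list[AttributeSpec], level_indices: dict[str, int]
) -> np.ndarray:
    """Coded vector for one alternative given its level index per attribute.

    Attributes absent from ``level_indices`` (not shown) contribute zeros.
    """
    blocks = _make_blocks(space)
    p = sum(b.n_free for b in blocks)
    x = np.zeros(p)
    for spec, block in zip(space, blocks):
        if spec.name in level_indices:
            x[block.offset : block.offset + block.n_free] = effects_row(
                level_indices[spec.name], spec.n_levels
            )
    return x


def encode_design(design: ChoiceDesign) -> CodedDesign:
    """Effects-code every alternative of every task in a design."""
    space = list(design.attribute_space)
    blocks = _make_blocks(space)
    p = sum(b.n_free for b in blocks)
    names = [spec.name for spec in space]
    X = np.zeros((design.n_tasks, design.n_alts, p))
    shown = np.zeros((design.n_tasks, len(space)), dtype=bool)
    for t, task in enumerate(design.tasks):
        for name in task.shown_attributes:
            shown[t, names.index(name)] = True
        for a, alt in enumerate(task.alternatives):
            X[t, a] = encode_levels(space, alt)
    return CodedDesign(X=X, blocks=blocks, shown=shown)


def encode_utilities(
    space: list[AttributeSpec], utilities: dict[str, np.ndarray]
) -> np.ndarray:
    """Coded coefficient vector(s) from zero-sum level utilities.

    Inverse of :func:`expand_partworths`; ``utilities[name]`` may be (L,) or
    (n, L).
    """
    blocks = _make_blocks(space)
    parts = []
    for block in blocks:
        u = np.asarray(utilities[block.name], dtype=float)
        parts.append(u[..., : block.n_free])
    return np.concatenate(parts, axis=-1)


def expand_partworths(
    blocks: tuple[AttributeBlock, ...], theta: np.ndarray
) -> dict[str, np.ndarray]:
    """Expand coded coefficients to zero-sum level utilities without a design."""
    theta = np.asarray(theta, dtype=float)
    out: dict[str, np.ndarray] = {}
    for block in blocks:
        free = theta[..., block.offset : block.offset + block.n_free]
        last = -free.sum(axis=-1, keepdims=True)
        out[block.name] = np.concatenate([free, last], axis=-1)
    return out
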