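"""Aitchison-geometry primitives for 24-hour time-use compositions.

A day is described by seven non-negative durations (min/day) that close to a
fixed total (1440 min). Because the parts carry only relative information, all
statistics are computed in isometric log-ratio (ilr) coordinates: an orthonormal
log-ratio basis defined by a sequential binary partition (SBP) of the parts.
This module provides closure, zero replacement (single-composition fixed rule
and a dataset-level regression-imputation scheme), the ilr transform and its
inverse, the compositional mean, and the 5:2 weekday:weekend weekly weighting
used by multi-day recall instruments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PART_NAMES: tuple[str, ...] = (
    "sleep",
    "screen",
    "physical_activity",
    "quiet",
    "passive_transport",
    "school",
    "domestic_selfcare",
)
N_PARTS = len(PART_NAMES)
DAY_MINUTES = 1440.0

#: Default zero-replacement rule: 65% of the 5-minute recall sampling frame.
ZERO_FRAME_MINUTES = 5.0
ZERO_FRACTION = 0.65


class CompositionError(ValueError):
    """Invalid composition (negative parts, degenerate rows, zeros where
    strict positivity is required, ...)."""


def _as_part_vector(parts) -> np.ndarray:
    """Coerce a mapping / sequence / Composition into a length-7 float array
    in the canonical part order."""
    if isinstance(parts, Composition):
        return parts.values.copy()
    if isinstance(parts, Mapping):
        missing = [p for p in PART_NAMES if p not in parts]
        if missing:
            raise CompositionError(f"missing parts: {missing}")
        extra = [p for p in parts if p not in PART_NAMES]
        if extra:
            raise CompositionError(f"unknown parts: {extra}")
        return np.array([float(parts[p]) for p in PART_NAMES])
    arr = np.asarray(parts, dtype=float)
    if arr.shape != (N_PARTS,):
        raise CompositionError(
            f"expected {N_PARTS} parts in order {PART_NAMES}, got shape {arr.shape}"
        )
    return arr.copy()


@dataclass(frozen=True)
class Composition:
    """Seven named durations (min/day) closed to a fixed daily total.

    Use :func:`close` to construct one from raw durations; the constructor
    validates that the parts are already closed.
    """

    values: np.ndarray
    total: float = DAY_MINUTES

    def __post_init__(self):
        vals = _as_part_vector(self.values)
        object.__setattr__(self, "values", vals)
        if self.total <= 0:
            raise CompositionError("total must be positive")
        if np.any(vals < 0):
            raise CompositionError("negative duration in composition")
        if abs(vals.sum() - self.total) > 1e-6:
            raise CompositionError(
                f"parts sum to {vals.sum():.8f}, expected {self.total} (within 1e-6)"
            )

    def __getitem__(self, part: str) -> float:
        return float(self.values[PART_NAMES.index(part)])

    def as_dict(self) -> dict[str, float]:
        return {p: float(v) for p, v in zip(PART_NAMES, self.values)}

    @property
    def is_strictly_positive(self) -> bool:
        return bool(np.all(self.values > 0))


def close(raw_parts, total: float = DAY_MINUTES) -> Composition:
    """Proportionally rescale non-negative durations so they sum to ``total``.

    Idempotent; raises on an all-zero ("degenerate") input.
    """
    vals = _as_part_vector(raw_parts)
    if total <= 0:
        raise CompositionError("total must be positive")
    if np.any(vals < 0):
        raise CompositionError("negative duration in composition")
    s = vals.sum()
    if s <= 0:
        raise CompositionError("degenerate composition: all parts are zero")
    return Composition(vals * (total / s), total=total)


# ---------------------------------------------------------------------------
# Sequential binary partitions and the ilr transform
# ---------------------------------------------------------------------------


class SequentialBinaryPartition:
    """A full binary splitting of the 7 parts defining an orthonormal ilr basis.

    Row k of the sign matrix splits one group of parts into a +1 subset (size r)
    and a -1 subset (size s); the induced balance is

        z_k = sqrt(r*s/(r+s)) * ln( g(+parts) / g(-parts) )

    with g the geometric mean. The 6x7 contrast matrix ``basis`` satisfies
    basis @ basis.T = I and each row sums to zero, so z = basis @ ln(x) is
    closure-invariant.
    """

    def __init__(self, matrix, parts: Sequence[str] = PART_NAMES):
        mat = np.asarray(matrix, dtype=int)
        d = len(parts)
        if mat.shape != (d - 1, d):
            raise ValueError(f"SBP matrix must be {(d - 1, d)}, got {mat.shape}")
        if not np.isin(mat, (-1, 0, 1)).all():
            raise ValueError("SBP entries must be in {-1, 0, +1}")
        basis = np.zeros((d - 1, d))
        for k, row in enumerate(mat):
            plus = row == 1
            minus = row == -1
            r, s = plus.sum(), minus.sum()
            if r == 0 or s == 0:
                raise ValueError(f"SBP row {k} must have both +1 and -1 entries")
            basis[k, plus] = np.sqrt(s / (r * (r + s)))
            basis[k, minus] = -np.sqrt(r / (s * (r + s)))
        gram = basis @ basis.T
        if not np.allclose(gram, np.eye(d - 1), atol=1e-10):
            raise ValueError("SBP does not induce an orthonormal basis "
                             "(rows must form a full binary tree over the parts)")
        self.matrix = mat
        self.parts = tuple(parts)
        self.basis = basis
        self.id = hashlib.sha1(
            mat.tobytes() + ",".join(self.parts).encode()
        ).hexdigest()[:12]

    @classmethod
    def pivot(cls, parts: Sequence[str] = PART_NAMES) -> "SequentialBinaryPartition":
        """Pivot coordinates: row k isolates part k against all later parts."""
        d = len(parts)
        mat = np.zeros((d - 1, d), dtype=int)
        for k in range(d - 1):
            mat[k, k] = 1
            mat[k, k + 1:] = -1
        return cls(mat, parts)

    @classmethod
    def random(cls, rng: np.random.Generator,
               parts: Sequence[str] = PART_NAMES) -> "SequentialBinaryPartition":
        """A uniformly-random recursive binary splitting (useful for testing
        basis invariance)."""
        d = len(parts)
        rows: list[np.ndarray] = []

        def split(idx: list[int]) -> None:
            if len(idx) < 2:
                return
            while True:
                side = rng.integers(0, 2, size=len(idx))
                if 0 < side.sum() < len(idx):
                    break
            row = np.zeros(d, dtype=int)
            plus = [i for i, s in zip(idx, side) if s == 1]
            minus = [i for i, s in zip(idx, side) if s == 0]
            row[plus] = 1
            row[minus] = -1
            rows.append(row)
            split(plus)
            split(minus)

        split(list(range(d)))
        return cls(np.array(rows), parts)

    def __eq__(self, other):
        return (isinstance(other, SequentialBinaryPartition)
                and self.id == other.id)

    def __repr__(self):
        return f"SequentialBinaryPartition(id={self.id!r}, parts={self.parts})"


DEFAULT_SBP = SequentialBinaryPartition.pivot()


def ilr(comp, sbp: SequentialBinaryPartition = DEFAULT_SBP) -> np.ndarray:
    """Isometric log-ratio coordinates (length D-1 = 6) of a strictly positive
    composition. Also accepts an (n, 7) array/DataFrame of rows, returning
    (n, 6)."""
    if isinstance(comp, Composition):
        vals = comp.values
    elif isinstance(comp, pd.DataFrame):
        vals = comp[list(sbp.parts)].to_numpy(dtype=float)
    else:
        vals = np.asarray(comp, dtype=float)
    if np.any(vals <= 0):
        raise CompositionError(
            "composition has non-positive parts; apply zero replacement "
            "(replace_zeros_fixed / replace_zeros_dataset) first"
        )
    return np.log(vals) @ sbp.basis.T


def ilr_inverse(z, sbp: SequentialBinaryPartition = DEFAULT_SBP,
                total: float = DAY_MINUTES) -> Composition:
    """Map ilr coordinates back to a strictly positive closed composition."""
    z = np.asarray(z, dtype=float)
    if z.shape != (len(sbp.parts) - 1,):
        raise ValueError(f"expected {len(sbp.parts) - 1} ilr coordinates, got {z.shape}")
    logp = sbp.basis.T @ z
    logp -= logp.max()  # guard exp overflow for extreme coordinates
    return close(np.exp(logp), total=total)


def ilr_inverse_rows(Z: np.ndarray, sbp: SequentialBinaryPartition = DEFAULT_SBP,
                     total: float = DAY_MINUTES) -> np.ndarray:
    """Vectorised ilr inverse for an (n, 6) coordinate array -> (n, 7) parts."""
    Z = np.asarray(Z, dtype=float)
    logp = Z @ sbp.basis
    logp -= logp.max(axis=1, keepdims=True)
    vals = np.exp(logp)
    return vals * (total / vals.sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# Zero replacement
# ---------------------------------------------------------------------------


def replace_zeros_fixed(comp, frame: float = ZERO_FRAME_MINUTES,
                        fraction: float = ZERO_FRACTION) -> Composition:
    """Replace zero parts with a fixed small duration (default 3.25 min, i.e.
    65% of the 5-minute sampling frame), shrinking the non-zero parts
    multiplicatively so the daily total is preserved."""
    if not isinstance(comp, Composition):
        comp = close(comp)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    zeros = comp.values == 0
    if not zeros.any():
        return comp
    imputed = frame * fraction
    n0 = int(zeros.sum())
    if n0 * imputed >= comp.total:
        raise CompositionError("imputed zeros would exceed the daily total")
    vals = comp.values * ((comp.total - n0 * imputed) / comp.total)
    vals[zeros] = imputed
    return Composition(vals, total=comp.total)


def _table_to_array(table) -> tuple[np.ndarray, bool]:
    if isinstance(table, pd.DataFrame):
        return table[list(PART_NAMES)].to_numpy(dtype=float), True
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_PARTS:
        raise CompositionError(f"expected an (n, {N_PARTS}) table, got {arr.shape}")
    return arr.copy(), False


def replace_zeros_dataset(table, total: float = DAY_MINUTES,
                          frame: float = ZERO_FRAME_MINUTES,
                          fraction: float = ZERO_FRACTION,
                          tol: float = 1e-6, max_iter: int = 50):
    """Impute structural zeros in an (n, 7) table of compositions.

    Zeros are treated as unobserved small durations at the 5-min sampling
    frame. Each zero entry is imputed at its conditional geometric expectation:
    ln(part) is regressed (OLS, with intercept) on the pivot-ilr coordinates of
    the remaining six parts over the rows where the part was observed, iterated
    to convergence. Rows without zeros are returned unchanged up to closure;
    rows with zeros keep their total by shrinking the observed parts
    multiplicatively. When regression is infeasible (a single row, or too few
    observed rows) the fixed 65%-of-frame rule is used instead.
    """
    X, was_df = _table_to_array(table)
    if X.shape[0] == 0:
        raise CompositionError("empty table")
    if np.any(X < 0):
        raise CompositionError("negative duration in table")
    dead = np.where(X.sum(axis=1) <= 0)[0]
    if dead.size:
        raise CompositionError(f"rows with all-zero parts: {dead.tolist()}")
    # close rows
    X = X * (total / X.sum(axis=1, keepdims=True))
    zero_mask = X == 0

    def _finish(arr: np.ndarray):
        if was_df:
            out = table.copy()
            out.loc[:, list(PART_NAMES)] = arr
            return out
        return arr

    if not zero_mask.any():
        return _finish(X)

    imputed0 = frame * fraction
    # initialise with the fixed rule (per-row multiplicative preservation)
    n0 = zero_mask.sum(axis=1)
    rows_z = n0 > 0
    X[rows_z] *= ((total - n0[rows_z, None] * imputed0) / total)
    X[zero_mask] = imputed0

    sub_sbp = SequentialBinaryPartition.pivot(PART_NAMES[:-1])  # any 6-part SBP
    min_obs = 12  # need enough observed rows for a 6-parameter regression

    for _ in range(max_iter):
        prev = X[zero_mask].copy()
        for j in range(N_PARTS):
            mis = zero_mask[:, j]
            if not mis.any():
                continue
            obs = ~mis
            if obs.sum() < min_obs:
                continue  # keep fixed-rule values
            others = np.delete(X, j, axis=1)
            W = np.log(others) @ sub_sbp.basis.T  # 6-part subcomposition ilr
            A = np.column_stack([np.ones(len(X)), W])
            coef, *_ = np.linalg.lstsq(A[obs], np.log(X[obs, j]), rcond=None)
            X[mis, j] = np.exp(A[mis] @ coef)
        # re-close rows with zeros: rescale the observed parts so the imputed
        # values fit inside the preserved total
        for i in np.where(rows_z)[0]:
            zi = zero_mask[i]
            imp_sum = X[i, zi].sum()
            if imp_sum >= total:
                raise CompositionError(f"imputed values exceed total in row {i}")
            X[i, ~zi] *= (total - imp_sum) / X[i, ~zi].sum()
        new = X[zero_mask]
        if np.max(np.abs(new - prev) / np.maximum(new, 1e-12)) < tol:
            break
    return _finish(X)


# ---------------------------------------------------------------------------
# Averages
# ---------------------------------------------------------------------------


def compositional_mean(table, total: float = DAY_MINUTES) -> Composition:
    """Compositional centre: closure of the vector of per-part geometric means."""
    X, _ = _table_to_array(table)
    if X.shape[0] == 0:
        raise CompositionError("empty table")
    if np.any(X <= 0):
        raise CompositionError(
            "compositional mean requires strictly positive rows; apply zero "
            "replacement first"
        )
    gm = np.exp(np.log(X).mean(axis=0))
    return close(gm, total=total)


def weighted_weekly_composition(day_comps: Iterable, day_types: Sequence[str],
                                weights: tuple[float, float] = (5.0, 2.0),
                                total: float = DAY_MINUTES) -> Composition:
    """Combine multi-day recalls into a weekly composition.

    Parts are arithmetically averaged within day type, combined as
    (5*weekday + 2*weekend)/7, and closed. Requires at least one recalled
    weekday and one weekend day.
    """
    comps = [c.values if isinstance(c, Composition) else _as_part_vector(c)
             for c in day_comps]
    day_types = list(day_types)
    if len(comps) != len(day_types):
        raise ValueError("day_comps and day_types must have equal length")
    bad = sorted(set(day_types) - {"weekday", "weekend"})
    if bad:
        raise ValueError(f"unknown day types: {bad}")
    arr = np.array(comps)
    means = {}
    for dt in ("weekday", "weekend"):
        mask = np.array([t == dt for t in day_types])
        if not mask.any():
            raise ValueError(f"no {dt} recall: at least one {dt} day is required")
        means[dt] = arr[mask].mean(axis=0)
    w_wd, w_we = weights
    weekly = (w_wd * means["weekday"] + w_we * means["weekend"]) / (w_wd + w_we)
    return close(weekly, total=total)
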