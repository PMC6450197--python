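"""Item banks with within- and between-item multidimensionality.

Two loading structures recur throughout the simulation studies:

* ``bank1`` (within-item multidimensionality): every item loads on the
  primary dimension theta_1; disjoint blocks of items additionally load on
  one auxiliary dimension each.
* ``bank2`` (between-item multidimensionality): every item loads on exactly
  one dimension.

Block sizes follow a largest-remainder allocation of ``n_items`` over the
given proportions (default 40/35/25).  Each item carries a difficulty
``beta`` (drawn N(0, 1) by default), a 0/1 loading vector, and generating
slopes ``alpha`` (drawn U(0.5, 2) by default) that are used only by the
data generator — the rating engine's working model fixes slopes at 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemBank",
    "generate_bank",
    "largest_remainder",
    "read_bank",
    "write_bank",
]


@dataclass(frozen=True)
class Item:
    """One calibrated item: difficulty, loading pattern, generating slopes."""

    item_id: int
    difficulty: float
    loadings: tuple[int, ...]
    gen_slopes: tuple[float, ...]

    def __post_init__(self):
        if self.item_id < 1:
            raise ValueError(f"item_id must be >= 1, got {self.item_id}")
        if len(self.loadings) != len(self.gen_slopes):
            raise ValueError("loadings and gen_slopes must have equal length")
        if not any(self.loadings):
            raise ValueError(f"item {self.item_id}: at least one loading must be 1")
        for m, (d, a) in enumerate(zip(self.loadings, self.gen_slopes)):
            if d not in (0, 1):
                raise ValueError(f"item {self.item_id}: loading d{m+1} must be 0/1")
            if (d == 1) != (a > 0):
                raise ValueError(
                    f"item {self.item_id}: gen_slopes[{m}] must be positive "
                    f"exactly where the item loads"
                )

    @property
    def n_dims(self) -> int:
        return len(self.loadings)


@dataclass
class ItemBank:
    """Ordered collection of items sharing a dimensionality M."""

    items: list[Item]
    n_dims: int
    pattern_label: str = "custom"

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        for it in self.items:
            if it.n_dims != self.n_dims:
                raise ValueError(
                    f"item {it.item_id} has M={it.n_dims}, bank has M={self.n_dims}"
                )
        self.items = sorted(self.items, key=lambda it: it.item_id)

    def __len__(self) -> int:
        return len(self.items)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ItemBank)
            and self.n_dims == other.n_dims
            and self.pattern_label == other.pattern_label
            and self.items == other.items
        )

    # --- array views used by the engine and simulator -------------------
    @property
    def difficulties(self) -> np.ndarray:
        return np.array([it.difficulty for it in self.items])

    @property
    def loadings(self) -> np.ndarray:
        return np.array([it.loadings for it in self.items], dtype=float)

    @property
    def gen_slopes(self) -> np.ndarray:
        return np.array([it.gen_slopes for it in self.items], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        m = self.n_dims
        rows = {
            "item_id": [it.item_id for it in self.items],
            "beta": [it.difficulty for it in self.items],
        }
        for k in range(m):
            rows[f"d{k+1}"] = [it.loadings[k] for it in self.items]
        for k in range(m):
            rows[f"a{k+1}"] = [it.gen_slopes[k] for it in self.items]
        return pd.DataFrame(rows)


def largest_remainder(n: int, proportions) -> list[int]:
    """Integer allocation of ``n`` over ``proportions`` (Hare quota).

    Floors the exact quotas, then distributes the leftover units to the
    largest fractional remainders (ties broken by lower index).
    """
    p = np.asarray(proportions, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    quota = n * p
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    # stable: highest remainder first, lower index wins ties
    order = np.lexsort((np.arange(len(p)), -rem))
    for k in order[: n - counts.sum()]:
        counts[k] += 1
    return counts.tolist()


def _draw(sampler, size: int, rng: np.random.Generator, default) -> np.ndarray:
    """Draw ``size`` values from a distribution spec.

    Accepts None (use the study default), a callable ``f(size, rng)``, or a
    dict like ``{"dist": "normal", "loc": 0, "scale": 1}`` /
    ``{"dist": "uniform", "low": 0.5, "high": 2}``.
    """
    if sampler is None:
        return default(size, rng)
    if callable(sampler):
        return np.asarray(sampler(size, rng), dtype=float)
    spec = dict(sampler)
    name = spec.pop("dist")
    if name == "normal":
        return rng.normal(spec.get("loc", 0.0), spec.get("scale", 1.0), size)
    if name == "uniform":
        return rng.uniform(spec.get("low", 0.0), spec.get("high", 1.0), size)
    raise ValueError(f"unknown distribution spec {name!r}")


def generate_bank(
    pattern: str,
    n_items: int = 200,
    n_dims: int = 3,
    proportions=(0.40, 0.35, 0.25),
    difficulty_sampler=None,
    slope_sampler=None,
    seed=None,
    rng: np.random.Generator | None = None,
) -> ItemBank:
    """Generate a ``bank1`` or ``bank2`` item bank.

    ``bank1``: all items load on dimension 1; the block of the m-th
    proportion (m >= 2) additionally loads on dimension m, so the auxiliary
    blocks are disjoint.  ``bank2``: the m-th block loads on dimension m
    only.  Difficulties default to N(0, 1), slopes to U(0.5, 2); slopes are
    set only on loaded dimensions.
    """
    if pattern not in ("bank1", "bank2"):
        raise ValueError(f"pattern must be 'bank1' or 'bank2', got {pattern!r}")
    if len(proportions) != n_dims:
        raise ValueError("need one proportion per dimension")
    if n_items < n_dims:
        raise ValueError(f"n_items={n_items} < n_dims={n_dims}")
    if rng is None:
        rng = np.random.default_rng(seed)

    counts = largest_remainder(n_items, proportions)
    beta = _draw(difficulty_sampler, n_items, rng, lambda s, r: r.normal(0.0, 1.0, s))

    loadings = np.zeros((n_items, n_dims), dtype=int)
    start = 0
    for m, c in enumerate(counts):
        block = slice(start, start + c)
        if pattern == "bank1":
            loadings[block, 0] = 1
            if m >= 1:
                loadings[block, m] = 1
        else:
            loadings[block, m] = 1
        start += c

    raw = _draw(
        slope_sampler, n_items * n_dims, rng, lambda s, r: r.uniform(0.5, 2.0, s)
    ).reshape(n_items, n_dims)
    slopes = raw * loadings

    items = [
        Item(
            item_id=j + 1,
            difficulty=float(beta[j]),
            loadings=tuple(int(v) for v in loadings[j]),
            gen_slopes=tuple(float(v) for v in slopes[j]),
        )
        for j in range(n_items)
    ]
    return ItemBank(items=items, n_dims=n_dims, pattern_label=pattern)


def write_bank(bank: ItemBank, path) -> None:
    """Serialise a bank to CSV (columns item_id, beta, d1..dM, a1..aM) or JSON."""
    path = Path(path)
    df = bank.to_frame()
    if path.suffix == ".json":
        payload = {
            "n_dims": bank.n_dims,
            "pattern_label": bank.pattern_label,
            "items": df.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        with path.open("w") as fh:
            fh.write(f"# pattern_label={bank.pattern_label}\n")
            # %.17g guarantees exact binary round-trip of stored reals
            df.to_csv(fh, index=False, float_format="%.17g")


def read_bank(path) -> ItemBank:
    """Read a bank written by :func:`write_bank`; validates every row."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        records = payload["items"]
        n_dims = int(payload["n_dims"])
        label = payload.get("pattern_label", "custom")
    else:
        label = "custom"
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("#"):
                if "pattern_label=" in first:
                    label = first.split("pattern_label=")[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
        dcols = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
        n_dims = len(dcols)
        records = df.to_dict(orient="records")
    if n_dims < 1:
        raise ValueError(f"{path}: no loading columns found")

    items = []
    for row_no, rec in enumerate(records, start=1):
        try:
            keys = [f"d{k+1}" for k in range(n_dims)] + [f"a{k+1}" for k in range(n_dims)]
            missing = [k for k in keys + ["item_id", "beta"] if k not in rec]
            if missing:
                raise ValueError(f"missing columns {missing}")
            items.append(
                Item(
                    item_id=int(rec["item_id"]),
                    difficulty=float(rec["beta"]),
                    loadings=tuple(int(rec[f"d{k+1}"]) for k in range(n_dims)),
                    gen_slopes=tuple(float(rec[f"a{k+1}"]) for k in range(n_dims)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad item at row {row_no}: {exc}") from exc
    return ItemBank(items=items, n_dims=n_dims, pattern_label=label)
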