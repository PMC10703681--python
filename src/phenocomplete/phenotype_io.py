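"""Typed ingestion, normalization, splitting and serialization of phenotype matrices.

The central container is :class:`MaskedPhenotypeMatrix`: an N x P value matrix
with an explicit observedness mask M (M_ij = 1 iff phenotype j was measured on
individual i) and a schema declaring each column continuous, binary, or ordinal
(ordinal phenotypes are processed as continuous but keep their label so reports
can flag them). Missing cells carry NaN and are never read as data.

Columns are ordered so that continuous/ordinal phenotypes precede binary ones;
downstream code partitions mixed-type operations by the single index C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_KINDS = ("continuous", "binary", "ordinal")

#: tokens (case-insensitive, after stripping) read as missing
MISSING_TOKENS = frozenset({"", "na", "nan"})


@dataclass(frozen=True)
class PhenotypeSchema:
    """Ordered phenotype names and their declared kinds.

    ``n_continuous`` (C) counts continuous *and* ordinal columns; the invariant
    maintained throughout the package is that the first C columns are treated
    as continuous and columns C..P-1 are binary.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate phenotype names in schema")
        for k in self.kinds:
            if k not in VALID_KINDS:
                raise ValueError(f"unknown phenotype kind {k!r}")

    @property
    def n_phenotypes(self) -> int:
        return len(self.names)

    @property
    def n_continuous(self) -> int:
        """C: number of columns treated as continuous (ordinal included)."""
        return sum(k != "binary" for k in self.kinds)

    @property
    def is_binary(self) -> np.ndarray:
        return np.array([k == "binary" for k in self.kinds], dtype=bool)

    @property
    def continuous_first(self) -> bool:
        """True iff continuous/ordinal columns all precede binary columns."""
        return not any(
            self.kinds[i] == "binary" and self.kinds[j] != "binary"
            for i in range(len(self.kinds))
            for j in range(i + 1, len(self.kinds))
        )

    def reordered(self) -> tuple["PhenotypeSchema", np.ndarray]:
        """Return a schema with continuous/ordinal columns first and the
        permutation (new position -> old position) that achieves it.

        Relative order within each block is preserved.
        """
        order = np.array(
            sorted(range(len(self.names)), key=lambda i: (self.kinds[i] == "binary", i)),
            dtype=int,
        )
        return (
            PhenotypeSchema(
                names=tuple(self.names[i] for i in order),
                kinds=tuple(self.kinds[i] for i in order),
            ),
            order,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {n: {"kind": k} for n, k in zip(self.names, self.kinds)}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeSchema":
        payload = json.loads(Path(path).read_text())
        return cls(
            names=tuple(payload.keys()),
            kinds=tuple(v["kind"] for v in payload.values()),
        )


@dataclass
class MaskedPhenotypeMatrix:
    """N x P phenotype values with an explicit observedness mask.

    ``values`` holds NaN wherever ``mask`` is False; binary columns contain
    only 0/1 where observed. ``original_columns`` optionally remembers the
    column order of the source file so outputs can be written back in it.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray
    schema: PhenotypeSchema
    original_columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.ids = tuple(str(i) for i in self.ids)
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape if self.values.ndim == 2 else (len(self.values), 0)
        if self.values.ndim != 2 or self.mask.shape != self.values.shape:
            raise ValueError("values and mask must be 2-D with equal shape")
        if len(self.ids) != n:
            raise ValueError("number of ids must match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sample IDs")
        if p != self.schema.n_phenotypes:
            raise ValueError("column count does not match schema")
        if not self.schema.continuous_first:
            raise ValueError("schema must order continuous/ordinal columns first")
        if np.isfinite(self.values[~self.mask]).any():
            raise ValueError("unmasked sentinel: missing cells must be NaN")
        if np.isnan(self.values[self.mask]).any():
            raise ValueError("observed cells may not be NaN")
        isbin = self.schema.is_binary
        if isbin.any():
            obs = self.values[:, isbin]
            ok = np.isnan(obs) | (obs == 0.0) | (obs == 1.0)
            if not ok.all():
                raise ValueError("binary columns must contain only 0/1 where observed")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    @property
    def observed_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def take_rows(self, index: Sequence[int] | np.ndarray) -> "MaskedPhenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return MaskedPhenotypeMatrix(
            ids=tuple(self.ids[i] for i in index),
            values=self.values[index].copy(),
            mask=self.mask[index].copy(),
            schema=self.schema,
            original_columns=self.original_columns,
        )

    def copy(self) -> "MaskedPhenotypeMatrix":
        return MaskedPhenotypeMatrix(
            ids=self.ids,
            values=self.values.copy(),
            mask=self.mask.copy(),
            schema=self.schema,
            original_columns=self.original_columns,
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Per-column affine normalization fitted on a training split.

    Continuous/ordinal columns are z-scored with the population (divide-by-N)
    standard deviation; binary columns are left 0/1 in the matrix, with
    ``binary_recode`` recording that the model encodes them as -0.5/+0.5 at
    its input.
    """

    names: tuple[str, ...]
    mean: np.ndarray  # NaN at binary positions
    sd: np.ndarray  # NaN at binary positions
    binary_recode: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "names": list(self.names),
            "mean": [None if np.isnan(m) else m for m in self.mean],
            "sd": [None if np.isnan(s) else s for s in self.sd],
            "binary_recode": self.binary_recode,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        payload = json.loads(Path(path).read_text())
        return cls(
            names=tuple(payload["names"]),
            mean=np.array([np.nan if m is None else m for m in payload["mean"]]),
            sd=np.array([np.nan if s is None else s for s in payload["sd"]]),
            binary_recode=bool(payload["binary_recode"]),
        )


def _detect_sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_phenotype_table(
    path: str | Path,
    schema: PhenotypeSchema | str | Path,
) -> MaskedPhenotypeMatrix:
    """Read a delimited phenotype table into a :class:`MaskedPhenotypeMatrix`.

    The file must have a header row whose first column is the sample ID
    ("IID"); every other header must appear in the schema and vice versa.
    Empty fields, "NA" and "NaN" (case-insensitive) are read as missing.
    Columns are permuted so continuous/ordinal precede binary; the file's
    column order is retained in ``original_columns``.
    """
    if not isinstance(schema, PhenotypeSchema):
        schema = PhenotypeSchema.from_json(schema)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ValueError("file has no columns")
    id_col = df.columns[0]
    file_cols = list(df.columns[1:])
    unknown = set(file_cols) - set(schema.names)
    if unknown:
        raise ValueError(f"columns not in schema: {sorted(unknown)}")
    absent = set(schema.names) - set(file_cols)
    if absent:
        raise ValueError(f"schema columns missing from file: {sorted(absent)}")

    ordered_schema, _ = schema.reordered()
    n = len(df)
    p = schema.n_phenotypes
    values = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    for j, name in enumerate(ordered_schema.names):
        col = df[name].astype(str).str.strip()
        missing = col.str.lower().isin(MISSING_TOKENS)
        try:
            numeric = pd.to_numeric(col.where(~missing), errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {name!r}: {exc}") from exc
        values[:, j] = numeric.to_numpy(dtype=float)
        mask[:, j] = ~missing.to_numpy()
        if ordered_schema.kinds[j] == "binary":
            obs = values[mask[:, j], j]
            if not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError(f"binary column {name!r} contains values outside {{0,1}}")
    ids = df[id_col].astype(str).tolist()
    return MaskedPhenotypeMatrix(
        ids=tuple(ids),
        values=values,
        mask=mask,
        schema=ordered_schema,
        original_columns=tuple(file_cols),
    )


def write_phenotype_table(
    data: MaskedPhenotypeMatrix,
    path: str | Path,
    values: np.ndarray | None = None,
) -> None:
    """Write a phenotype table (TSV by default, CSV for .csv paths).

    Missing cells are written as "NA". If ``values`` is given it replaces the
    matrix's values (used to write imputed completions with the original mask
    ignored); it must have the same shape.
    """
    vals = data.values if values is None else np.asarray(values, dtype=float)
    if vals.shape != data.values.shape:
        raise ValueError("replacement values have wrong shape")
    out_cols = data.original_columns or data.schema.names
    col_idx = {n: j for j, n in enumerate(data.schema.names)}
    df = pd.DataFrame({"IID": list(data.ids)})
    for name in out_cols:
        j = col_idx[name]
        col = vals[:, j].astype(object)
        if values is None:
            col[~data.mask[:, j]] = np.nan
        df[name] = col
    df.to_csv(path, sep=_detect_sep(path), index=False, na_rep="NA")


def split_individuals(
    data: MaskedPhenotypeMatrix,
    test_fraction: float,
    validation_fraction: float,
    seed: int,
) -> tuple[MaskedPhenotypeMatrix, MaskedPhenotypeMatrix, MaskedPhenotypeMatrix]:
    """Randomly partition individuals into (train, validation, test).

    ``test_fraction`` applies to all N rows; ``validation_fraction`` applies
    to the non-test remainder — so (0.5, 0.2) reproduces a 50% held-out test
    set with an 80-20 train/validation split of the rest. Identical seeds
    give identical splits.
    """
    for name, f in (("test_fraction", test_fraction), ("validation_fraction", validation_fraction)):
        if not (0.0 <= f < 1.0):
            raise ValueError(f"{name} must be in [0, 1), got {f}")
    n = data.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    n_val = int(round((n - n_test) * validation_fraction))
    for name, frac, count in (
        ("test", test_fraction, n_test),
        ("validation", validation_fraction, n_val),
    ):
        if frac > 0 and count == 0 and n > 0:
            raise ValueError(f"N={n} too small for a non-empty {name} split at fraction {frac}")
    test_idx = np.sort(perm[:n_test])
    val_idx = np.sort(perm[n_test : n_test + n_val])
    train_idx = np.sort(perm[n_test + n_val :])
    return data.take_rows(train_idx), data.take_rows(val_idx), data.take_rows(test_idx)


def fit_normalization(train: MaskedPhenotypeMatrix) -> NormalizationStats:
    """Estimate per-column z-scoring statistics on observed training entries.

    Continuous/ordinal columns require at least two observed values and
    nonzero variance; the population (divide-by-N) SD is used. Binary columns
    get no z-scoring; the -0.5/+0.5 input recoding is recorded as a flag.
    """
    p = train.n_phenotypes
    mean = np.full(p, np.nan)
    sd = np.full(p, np.nan)
    for j in range(train.schema.n_continuous):
        obs = train.values[train.mask[:, j], j]
        name = train.schema.names[j]
        if obs.size == 0:
            raise ValueError(f"column {name!r} has no observed entries")
        if obs.size < 2:
            raise ValueError(f"column {name!r} has fewer than 2 observed entries")
        m = float(obs.mean())
        s = float(obs.std(ddof=0))
        if s <= 0.0:
            raise ValueError(f"column {name!r} has zero variance on the training split")
        mean[j], sd[j] = m, s
    return NormalizationStats(names=train.schema.names, mean=mean, sd=sd)


def apply_normalization(
    data: MaskedPhenotypeMatrix,
    stats: NormalizationStats,
    direction: str = "forward",
) -> MaskedPhenotypeMatrix:
    """Z-score (or un-z-score) the continuous columns of ``data``.

    Only observed cells are transformed, the mask is untouched, and
    forward followed by inverse is the identity on observed cells. Binary
    columns pass through unchanged (their model-input recoding happens at
    encoding time, not in the stored matrix).
    """
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    if stats.names != data.schema.names:
        raise ValueError("normalization stats do not match data schema")
    out = data.copy()
    for j in range(data.schema.n_continuous):
        m, s = stats.mean[j], stats.sd[j]
        obs = out.mask[:, j]
        if direction == "forward":
            out.values[obs, j] = (out.values[obs, j] - m) / s
        else:
            out.values[obs, j] = out.values[obs, j] * s + m
    return out
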