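"""Feature-by-sample abundance tables: reading, writing, validation, normalization.

The central container is :class:`AbundanceTable`, a nonnegative features x
samples matrix with string identifiers and an explicit ``scale`` flag
("raw" or "relative").  Relative tables have every sample column summing
to one, so a value of 0.1 means the feature holds 10% of the sample's
total observations.

The on-disk format is a plain UTF-8 TSV: a header row whose first cell is
the literal ``feature_id`` followed by sample identifiers, then one row
per feature.  Values are written at full round-trip precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "normalize_relative",
]

#: column sums of a relative table must match 1 to this tolerance
RELATIVE_TOL = 1e-9
#: looser tolerance used when inferring the scale of a freshly parsed file
RELATIVE_INFER_TOL = 1e-6

INDEX_HEADER = "feature_id"


class AbundanceTableError(ValueError):
    """Invalid abundance-table content (parse or validation failure)."""


@dataclass(frozen=True)
class AbundanceTable:
    """Nonnegative feature-by-sample abundance matrix.

    Parameters
    ----------
    feature_ids :
        Unique feature (e.g. OTU) identifiers, one per matrix row.
    sample_ids :
        Unique sample identifiers, one per matrix column.
    values :
        Nonnegative real matrix of shape ``(len(feature_ids), len(sample_ids))``.
    scale :
        ``"raw"`` for unnormalized abundances, ``"relative"`` when every
        sample column sums to one (tolerance ``1e-9``).
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    scale: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise AbundanceTableError("values must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise AbundanceTableError("duplicate feature identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AbundanceTableError("duplicate sample identifiers")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise AbundanceTableError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise AbundanceTableError("non-finite abundance values")
        if (values < 0).any():
            f, s = np.argwhere(values < 0)[0]
            raise AbundanceTableError(
                f"negative abundance at feature {self.feature_ids[f]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.scale not in ("raw", "relative"):
            raise AbundanceTableError(f"unknown scale {self.scale!r}")
        if self.scale == "relative":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, rtol=0.0, atol=RELATIVE_TOL):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
                raise AbundanceTableError(
                    f"scale='relative' but column {bad!r} sums to "
                    f"{sums[np.argmax(np.abs(sums - 1.0))]:.12g}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids) -> np.ndarray:
        """Column positions of the given sample identifiers."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """View as a pandas DataFrame (features x samples)."""
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


def read_abundance_table(path, *, dialect: str = "tsv") -> AbundanceTable:
    """Read a TSV abundance table, validating and inferring its scale.

    The first row holds sample identifiers (first cell ignored as the
    index header), the first column feature identifiers.  The scale is
    inferred as ``"relative"`` iff every column sums to 1 within 1e-6,
    otherwise ``"raw"``.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header[1:])) != len(header[1:]):
        raise AbundanceTableError(f"{path}: duplicate sample identifiers in header")
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if frame.shape[1] == 0:
        raise AbundanceTableError(f"{path}: no sample columns")
    feature_ids = [str(f) for f in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for a precise error message
        for i, fid in enumerate(feature_ids):
            for j, sid in enumerate(sample_ids):
                try:
                    float(frame.iat[i, j])
                except (TypeError, ValueError):
                    raise AbundanceTableError(
                        f"{path}: non-numeric cell at feature {fid!r}, sample {sid!r}"
                    ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise AbundanceTableError(
            f"{path}: missing value at feature {feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise AbundanceTableError(
            f"{path}: negative value at feature {feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    sums = values.sum(axis=0)
    relative = bool(np.allclose(sums, 1.0, rtol=0.0, atol=RELATIVE_INFER_TOL))
    if relative:
        # repair rounding drift from the text representation
        values = values / sums
    return AbundanceTable(
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(sample_ids),
        values=values,
        scale="relative" if relative else "raw",
    )


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write ``table`` as TSV in the dialect accepted by :func:`read_abundance_table`."""
    if table.n_features == 0:
        raise AbundanceTableError("refusing to write a table with no features")
    path = Path(path)
    frame = table.to_frame()
    frame.index.name = INDEX_HEADER
    # repr-precision floats so that read(write(t)) == t exactly
    frame.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total so columns sum to one.

    Idempotent: an already-relative table is returned unchanged.  A sample
    with zero total is an error, because a proportion is undefined there
    and silently dropping the sample would change the design size.
    """
    if table.scale == "relative":
        return table
    totals = table.values.sum(axis=0)
    if (totals <= 0).any():
        bad = table.sample_ids[int(np.argmin(totals))]
        raise AbundanceTableError(
            f"sample {bad!r} has zero total abundance; proportions undefined"
        )
    return replace(table, values=table.values / totals, scale="relative")
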