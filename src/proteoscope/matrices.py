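"""Shared in-memory containers for intensity matrices.

The whole pipeline moves features x samples tables around: the MS proteome,
the phosphoproteome, the RPPA panel and the collapsed per-cell-line views all
share one container, :class:`AbundanceMatrix`, which pairs the value table
with per-sample metadata (cell line, replicate, lineage) and a *scale tag*.
The tag records which transformations have been applied and lets each
operation refuse inputs on the wrong scale instead of silently producing
nonsense (e.g. median-normalizing an already collapsed matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Legal scale tags, in the order the preprocessing pipeline produces them.
#: ``raw``      -- linear intensities as quantified (NaN = missing)
#: ``log2``     -- log2 values from an external pipeline (RPPA rawlog2)
#: ``log2p1``   -- log2(x+1), median-adjusted
#: ``lognorm``  -- ln(1 + sf * x / colsum) (LogNormalize)
#: ``collapsed``-- replicate-averaged, one column per cell line
SCALES = ("raw", "log2", "log2p1", "lognorm", "collapsed")

META_COLUMNS = ("cell_line", "replicate", "lineage")


class ScaleError(ValueError):
    """An operation was applied to a matrix on the wrong scale."""


class ConfigError(ValueError):
    """Invalid configuration or parameter value."""


@dataclass
class AbundanceMatrix:
    """Features x samples intensity table with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with one column per sample.
        Missing measurements are NaN.
    meta
        DataFrame indexed by sample ID with columns ``cell_line``,
        ``replicate`` and ``lineage``. Must cover exactly the sample
        columns of ``values``.
    scale
        One of :data:`SCALES`.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        missing_meta = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_meta:
            raise ValueError(f"meta is missing columns {missing_meta}")
        if list(self.values.columns) != list(self.meta.index):
            if set(self.values.columns) == set(self.meta.index):
                # same samples, different order: align silently
                self.meta = self.meta.loc[self.values.columns]
            else:
                raise ValueError("sample columns of values do not match meta index")
        if self.scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("raw-scale intensities must be non-negative")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate feature IDs, e.g. {dup}")

    # -- convenience views -------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.meta["cell_line"]))

    @property
    def lineages(self) -> list[str]:
        return list(dict.fromkeys(self.meta["lineage"]))

    def line_columns(self) -> dict[str, list[str]]:
        """Sample columns grouped by cell line, preserving order."""
        out: dict[str, list[str]] = {}
        for sample, line in self.meta["cell_line"].items():
            out.setdefault(line, []).append(sample)
        return out

    def lineage_of_line(self) -> dict[str, str]:
        return {
            line: grp["lineage"].iloc[0]
            for line, grp in self.meta.groupby("cell_line", sort=False)
        }

    # -- scale bookkeeping -------------------------------------------------
    def require_scale(self, *allowed: str) -> None:
        if self.scale not in allowed:
            raise ScaleError(
                f"operation requires scale in {allowed}, got {self.scale!r}"
            )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        """New matrix with replaced values (same or subset features/samples)."""
        meta = self.meta.loc[values.columns]
        return AbundanceMatrix(values=values, meta=meta, scale=scale or self.scale)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.meta.copy(), self.scale)


def make_meta(
    cell_lines: list[str],
    replicates: dict[str, list[str]],
    lineage: dict[str, str],
) -> pd.DataFrame:
    """Build a sample metadata frame from line -> replicate-sample lists."""
    rows = []
    for line in cell_lines:
        for i, sample in enumerate(replicates[line], start=1):
            rows.append((sample, line, i, lineage[line]))
    df = pd.DataFrame(rows, columns=["sample", *META_COLUMNS]).set_index("sample")
    return df


def collapsed_meta(lines: list[str], lineage_of_line: dict[str, str]) -> pd.DataFrame:
    """Metadata frame for a collapsed (one column per cell line) matrix."""
    return pd.DataFrame(
        {
            "cell_line": lines,
            "replicate": [0] * len(lines),
            "lineage": [lineage_of_line[l] for l in lines],
        },
        index=pd.Index(lines, name="sample"),
    )
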