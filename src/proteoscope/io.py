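"""Readers and writers for every table schema the pipeline exchanges.

Canonical interchange is TSV (long format where natural); CSV is accepted
on read via delimiter sniffing. Abundance matrices travel with a small
header block: a ``#scale`` line followed by three ``#``-prefixed metadata
rows (cell_line, replicate, lineage) aligned with the sample columns.
Schema validation errors name the offending column.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .cna import CNAMatrix
from .matrices import AbundanceMatrix

# required columns and dtype casts per named schema
SCHEMAS: dict[str, dict[str, type]] = {
    "psm": {
        "protein": str,
        "site": int,
        "peptide": str,
        "charge": int,
        "missed_cleavages": int,
        "composition": str,
        "sample": str,
    },
    "ks_map": {"kinase": str, "substrate": str, "site_label": str},
    "panel": {
        "antibody": str,
        "targets": str,
        "representative": str,
        "is_phospho": bool,
    },
    "sites": {
        "protein": str,
        "residue": str,
        "position": int,
        "localization_prob": float,
    },
}


class SchemaError(ValueError):
    """Input table violates its declared schema."""


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV/CSV table and validate it against a named schema.

    Raises :class:`SchemaError` naming the missing column or the column and
    line of the first type violation.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    spec = SCHEMAS[schema]
    missing = [col for col in spec if col not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    for col, typ in spec.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header is line 1
                raise SchemaError(
                    f"{path.name}: column {col!r} has a non-numeric value at line {line}"
                )
            df[col] = coerced.astype(float if typ is float else "int64")
        elif typ is bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
        else:
            df[col] = df[col].astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

def write_abundance(m: AbundanceMatrix, path: str | Path) -> None:
    """TSV with a ``#scale`` line and three sample-metadata header rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#scale\t{m.scale}\n")
        fh.write("feature\t" + "\t".join(map(str, m.samples)) + "\n")
        for key in ("cell_line", "replicate", "lineage"):
            row = "\t".join(str(m.meta.loc[s, key]) for s in m.samples)
            fh.write(f"#{key}\t{row}\n")
        m.values.to_csv(fh, sep="\t", header=False, float_format="%.10g")


def read_abundance(path: str | Path) -> AbundanceMatrix:
    path = Path(path)
    with open(path) as fh:
        scale_line = fh.readline().rstrip("\n").split("\t")
        if scale_line[0] != "#scale":
            raise SchemaError(f"{path.name}: first line must be '#scale<TAB><tag>'")
        scale = scale_line[1]
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        meta_rows = {}
        for key in ("cell_line", "replicate", "lineage"):
            parts = fh.readline().rstrip("\n").split("\t")
            if parts[0] != f"#{key}":
                raise SchemaError(f"{path.name}: expected metadata row '#{key}'")
            meta_rows[key] = parts[1:]
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0,
                             names=["feature", *samples])
    meta = pd.DataFrame(meta_rows, index=pd.Index(samples, name="sample"))
    meta["replicate"] = pd.to_numeric(meta["replicate"])
    return AbundanceMatrix(values=values, meta=meta, scale=scale)


# ---------------------------------------------------------------------------
# CNA
# ---------------------------------------------------------------------------

def write_cna(cna: CNAMatrix, path: str | Path) -> None:
    df = cna.values.copy()
    df.insert(0, "arm", cna.arms)
    df.index.name = "gene"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_cna(path: str | Path) -> CNAMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col="gene")
    if "arm" not in df.columns:
        raise SchemaError(f"{Path(path).name}: missing required column 'arm'")
    arms = df.pop("arm")
    return CNAMatrix(values=df.astype(float), arms=arms)


# ---------------------------------------------------------------------------
# Site-glycan tables
# ---------------------------------------------------------------------------

def write_site_glycans(table, path: str | Path, wide: bool = False) -> None:
    """Write a SiteGlycanTable as long (default) or wide TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if wide:
        df = table.counts.copy()
        df.insert(0, "glycan_class", table.classes)
        df.to_csv(path, sep="\t")
        return
    long = (
        table.counts.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_3": "sample"})
    )
    long = long[long["count"] > 0]
    classes = table.classes.rename("glycan_class").reset_index()
    long = long.merge(classes, on=["protein", "site", "composition"])
    long.to_csv(path, sep="\t", index=False)
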