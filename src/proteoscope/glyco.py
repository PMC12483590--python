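"""Site-specific glycan quantification by spectral counting.

A *site-specific glycan* is one glycan composition attached at one
glycosylation site of one protein. Its abundance is estimated by spectral
counting: the number of glycopeptide-spectrum matches (PSMs) supporting that
(protein, site, composition) key in a sample, pooled over peptide length,
missed cleavages and precursor charge state.

Glycans are classified into mutually exclusive classes with priority
sialylated > fucosylated > high-mannose > other:

* **sialylated** -- at least one NeuAc;
* **fucosylated** -- no NeuAc, at least one Fuc;
* **high-mannose** -- the chitobiose core (HexNAc = 2) carrying >= 5 Hex,
  with no Fuc or NeuAc;
* **other** -- everything else.

The replicate-consistency filter keeps a site-specific glycan if it was
observed in strictly more than half of the replicates of at least one cell
line.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

GLYCAN_CLASSES = ("sialylated", "fucosylated", "high_mannose", "other")

#: Canonical monosaccharide ordering for the string form.
_CANONICAL_ORDER = ("HexNAc", "Hex", "Fuc", "NeuAc")

_TOKEN_RE = re.compile(r"([A-Za-z][A-Za-z0-9]*)\((\-?\d+)\)")


class GlycanParseError(ValueError):
    """Malformed glycan composition string."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide count multiset of one glycan.

    Stored as a sorted tuple of (token, count) pairs so instances are
    hashable and usable as table keys.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise GlycanParseError("empty glycan composition")
        for token, count in self.counts:
            if count < 0:
                raise GlycanParseError(f"negative count for token {token!r}")
        if all(c == 0 for _, c in self.counts):
            raise GlycanParseError("glycan composition has no residues")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GlycanComposition":
        return cls(tuple(sorted(d.items(), key=_token_sort_key)))

    def get(self, token: str) -> int:
        return dict(self.counts).get(token, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def canonical(self) -> str:
        """Order-stable string form: HexNAc, Hex, Fuc, NeuAc, then others."""
        d = self.as_dict()
        parts = []
        for token in _CANONICAL_ORDER:
            if d.get(token, 0) > 0:
                parts.append(f"{token}({d[token]})")
        for token in sorted(t for t in d if t not in _CANONICAL_ORDER):
            if d[token] > 0:
                parts.append(f"{token}({d[token]})")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


def _token_sort_key(item: tuple[str, int]):
    token = item[0]
    try:
        return (0, _CANONICAL_ORDER.index(token), token)
    except ValueError:
        return (1, 0, token)


def parse_glycan_composition(text: str) -> GlycanComposition:
    """Parse a Byonic-style composition string like ``"HexNAc(4)Hex(5)NeuAc(2)"``.

    Raises
    ------
    GlycanParseError
        If the string contains anything besides ``Token(count)`` runs, a
        non-integer count, or a negative count; the message names the
        offending fragment.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError("empty composition string")
    text = text.strip()
    pos = 0
    counts: Counter[str] = Counter()
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise GlycanParseError(
                f"malformed glycan composition near {text[pos:m.start()]!r} in {text!r}"
            )
        token, num = m.group(1), int(m.group(2))
        if num < 0:
            raise GlycanParseError(f"negative count for token {token!r} in {text!r}")
        counts[token] += num
        pos = m.end()
    if pos != len(text):
        raise GlycanParseError(f"malformed glycan composition near {text[pos:]!r} in {text!r}")
    return GlycanComposition.from_dict(dict(counts))


def classify_glycan(comp: GlycanComposition) -> str:
    """Mutually exclusive glycan class with priority sialylated > fucosylated
    > high-mannose > other."""
    if comp.get("NeuAc") >= 1:
        return "sialylated"
    if comp.get("Fuc") >= 1:
        return "fucosylated"
    if comp.get("HexNAc") == 2 and comp.get("Hex") >= 5:
        return "high_mannose"
    return "other"


def classify_composition_string(text: str) -> str:
    return classify_glycan(parse_glycan_composition(text))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

#: Columns a PSM table must carry.
PSM_REQUIRED = ("protein", "site", "composition", "sample")


@dataclass
class SiteGlycanTable:
    """Spectral counts of site-specific glycans.

    ``counts`` is indexed by (protein, site, composition-canonical-string)
    with one integer column per sample; ``classes`` labels each row key with
    its glycan class. Zero means "no PSM for this key in this sample".
    """

    counts: pd.DataFrame
    classes: pd.Series

    @property
    def n_keys(self) -> int:
        return len(self.counts)

    def total_counts(self) -> int:
        return int(self.counts.to_numpy().sum())


def aggregate_site_glycans(psms: pd.DataFrame) -> SiteGlycanTable:
    """Sum PSMs into site-specific glycan spectral counts.

    The count for key (protein, site, composition, sample) is the number of
    PSM rows with that key, pooling over peptide sequence, missed cleavages
    and charge. Compositions are canonicalized before keying, so different
    orderings of the same composition collapse to one key.

    If a ``spectrum_id`` column is present, duplicate spectrum identifiers
    raise (each spectrum may be counted once).
    """
    missing = [c for c in PSM_REQUIRED if c not in psms.columns]
    if missing:
        raise KeyError(f"PSM table is missing required columns {missing}")
    if "spectrum_id" in psms.columns and psms["spectrum_id"].duplicated().any():
        dup = psms.loc[psms["spectrum_id"].duplicated(), "spectrum_id"].iloc[0]
        raise ValueError(f"duplicate spectrum identifier {dup!r}; refusing to double count")

    if psms.empty:
        empty = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], [], []], names=["protein", "site", "composition"])
        )
        return SiteGlycanTable(counts=empty, classes=pd.Series(dtype=object))

    canon = psms["composition"].map(lambda s: parse_glycan_composition(s).canonical())
    keyed = psms.assign(composition=canon)
    counts = (
        keyed.groupby(["protein", "site", "composition", "sample"], sort=True)
        .size()
        .unstack("sample", fill_value=0)
        .astype(int)
    )
    classes = pd.Series(
        [classify_composition_string(c) for c in counts.index.get_level_values("composition")],
        index=counts.index,
        name="glycan_class",
    )
    return SiteGlycanTable(counts=counts, classes=classes)


def consistency_filter(
    table: SiteGlycanTable,
    replicate_map: pd.DataFrame | dict,
) -> tuple[SiteGlycanTable, pd.Series]:
    """Keep rows detected in > half of the replicates of >= 1 cell line.

    Parameters
    ----------
    table
        Site-glycan spectral counts.
    replicate_map
        Either a sample-indexed DataFrame with a ``cell_line`` column, or a
        mapping sample -> (cell_line, replicate).

    Returns
    -------
    (filtered table, n_consistent_lines)
        ``n_consistent_lines`` gives, for every *input* row, the number of
        cell lines in which it is consistently detected (> half of that
        line's replicates nonzero).
    """
    if isinstance(replicate_map, dict):
        line_of = {s: v[0] if isinstance(v, (tuple, list)) else v for s, v in replicate_map.items()}
    else:
        line_of = replicate_map["cell_line"].to_dict()
    missing = [s for s in table.counts.columns if s not in line_of]
    if missing:
        raise KeyError(f"samples missing from replicate map: {missing[:5]}")

    # the map, not the table, defines each line's replicate count: a sample
    # with zero PSMs overall has no column but still counts as a replicate
    lines: dict[str, list[str]] = {}
    for sample, line in line_of.items():
        lines.setdefault(line, []).append(sample)
    for line, samples in lines.items():
        if len(samples) == 0:  # pragma: no cover - defensive
            raise ValueError(f"cell line {line!r} has zero replicates")

    n_consistent = pd.Series(0, index=table.counts.index, dtype=int)
    for line, samples in lines.items():
        present = [s for s in samples if s in table.counts.columns]
        if not present:
            continue
        detected = (table.counts[present] > 0).sum(axis=1)
        n_consistent += (detected * 2 > len(samples)).astype(int)
    keep = n_consistent > 0
    filtered = SiteGlycanTable(
        counts=table.counts.loc[keep], classes=table.classes.loc[keep]
    )
    return filtered, n_consistent.rename("n_consistent_lines")


def class_fractions(table: SiteGlycanTable) -> pd.Series:
    """Fraction of distinct site-specific glycans per class.

    Counts unique row keys, not spectra: a glycan observed by 100 PSMs and
    one observed by a single PSM weigh the same, matching the enumeration
    of "site-specific glycans" as identified entities.
    """
    if table.n_keys == 0:
        raise ValueError("cannot compute class fractions of an empty table")
    frac = table.classes.value_counts(normalize=True)
    return frac.reindex(GLYCAN_CLASSES, fill_value=0.0).rename("fraction")
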