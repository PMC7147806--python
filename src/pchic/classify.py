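"""Classification of aligned Hi-C read ends and read pairs.

Each end of a Hi-C pair is assigned one of six mutually exclusive
categories. Reads aligning to canonical transposable elements are filtered
outright (TEs are abundant in both compartments, so their reads cannot be
attributed to either). Repeat-aligned ends count as heterochromatic without
a genomic position. Positionally mapped ends are unique (MAPQ >= 30) or
multi-mapped (MAPQ == 0, the value bwa assigns to multi-hit reads) within
PCH, or unique within derived euchromatin; everything else — including the
ambiguous 0 < MAPQ < 30 range — is OTHER.

Precedence: TE filter, then repeat hit (repeat alignments target a separate
reference and carry no genomic coordinate), then position.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, InputError, RepeatCatalog


class EndCategory(str, Enum):
    TE_FILTERED = "TE_FILTERED"
    UNIQUE_PCH = "UNIQUE_PCH"
    MULTI_PCH = "MULTI_PCH"
    REPEAT_PCH = "REPEAT_PCH"
    UNIQUE_EU = "UNIQUE_EU"
    OTHER = "OTHER"


class PairClass(str, Enum):
    PCH_PCH_UNIQUE = "PCH_PCH_UNIQUE"
    EU_PCH = "EU_PCH"
    EU_EU = "EU_EU"
    DISCARD = "DISCARD"


#: end categories that count as "heterochromatic" for euchromatin-PCH pairs
PCH_CATEGORIES = frozenset(
    {EndCategory.UNIQUE_PCH, EndCategory.MULTI_PCH, EndCategory.REPEAT_PCH}
)

MAPQ_UNIQUE = 30


@dataclass
class AlignedEnd:
    """One aligned end of a Hi-C read pair.

    ``arm``/``position`` are None for ends aligned only to the repeat
    library (which has no genomic coordinates).
    """

    read_id: str
    arm: Optional[str]
    position: Optional[int]
    mapq: int
    repeat_hit: Optional[str] = None
    te_hit: bool = False

    def __post_init__(self):
        if (self.arm is None) != (self.position is None):
            raise InputError("position must be present iff arm is present")
        if not (0 <= self.mapq <= 255):
            raise InputError("mapq must be in [0, 255]")


@dataclass
class ReadPair:
    end1: AlignedEnd
    end2: AlignedEnd
    cat1: Optional[EndCategory] = None
    cat2: Optional[EndCategory] = None


def classify_end(
    end: AlignedEnd,
    annotation: GenomeAnnotation,
    catalog: RepeatCatalog,
    euchromatin=None,
) -> EndCategory:
    """Assign the category of one aligned end (pure; OTHER is the fall-through)."""
    if end.te_hit:
        return EndCategory.TE_FILTERED
    if catalog.is_repeat(end.repeat_hit):
        return EndCategory.REPEAT_PCH
    if end.arm is None:
        return EndCategory.OTHER
    if euchromatin is None:
        euchromatin = annotation.euchromatin()
    pch = annotation.pch.get(end.arm)
    if pch is not None and bool(pch.contains(end.position)):
        if end.mapq >= MAPQ_UNIQUE:
            return EndCategory.UNIQUE_PCH
        if end.mapq == 0:
            return EndCategory.MULTI_PCH
        return EndCategory.OTHER
    eu = euchromatin.get(end.arm)
    if eu is not None and bool(eu.contains(end.position)) and end.mapq >= MAPQ_UNIQUE:
        return EndCategory.UNIQUE_EU
    return EndCategory.OTHER


def classify_pair(cat1: EndCategory, cat2: EndCategory) -> PairClass:
    """Pair class from the two end categories.

    Pairs touching a TE-filtered or OTHER end are discarded, as are pairs of
    two non-unique PCH ends (no locatable end).
    """
    cats = {cat1, cat2}
    if EndCategory.TE_FILTERED in cats or EndCategory.OTHER in cats:
        return PairClass.DISCARD
    if cat1 == EndCategory.UNIQUE_PCH and cat2 == EndCategory.UNIQUE_PCH:
        return PairClass.PCH_PCH_UNIQUE
    if cat1 == EndCategory.UNIQUE_EU and cat2 == EndCategory.UNIQUE_EU:
        return PairClass.EU_EU
    if (cat1 == EndCategory.UNIQUE_EU and cat2 in PCH_CATEGORIES) or (
        cat2 == EndCategory.UNIQUE_EU and cat1 in PCH_CATEGORIES
    ):
        return PairClass.EU_PCH
    return PairClass.DISCARD


# ---------------------------------------------------------------------------
# vectorized classification of a pairs table


def _classify_ends_vectorized(
    arm: pd.Series,
    pos: pd.Series,
    mapq: pd.Series,
    repeat: pd.Series,
    te: pd.Series,
    annotation: GenomeAnnotation,
    catalog: RepeatCatalog,
    euchromatin: dict,
) -> np.ndarray:
    n = len(arm)
    out = np.full(n, EndCategory.OTHER.value, dtype=object)

    te_mask = te.to_numpy(dtype=bool)
    rep_names = repeat.fillna("").to_numpy(dtype=object)
    rep_mask = np.fromiter(
        (catalog.is_repeat(r) if r else False for r in rep_names), bool, count=n
    )
    rep_mask &= ~te_mask

    positioned = arm.notna().to_numpy() & ~te_mask & ~rep_mask
    mapq_arr = mapq.to_numpy()
    pos_arr = pos.to_numpy()

    for arm_name in annotation.arm_names:
        sel = positioned & (arm.to_numpy(dtype=object) == arm_name)
        if not sel.any():
            continue
        p = pos_arr[sel].astype(np.int64)
        q = mapq_arr[sel]
        in_pch = annotation.pch.get(arm_name, None)
        in_pch = in_pch.contains(p) if in_pch is not None else np.zeros(p.size, bool)
        eu_iv = euchromatin.get(arm_name)
        in_eu = eu_iv.contains(p) if eu_iv is not None else np.zeros(p.size, bool)

        cat = np.full(p.size, EndCategory.OTHER.value, dtype=object)
        cat[in_pch & (q >= MAPQ_UNIQUE)] = EndCategory.UNIQUE_PCH.value
        cat[in_pch & (q == 0)] = EndCategory.MULTI_PCH.value
        cat[~in_pch & in_eu & (q >= MAPQ_UNIQUE)] = EndCategory.UNIQUE_EU.value
        out[sel] = cat

    out[te_mask] = EndCategory.TE_FILTERED.value
    out[rep_mask] = EndCategory.REPEAT_PCH.value
    return out


def classify_frame(
    pairs: pd.DataFrame,
    annotation: GenomeAnnotation,
    catalog: RepeatCatalog,
) -> pd.DataFrame:
    """Classify every pair in a table; appends cat1/cat2/pair_class columns.

    Expected columns: arm1 pos1 mapq1 repeat1 te1 arm2 pos2 mapq2 repeat2 te2
    (arm/repeat may be NaN/empty). Positions are 0-based here; the I/O layer
    converts the on-disk 1-based pairs-TSV convention.
    """
    eu = annotation.euchromatin()
    out = pairs.copy()
    for i in (1, 2):
        out[f"cat{i}"] = _classify_ends_vectorized(
            pairs[f"arm{i}"], pairs[f"pos{i}"], pairs[f"mapq{i}"],
            pairs[f"repeat{i}"], pairs[f"te{i}"], annotation, catalog, eu,
        )

    c1 = out["cat1"].to_numpy(dtype=object)
    c2 = out["cat2"].to_numpy(dtype=object)
    pc = np.full(len(out), PairClass.DISCARD.value, dtype=object)

    bad = (
        (c1 == EndCategory.TE_FILTERED.value) | (c2 == EndCategory.TE_FILTERED.value)
        | (c1 == EndCategory.OTHER.value) | (c2 == EndCategory.OTHER.value)
    )
    upch1 = c1 == EndCategory.UNIQUE_PCH.value
    upch2 = c2 == EndCategory.UNIQUE_PCH.value
    ueu1 = c1 == EndCategory.UNIQUE_EU.value
    ueu2 = c2 == EndCategory.UNIQUE_EU.value
    pch_vals = {c.value for c in PCH_CATEGORIES}
    anypch1 = np.isin(c1, list(pch_vals))
    anypch2 = np.isin(c2, list(pch_vals))

    pc[upch1 & upch2] = PairClass.PCH_PCH_UNIQUE.value
    pc[ueu1 & ueu2] = PairClass.EU_EU.value
    pc[(ueu1 & anypch2) | (ueu2 & anypch1)] = PairClass.EU_PCH.value
    pc[bad] = PairClass.DISCARD.value
    out["pair_class"] = pc
    return out


def category_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-category end counts and per-class pair counts (conservation audit)."""
    ends = pd.concat([classified["cat1"], classified["cat2"]])
    end_counts = ends.value_counts().reindex(
        [c.value for c in EndCategory], fill_value=0
    )
    pair_counts = classified["pair_class"].value_counts().reindex(
        [c.value for c in PairClass], fill_value=0
    )
    rows = [("end", k, v) for k, v in end_counts.items()]
    rows += [("pair", k, v) for k, v in pair_counts.items()]
    return pd.DataFrame(rows, columns=["kind", "category", "count"])
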