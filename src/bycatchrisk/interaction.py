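"""Relative-probability normalization and the turtle-fishery interaction index.

Raw use-intensity and effective-effort surfaces are on arbitrary scales; to
compare them they are each converted to relative probabilities by dividing
every non-masked cell-quarter value by the grand total over all cells and
all four quarters, so each surface sums to one.

The interaction (bycatch-risk) index in cell *i* at quarter *t* is then the
normalized product

    I(i, t) = P_turtle(i, t) * P_effort(i, t) / sum over all (i, t) of the products,

taken over cell-quarters non-masked in *both* inputs.  The result again sums
to one across all cells and quarters, so values are directly comparable
across seasons.  It is a relative risk surface: it ranks where and when
bycatch is most likely given co-occurrence, and predicts neither absolute
bycatch counts nor rates.
"""

from __future__ import annotations

import math

import pandas as pd

from .geogrid import QuarterlyField, field_sum

__all__ = [
    "relative_probability",
    "interaction_index",
    "top_hotspots",
]


def relative_probability(f: QuarterlyField) -> QuarterlyField:
    """Normalize a nonnegative field to sum to 1 over non-masked entries."""
    if len(f) == 0:
        raise ValueError("cannot normalize an all-masked (empty) field")
    neg = [(k, v) for k, v in f.items() if v < 0]
    if neg:
        raise ValueError(f"negative field value at {neg[0][0]}: {neg[0][1]}")
    total = field_sum(f)
    if total <= 0:
        raise ValueError("cannot normalize an all-zero field")
    return QuarterlyField({k: v / total for k, v in f.items()}, f.spec)


def interaction_index(pt: QuarterlyField, pe: QuarterlyField) -> QuarterlyField:
    """Normalized product of two relative-probability surfaces.

    Output entries exist only where both inputs are non-masked; the values
    sum to 1 over that joint support.

    Raises
    ------
    ValueError
        If the joint support is empty or the product sums to zero (no
        overlap between animal occupancy and fishing effort).
    """
    joint = pt.keys() & pe.keys()
    if not joint:
        raise ValueError(
            "empty joint support: turtle surface covers "
            f"{len(pt)} cell-quarters, effort surface {len(pe)}, overlap 0"
        )
    products = {k: pt[k] * pe[k] for k in joint}
    denom = math.fsum(products.values())
    if denom <= 0:
        n_pos = sum(1 for v in products.values() if v > 0)
        raise ValueError(
            f"joint support of {len(joint)} cell-quarters but product sum is 0 "
            f"({n_pos} entries with positive product)"
        )
    return QuarterlyField({k: v / denom for k, v in products.items()}, pt.spec)


def top_hotspots(
    surface: QuarterlyField,
    k: int | None = None,
    q: float | None = None,
) -> pd.DataFrame:
    """Rank cell-quarters by interaction index, descending.

    Either ``k`` (top-k entries) or ``q`` (entries above the upper ``q``
    quantile of values, e.g. q=0.95 for the top 5%) selects the rows.  Ties
    are broken by (quarter, lat_lo, lon_lo) ascending for determinism.  A
    ``k`` larger than the support returns everything.
    """
    if (k is None) == (q is None):
        raise ValueError("specify exactly one of k or q")
    entries = [
        (v, (c, qq)) for (c, qq), v in surface.items()
    ]
    entries.sort(key=lambda e: (-e[0], e[1][1], e[1][0].lat_lo, e[1][0].lon_lo))
    if k is not None:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        selected = entries[:k]
    else:
        if not 0 < q < 1:
            raise ValueError(f"q must be in (0, 1), got {q}")
        values = sorted(v for v, _ in entries)
        cut = values[min(int(math.floor(q * len(values))), len(values) - 1)]
        selected = [e for e in entries if e[0] >= cut]
    rows = [
        {
            "rank": i + 1,
            "lat_lo": cell.lat_lo,
            "lon_lo": cell.lon_lo,
            "quarter": qq,
            "value": v,
        }
        for i, (v, (cell, qq)) in enumerate(selected)
    ]
    return pd.DataFrame(rows, columns=["rank", "lat_lo", "lon_lo", "quarter", "value"])
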