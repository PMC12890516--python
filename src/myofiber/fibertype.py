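"""Fiber-type classification from myosin heavy-chain isoform abundances.

Skeletal muscle fiber types map onto the dominant myosin heavy-chain isoform:
MYH7 -> type I (slow), MYH2 -> 2A, MYH1 -> 2X, MYH4 -> 2B.  Given the summed
abundance of the four isoforms in a sample, each isoform's share is expressed
as a percentage; a sample is a *pure* fiber type when one isoform reaches at
least 80% of the total, and a *mixed* type named by the highest and
second-highest contributors otherwise (e.g. "mixed I/2A").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, UnclassifiableError

#: Isoform -> fiber-type name, in the fixed priority order used to break ties.
ISOFORM_TYPES: dict[str, str] = {
    "myh7": "I",
    "myh2": "2A",
    "myh1": "2X",
    "myh4": "2B",
}

#: A sample is a pure fiber type when one isoform reaches this share (percent).
PURE_THRESHOLD_PCT = 80.0


@dataclass(frozen=True)
class FiberComposition:
    """MYH isoform abundances for one sample (arbitrary, non-negative units)."""

    myh1: float
    myh2: float
    myh4: float
    myh7: float

    def __post_init__(self) -> None:
        for name in ISOFORM_TYPES:
            if getattr(self, name) < 0:
                raise InvalidInputError(f"negative abundance for {name}")

    @property
    def percentages(self) -> dict[str, float]:
        """Each isoform's share of the summed abundance, in percent."""
        total = sum(getattr(self, name) for name in ISOFORM_TYPES)
        if total == 0:
            raise UnclassifiableError("all isoform abundances are zero")
        return {
            name: 100.0 * getattr(self, name) / total for name in ISOFORM_TYPES
        }


def classify_fiber_type(composition: FiberComposition) -> str:
    """Label a sample as a pure or mixed fiber type.

    Pure when the top isoform share is >= 80% (inclusive); otherwise mixed,
    named by the two largest contributors, highest first.  Ties are broken by
    the fixed isoform order MYH7 > MYH2 > MYH1 > MYH4.
    """
    pct = composition.percentages
    # stable sort over the fixed priority order implements the tie-break
    ranked = sorted(ISOFORM_TYPES, key=lambda n: -pct[n])
    top = ranked[0]
    if pct[top] >= PURE_THRESHOLD_PCT:
        return f"pure {ISOFORM_TYPES[top]}"
    return f"mixed {ISOFORM_TYPES[top]}/{ISOFORM_TYPES[ranked[1]]}"


def classify_fiber_types(
    abundances: pd.DataFrame,
    id_map: dict[str, str] | None = None,
) -> pd.Series:
    """Classify every sample (column) of a protein x sample abundance table.

    ``id_map`` maps the table's protein identifiers to the canonical isoform
    keys (myh1/myh2/myh4/myh7); by default rows named MYH1/... (any case) are
    used.  Missing values count as zero abundance.
    """
    if id_map is None:
        id_map = {name.upper(): name for name in ISOFORM_TYPES}
    rows = {
        iso: pd.Series(0.0, index=abundances.columns) for iso in ISOFORM_TYPES
    }
    for pid, iso in id_map.items():
        if iso not in ISOFORM_TYPES:
            raise InvalidInputError(f"unknown isoform key {iso!r} in id map")
        if pid in abundances.index:
            rows[iso] = abundances.loc[pid].fillna(0.0)
    labels = {}
    for sample in abundances.columns:
        comp = FiberComposition(
            myh1=float(rows["myh1"][sample]),
            myh2=float(rows["myh2"][sample]),
            myh4=float(rows["myh4"][sample]),
            myh7=float(rows["myh7"][sample]),
        )
        labels[sample] = classify_fiber_type(comp)
    return pd.Series(labels, name="fiber_type")
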