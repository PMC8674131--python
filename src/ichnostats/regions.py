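"""The 14-region anatomical protocol for footprint depth measurement.

Depths are measured at the medial and lateral heel, the medial and lateral
midfoot, the five metatarsal heads and the five toes.  The order defined
here fixes the layout of every 14-vector in the package (profiles, mean
profiles, covariance rows/columns).
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = (
    "heel_medial",
    "heel_lateral",
    "midfoot_medial",
    "midfoot_lateral",
    "mt1",
    "mt2",
    "mt3",
    "mt4",
    "mt5",
    "toe1",
    "toe2",
    "toe3",
    "toe4",
    "toe5",
)

N_REGIONS: int = len(REGIONS)

REGION_INDEX: dict[str, int] = {r: i for i, r in enumerate(REGIONS)}

HEEL_REGIONS: tuple[str, ...] = ("heel_medial", "heel_lateral")
TOE_REGIONS: tuple[str, ...] = ("toe1", "toe2", "toe3", "toe4", "toe5")


def validate_regions(names) -> None:
    """Raise ValueError unless *names* is exactly the 14-region set."""
    got = set(names)
    expected = set(REGIONS)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        parts = []
        if missing:
            parts.append(f"missing regions: {missing}")
        if extra:
            parts.append(f"unknown regions: {extra}")
        raise ValueError("; ".join(parts))
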