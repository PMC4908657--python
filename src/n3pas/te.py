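"""Association of PACs with nearby transposable elements.

A PAC associates with a TE when its representative site lies inside
the TE (distance 0) or within the distance cutoff of the nearest TE
edge (40 nt by default, inclusive; the comparator is configurable
because both "less than 40 nt" and "a minimum distance of 40 nt" are
defensible readings). Strand is ignored. Only sense genic calls
(3'UTR and the three non-3'UTR categories) enter the family tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotation import TeRecord
from .classification import N3PAS_CATEGORIES, SENSE_CATEGORIES, PacCall

TE_DISTANCE_CUTOFF = 40


@dataclass(frozen=True)
class TeAssociation:
    pac_id: str
    te_id: str
    distance: int
    family: str

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def _distance(pos: int, te: TeRecord) -> int:
    if te.start <= pos <= te.end:
        return 0
    return min(abs(pos - te.start), abs(pos - te.end))


def associate_tes(
    calls: Sequence[PacCall],
    tes: Sequence[TeRecord],
    cutoff: int = TE_DISTANCE_CUTOFF,
    inclusive: bool = True,
) -> list[TeAssociation]:
    """All (PAC, TE) associations within the cutoff.

    Returned sorted by PAC then distance then te_id, so the first
    association listed per PAC is its nearest TE.
    """
    by_chrom: dict[str, list[TeRecord]] = {}
    for te in tes:
        by_chrom.setdefault(te.chrom, []).append(te)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t.start, t.te_id))
    out: list[TeAssociation] = []
    for c in calls:
        pos = c.pac.rep_pos
        for te in by_chrom.get(c.pac.chrom, []):
            if te.start - pos > cutoff:
                break
            d = _distance(pos, te)
            within = d <= cutoff if inclusive else d < cutoff
            if within:
                out.append(TeAssociation(c.pac.pac_id, te.te_id, d, te.family))
    out.sort(key=lambda a: (a.pac_id, a.distance, a.te_id))
    return out


def nearest_te(assocs: Sequence[TeAssociation]) -> dict[str, TeAssociation]:
    """Per PAC, the nearest associated TE (ties on smaller te_id)."""
    best: dict[str, TeAssociation] = {}
    for a in assocs:
        cur = best.get(a.pac_id)
        if cur is None or (a.distance, a.te_id) < (cur.distance, cur.te_id):
            best[a.pac_id] = a
    return best


def family_tally(
    assocs: Sequence[TeAssociation], calls: Sequence[PacCall]
) -> pd.DataFrame:
    """Per-family PAC counts via each PAC's nearest TE, restricted to
    sense genic calls and split into n3PAS vs 3'UTR columns."""
    by_id = {c.pac.pac_id: c for c in calls}
    nearest = nearest_te(assocs)
    rows: dict[str, dict[str, int]] = {}
    for pac_id, a in nearest.items():
        call = by_id.get(pac_id)
        if call is None or call.category not in SENSE_CATEGORIES:
            continue
        row = rows.setdefault(a.family, {"n3PAS": 0, "ThreeUTR": 0})
        if call.category in N3PAS_CATEGORIES:
            row["n3PAS"] += 1
        else:
            row["ThreeUTR"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["n3PAS", "ThreeUTR"], dtype=int)
    else:
        df["total"] = df["n3PAS"] + df["ThreeUTR"]
        df = df.sort_values("total", ascending=False)
    df.index.name = "family"
    return df
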