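"""Single-nucleotide composition profiles around representative sites.

For each PAC category the -100..+100 window around every usable
representative site (position 0 = the cleavage base) is extracted on
the transcription strand; per-position base fractions summarize the
poly(A) signal landscape of that category. Ambiguous bases (N) are
excluded from the per-position denominator and reported separately.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import chrom_length, fetch, revcomp
from .classification import CATEGORIES, PacCall

DEFAULT_FLANK = 100

_BASES = "ACGT"


def composition_profile(
    calls: Sequence[PacCall],
    genome,
    flank: int = DEFAULT_FLANK,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, pd.DataFrame]:
    """Per-category position-by-position base fractions.

    Sites closer than ``flank`` to a chromosome edge are skipped (the
    skip count is recorded in the frame attrs). Each returned frame
    has 2*flank+1 rows: position, fracA..fracT, n_N and n (usable
    sites); categories with zero usable sites yield an empty frame.
    """
    width = 2 * flank + 1
    out: dict[str, pd.DataFrame] = {}
    for cat in categories:
        counts = np.zeros((width, 4), dtype=np.int64)
        n_counts = np.zeros(width, dtype=np.int64)
        n_sites = 0
        n_skipped = 0
        for c in calls:
            if c.category != cat:
                continue
            pac = c.pac
            pos = pac.rep_pos
            clen = chrom_length(genome, pac.chrom)
            if pos - flank < 1 or pos + flank > clen:
                n_skipped += 1
                continue
            seq = fetch(genome, pac.chrom, pos - flank, pos + flank)
            if pac.strand == "-":
                seq = revcomp(seq)
            n_sites += 1
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for j, base in enumerate(_BASES):
                counts[:, j] += arr == ord(base)
            n_counts += ~np.isin(arr, [ord(b) for b in _BASES])
        if n_sites == 0:
            df = pd.DataFrame(
                columns=["position", "fracA", "fracC", "fracG", "fracT", "n_N", "n"]
            )
        else:
            denom = counts.sum(axis=1).astype(float)
            denom[denom == 0] = np.nan
            df = pd.DataFrame(
                {
                    "position": np.arange(-flank, flank + 1),
                    "fracA": counts[:, 0] / denom,
                    "fracC": counts[:, 1] / denom,
                    "fracG": counts[:, 2] / denom,
                    "fracT": counts[:, 3] / denom,
                    "n_N": n_counts,
                    "n": n_sites,
                }
            )
        df.attrs["n_sites"] = n_sites
        df.attrs["n_skipped"] = n_skipped
        out[cat] = df
    return out
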