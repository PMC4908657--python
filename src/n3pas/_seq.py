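"""Small sequence helpers shared across modules.

A "genome" anywhere in this package is either a plain mapping of
chromosome name -> sequence string (as produced by the simulator) or a
``pyfaidx.Fasta`` handle; :func:`fetch` hides the difference.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def chrom_length(genome, chrom: str) -> int:
    rec = genome[chrom]
    return len(rec)


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Return the sequence of ``chrom`` between 1-based inclusive coords.

    ``start``/``end`` must already be clipped to the chromosome.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    rec = genome[chrom]
    if isinstance(rec, str):
        return rec[start - 1 : end].upper()
    # pyfaidx FastaRecord supports python slicing on 0-based coords
    return str(rec[start - 1 : end]).upper()


def max_base_run(seq: str, base: str = "A") -> int:
    """Length of the longest run of ``base`` in ``seq``."""
    best = cur = 0
    for ch in seq:
        if ch == base:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best
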