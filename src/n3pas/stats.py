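"""Statistical comparisons used across the analyses.

Feature-frequency differences between the genome and the hosts of
non-3'UTR sites are tested with a Pearson chi-square on the
labeled/unlabeled contingency (no continuity correction by default;
R-style Yates correction is available for 2x2 tables). Length
comparisons use the Welch unequal-variance t-test, since intron-length
variances differ grossly between groups. Significance is read at
P = 0.05 throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class FrequencyComparison:
    feature: str
    genome_rate: float
    host_rates: dict[str, float] = field(default_factory=dict)
    chi_square: float = math.nan
    p_value: float = math.nan

    def __post_init__(self):
        for r in [self.genome_rate, *self.host_rates.values()]:
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


def chi_square_test(
    table, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a contingency table.

    Returns (statistic, P). With ``correction=True`` the Yates
    continuity correction is applied (R's default for 2x2 tables).
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    stat, p, _, expected = sps.chi2_contingency(table, correction=correction)
    if (expected < 5).any():
        warnings.warn(
            "expected cell count < 5; consider an exact test", UserWarning
        )
    return float(stat), float(p)


def feature_frequency_test(
    feature: str,
    genome_counts: Sequence[int],
    host_counts: Mapping[str, Sequence[int]] | Sequence[int],
    correction: bool = False,
) -> FrequencyComparison:
    """Compare a feature's genome-wide rate with its rate among the
    host genes of non-3'UTR sites.

    ``genome_counts`` and each entry of ``host_counts`` are
    (labeled, unlabeled) 2-vectors; ``host_counts`` may be one vector
    or a mapping dataset-name -> vector (the contingency then has one
    row per dataset plus the genome row).
    """
    if not isinstance(host_counts, Mapping):
        host_counts = {"hosts": host_counts}
    rows = [list(genome_counts)] + [list(v) for v in host_counts.values()]
    stat, p = chi_square_test(rows, correction=correction)

    def rate(v):
        return v[0] / (v[0] + v[1])

    return FrequencyComparison(
        feature=feature,
        genome_rate=rate(list(genome_counts)),
        host_rates={k: rate(list(v)) for k, v in host_counts.items()},
        chi_square=stat,
        p_value=p,
    )


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch unequal-variance t-test.

    Returns (t, Welch-Satterthwaite df, two-sided P). Two groups with
    zero variance and equal means give t = 0, P = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(df), float(res.pvalue)
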