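"""Cross-platform agreement between microarray and qPCR fold changes.

Pairs each miRNA's replicate-averaged microarray log2 fold change with the
log2 of its qPCR 2^-ddCt fold change, reports the Pearson correlation
between platforms, and selects reporting candidates above a log2 fold-change
threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .microarray import ExpressionCall

__all__ = [
    "PlatformPair",
    "pearson",
    "build_pairs",
    "select_candidates",
    "write_pairs_csv",
    "write_correlation_json",
]


class IntegrationInputError(ValueError):
    pass


@dataclass(frozen=True)
class PlatformPair:
    """One miRNA's log2 fold change on both platforms."""

    mirna_name: str
    log2fc_array: float
    log2fc_qpcr: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log2fc_array) and np.isfinite(self.log2fc_qpcr)):
            raise IntegrationInputError(f"{self.mirna_name}: non-finite fold change")


def pearson(pairs: Sequence[PlatformPair]) -> dict[str, float]:
    """Pearson correlation between platforms: ``{"r", "p", "n"}``.

    Two-sided p from the t transform with n - 2 degrees of freedom; needs
    at least 3 pairs and non-zero variance on both axes.
    """
    if len(pairs) < 3:
        raise IntegrationInputError("need >= 3 pairs for a correlation")
    x = np.array([p.log2fc_array for p in pairs])
    y = np.array([p.log2fc_qpcr for p in pairs])
    if x.std() == 0 or y.std() == 0:
        raise IntegrationInputError("zero variance on one platform; r undefined")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(pairs)}


def build_pairs(
    array_calls: Sequence[ExpressionCall],
    qpcr_log2fc: Mapping[str, float],
) -> list[PlatformPair]:
    """Match array calls to qPCR log2 fold changes by miRNA name.

    miRNAs present on only one platform are dropped with a warning.
    """
    array_fc = {c.mirna_name: c.mean_log2_fc for c in array_calls}
    shared = sorted(set(array_fc) & set(qpcr_log2fc))
    unmatched = sorted(set(array_fc) ^ set(qpcr_log2fc))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} miRNA(s) present on one platform only, dropped: "
            f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}",
            stacklevel=2,
        )
    return [
        PlatformPair(name, array_fc[name], float(qpcr_log2fc[name])) for name in shared
    ]


def select_candidates(
    calls: Sequence[ExpressionCall],
    threshold: float = 0.5,
) -> list[ExpressionCall]:
    """Calls with mean log2 FC above ``threshold``, ranked descending.

    Ties are broken lexicographically by miRNA name so output is
    deterministic.
    """
    hits = [c for c in calls if c.mean_log2_fc > threshold]
    return sorted(hits, key=lambda c: (-c.mean_log2_fc, c.mirna_name))


def write_pairs_csv(pairs: Iterable[PlatformPair], path) -> None:
    pd.DataFrame(
        [
            {
                "mirna": p.mirna_name,
                "log2fc_array": p.log2fc_array,
                "log2fc_qpcr": p.log2fc_qpcr,
            }
            for p in pairs
        ]
    ).to_csv(path, index=False)


def write_correlation_json(result: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(result), fh, indent=2)
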