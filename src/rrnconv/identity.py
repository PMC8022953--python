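"""Within-genome homogenization of the operon family.

Concerted evolution predicts that gene conversion slowly homogenizes the
copies of a multigene family.  On the short timescale of a mutation
accumulation experiment individual conversions move pairwise identities
up or down without fixing alleles, so the mean pairwise identity of the
concatenated subunit genes is tracked per lineage and the across-lineage
trend tested with a two-sided Wilcoxon signed-rank test (exact null
distribution up to n = 25 after dropping zero deltas, normal
approximation above).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import OperonAlignment, concatenate_alignments, mean_pairwise_identity

__all__ = ["IdentityDelta", "TrendTestResult", "identity_change_per_lineage", "identity_trend_test"]


@dataclass(frozen=True)
class IdentityDelta:
    """Change in mean pairwise identity of one lineage, percentage points."""

    lineage_id: str
    ancestral_identity: float
    evolved_identity: float

    @property
    def delta(self) -> float:
        return self.evolved_identity - self.ancestral_identity


@dataclass(frozen=True)
class TrendTestResult:
    p_value: float
    statistic: float
    n_nonzero: int
    degenerate: bool  # all deltas were exactly zero


def identity_change_per_lineage(
    ancestors: Sequence[OperonAlignment],
    evolved_per_lineage: Mapping[str, Sequence[OperonAlignment]],
) -> list[IdentityDelta]:
    """Identity deltas on the concatenated gene regions, one per lineage."""
    anc_concat = concatenate_alignments(list(ancestors))
    anc_identity = mean_pairwise_identity(anc_concat).mean
    out = []
    for lineage_id, alns in evolved_per_lineage.items():
        ev_concat = concatenate_alignments(list(alns))
        if ev_concat.data.shape != anc_concat.data.shape:
            raise ValueError(
                f"lineage {lineage_id!r} does not share the ancestral alignment shape"
            )
        out.append(
            IdentityDelta(
                lineage_id, anc_identity, mean_pairwise_identity(ev_concat).mean
            )
        )
    return out


def identity_trend_test(deltas: Sequence[IdentityDelta] | Sequence[float]) -> TrendTestResult:
    """Two-sided signed-rank test of the identity deltas against zero.

    Zero deltas are dropped (standard convention; the count is reported);
    an all-zero input is flagged degenerate with p = 1.
    """
    values = np.array(
        [d.delta if isinstance(d, IdentityDelta) else float(d) for d in deltas]
    )
    if values.size == 0:
        raise ValueError("at least one delta is required")
    nonzero = values[values != 0]
    if nonzero.size == 0:
        return TrendTestResult(1.0, 0.0, 0, True)
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    return TrendTestResult(float(res.pvalue), float(res.statistic), int(nonzero.size), False)


def deltas_to_frame(deltas: Sequence[IdentityDelta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lineage": [d.lineage_id for d in deltas],
            "ancestral_identity": [d.ancestral_identity for d in deltas],
            "evolved_identity": [d.evolved_identity for d in deltas],
            "delta": [d.delta for d in deltas],
        }
    )
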