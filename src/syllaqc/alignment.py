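"""Reference/hypothesis token alignment and WER decomposition.

Word error rate is computed from the minimum edit distance between the
reference (human) and hypothesis (ASR) token sequences under unit costs for
substitution, deletion and insertion (the Wagner-Fischer dynamic program).
The backtrace decomposes the distance into deletions D (omissions),
substitutions S, and insertions I (intrusions); with reference length N,

    WER% = (S + D + I) / N * 100 = del% + sub% + ins%

and the decomposition identity holds exactly because the total is computed
as the sum of its components (no independent rounding). WER can exceed
100% when insertions are numerous.

Ties in the backtrace are broken match > substitution > deletion >
insertion so the reported counts are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .textsyll import Transcript

__all__ = ["AlignmentCounts", "ErrorRates", "align", "error_rates"]


@dataclass(frozen=True)
class AlignmentCounts:
    """Token-alignment outcome: N = hits + subs + dels; distance = S+D+I."""

    n_ref: int
    hits: int
    subs: int
    dels: int
    ins: int

    def __post_init__(self) -> None:
        if min(self.n_ref, self.hits, self.subs, self.dels, self.ins) < 0:
            raise ValueError("alignment counts must be non-negative")
        if self.hits + self.subs + self.dels != self.n_ref:
            raise ValueError(
                f"hits+subs+dels = {self.hits + self.subs + self.dels} "
                f"must equal n_ref = {self.n_ref}"
            )

    @property
    def distance(self) -> int:
        """Minimum edit distance S + D + I."""
        return self.subs + self.dels + self.ins


@dataclass(frozen=True)
class ErrorRates:
    """WER and its omission/substitution/intrusion components, in percent."""

    del_pct: float
    sub_pct: float
    ins_pct: float

    @property
    def wer_pct(self) -> float:
        # sum of components by construction: the decomposition identity is
        # exact, not up to rounding
        return self.del_pct + self.sub_pct + self.ins_pct


def _tokens(x: Transcript | Sequence[str]) -> tuple[str, ...]:
    if isinstance(x, Transcript):
        return x.tokens
    return tuple(str(t) for t in x)


def align(ref: Transcript | Sequence[str], hyp: Transcript | Sequence[str]) -> AlignmentCounts:
    """Minimum-edit-distance alignment of hypothesis against reference.

    The reference must be nonempty (WER is undefined at N = 0); the
    hypothesis may be empty (every reference token is then a deletion).
    """
    r = _tokens(ref)
    h = _tokens(hyp)
    n, m = len(r), len(h)
    if n == 0:
        raise ValueError("empty reference: WER is undefined at N = 0")

    dist = np.zeros((n + 1, m + 1), dtype=np.int64)
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        ri = r[i - 1]
        row = dist[i]
        prev = dist[i - 1]
        for j in range(1, m + 1):
            sub_cost = 0 if ri == h[j - 1] else 1
            row[j] = min(prev[j - 1] + sub_cost, prev[j] + 1, row[j - 1] + 1)

    hits = subs = dels = ins = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and r[i - 1] == h[j - 1] and dist[i, j] == dist[i - 1, j - 1]:
            hits += 1
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and dist[i, j] == dist[i - 1, j - 1] + 1:
            subs += 1
            i, j = i - 1, j - 1
        elif i > 0 and dist[i, j] == dist[i - 1, j] + 1:
            dels += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return AlignmentCounts(n_ref=n, hits=hits, subs=subs, dels=dels, ins=ins)


def error_rates(c: AlignmentCounts) -> ErrorRates:
    """Percentage error rates of an alignment (components of N)."""
    if c.n_ref < 1:
        raise ValueError("error rates require n_ref >= 1")
    scale = 100.0 / c.n_ref
    return ErrorRates(
        del_pct=c.dels * scale,
        sub_pct=c.subs * scale,
        ins_pct=c.ins * scale,
    )
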