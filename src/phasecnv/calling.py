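"""Per-individual diplotype calls from EM posterior proportions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .em import EMResult
from .sites import Diplotype, SiteSpec, State, collapse_diplotype

__all__ = ["DiplotypeCall", "call_diplotypes", "implied_unphased_calls"]


@dataclass(frozen=True)
class DiplotypeCall:
    """A called diplotype (or no-call) with its posterior proportion."""

    diplotype: Optional[Diplotype]
    proportion: float

    @property
    def is_no_call(self) -> bool:
        return self.diplotype is None


def call_diplotypes(
    result: EMResult, threshold: Optional[float] = None
) -> Dict[str, DiplotypeCall]:
    """Call each individual's diplotype as the posterior argmax.

    With a *threshold*, individuals whose best posterior proportion does not
    exceed it become no-calls (their proportion is still reported).  Exact
    posterior ties are broken deterministically by canonical diplotype
    string.
    """
    if threshold is not None and not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    calls: Dict[str, DiplotypeCall] = {}
    for ind, dips, w in result.posterior_items():
        top = float(np.max(w))
        best = min(
            (d for d, wk in zip(dips, w) if wk == top),
            key=str,
        )
        if threshold is not None and top <= threshold:
            calls[ind] = DiplotypeCall(None, top)
        else:
            calls[ind] = DiplotypeCall(best, top)
    return calls


def implied_unphased_calls(
    called: Mapping[str, Union[DiplotypeCall, Diplotype, None]],
    sites: Sequence[SiteSpec],
) -> Dict[str, Optional[Tuple[State, ...]]]:
    """Collapse called diplotypes to per-site unphased states.

    Total copy numbers and unphased genotypes follow directly from a
    diplotype by summing (pooling) its two haplotypes site by site.
    No-calls map to ``None``.
    """
    out: Dict[str, Optional[Tuple[State, ...]]] = {}
    for ind, call in called.items():
        diplotype = call.diplotype if isinstance(call, DiplotypeCall) else call
        out[ind] = None if diplotype is None else collapse_diplotype(diplotype, sites)
    return out
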