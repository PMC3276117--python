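"""Accuracy metrics for haplotype-frequency and diplotype inference.

Frequency estimates are scored by total variation distance, half the L1
distance between the true and estimated frequency tables over the union of
their haplotypes.  Diplotype calls are scored by exact-match accuracy (all
sites must agree).  Because the EM can overturn the per-site maximum-
likelihood calls it was fed, two further rates compare the EM-implied
unphased states against the argmax-likelihood states: the correction rate
(argmax wrong, EM right) and the corruption rate (argmax right, EM wrong),
both over all individuals, so that

    accuracy_EM = accuracy_ML + correction - corruption

holds as an identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calling import DiplotypeCall
from .sites import Diplotype, Haplotype, State

__all__ = [
    "EvaluationReport",
    "total_variation",
    "diplotype_accuracy",
    "ml_call_accuracy",
    "correction_corruption",
    "frequency_spectrum",
]


@dataclass(frozen=True)
class EvaluationReport:
    """The five headline metrics of one evaluation run."""

    tv: float
    diplotype_accuracy: float
    ml_call_accuracy: float
    correction_rate: float
    corruption_rate: float

    def __post_init__(self) -> None:
        for name in ("tv", "diplotype_accuracy", "ml_call_accuracy",
                     "correction_rate", "corruption_rate"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name} = {v!r} outside [0, 1]")

    def to_dict(self) -> Dict[str, float]:
        return {
            "tv": self.tv,
            "diplotype_accuracy": self.diplotype_accuracy,
            "ml_call_accuracy": self.ml_call_accuracy,
            "correction_rate": self.correction_rate,
            "corruption_rate": self.corruption_rate,
        }


def total_variation(
    truth: Mapping[Haplotype, float],
    estimate: Mapping[Haplotype, float],
    atol: float = 1e-6,
) -> float:
    """Total variation distance ``(1/2) sum_i |p_i - p^_i|``.

    Both tables must be normalized; the sum runs over the union of their
    haplotypes, with absent haplotypes counted as frequency zero.  The
    result lies in [0, 1].
    """
    for name, table in (("truth", truth), ("estimate", estimate)):
        total = sum(table.values())
        if abs(total - 1.0) > atol:
            raise ValueError(f"{name} frequencies sum to {total!r}, not 1")
    keys = set(truth) | set(estimate)
    return 0.5 * sum(abs(truth.get(h, 0.0) - estimate.get(h, 0.0)) for h in keys)


def _as_diplotype(value: Union[DiplotypeCall, Diplotype, None]) -> Optional[Diplotype]:
    return value.diplotype if isinstance(value, DiplotypeCall) else value


def diplotype_accuracy(
    called: Mapping[str, Union[DiplotypeCall, Diplotype, None]],
    truth: Mapping[str, Diplotype],
) -> float:
    """Fraction of individuals whose called diplotype matches the truth.

    The comparison is exact over all sites (canonical equality); no-calls
    count as incorrect.  The two mappings must cover the same individuals.
    """
    if set(called) != set(truth):
        raise ValueError("called and truth cover different individuals")
    if not truth:
        raise ValueError("empty individual set")
    hits = sum(1 for ind in truth if _as_diplotype(called[ind]) == truth[ind])
    return hits / len(truth)


def ml_call_accuracy(
    ml_states: Mapping[str, Tuple[State, ...]],
    truth_states: Mapping[str, Tuple[State, ...]],
) -> float:
    """Fraction of individuals whose argmax-likelihood states are all correct.

    *ml_states* is the per-individual tuple of most likely unphased states
    (see :meth:`GenoSpectrum.argmax_states`); an individual counts as
    correct only when every site agrees with the truth.
    """
    if set(ml_states) != set(truth_states):
        raise ValueError("ml_states and truth_states cover different individuals")
    if not truth_states:
        raise ValueError("empty individual set")
    hits = sum(1 for ind in truth_states if ml_states[ind] == truth_states[ind])
    return hits / len(truth_states)


def correction_corruption(
    em_states: Mapping[str, Optional[Tuple[State, ...]]],
    ml_states: Mapping[str, Tuple[State, ...]],
    truth_states: Mapping[str, Tuple[State, ...]],
) -> Tuple[float, float]:
    """Correction and corruption rates of EM-implied states vs argmax calls.

    Correction: fraction of individuals whose argmax-likelihood states were
    wrong but whose EM-implied states are right.  Corruption: the converse.
    Both use all individuals as the denominator, which makes
    ``accuracy_EM = accuracy_ML + correction - corruption`` exact.
    """
    if not (set(em_states) == set(ml_states) == set(truth_states)):
        raise ValueError("state mappings cover different individuals")
    if not truth_states:
        raise ValueError("empty individual set")
    n = len(truth_states)
    correction = corruption = 0
    for ind, truth in truth_states.items():
        ml_right = ml_states[ind] == truth
        em_right = em_states[ind] == truth
        if em_right and not ml_right:
            correction += 1
        elif ml_right and not em_right:
            corruption += 1
    return correction / n, corruption / n


def frequency_spectrum(
    frequencies: Mapping[str, Sequence[float]],
    n_individuals: int,
    bin_width: float = 0.02,
) -> pd.DataFrame:
    """Allele-frequency spectrum over many regions, binned per allele class.

    *frequencies* maps an allele class label (e.g. ``A0``, ``A1``, ``A2``)
    to the estimated frequencies of that class across regions.  Frequencies
    below ``1/(2N)`` or above ``1 - 1/(2N)`` are excluded as unresolvable at
    sample size ``N``; the remainder are counted in half-open bins
    ``[lo, lo + bin_width)``.

    Returns a data frame with columns ``allele_class``, ``bin_left``,
    ``bin_right`` and ``count`` (bins with zero counts everywhere omitted).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be at least 1")
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must lie in (0, 1]")
    lo = 1.0 / (2 * n_individuals)
    hi = 1.0 - lo
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    rows = []
    for label, values in frequencies.items():
        kept = [v for v in values if lo <= v <= hi]
        # half-open [lo, hi) bins; the closed final bin of np.histogram is
        # immaterial because frequencies of exactly 1 are excluded above
        counts, _ = np.histogram(kept, bins=edges)
        for i, c in enumerate(counts):
            if c:
                rows.append(
                    {
                        "allele_class": label,
                        "bin_left": float(edges[i]),
                        "bin_right": float(edges[i + 1]),
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows, columns=["allele_class", "bin_left", "bin_right", "count"])
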