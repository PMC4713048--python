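"""Weighted Kolmogorov–Smirnov enrichment of a probe set in a ranked list.

Walking the ranked response pattern L from top to bottom, a running sum
increases at each member of the probe set S ("hit") by that probe's
weight |r|^p normalized over all hits, and decreases at each non-member
("miss") by 1/(N - N_H). The enrichment score ES is the signed value of
the running sum at its maximum absolute deviation from zero: near +1
when S concentrates at the top of L, near -1 at the bottom. The default
weight exponent p = 1 uses the ranking statistic itself as the weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .core import (
    RankedResponsePattern,
    ResponseSignature,
    UndefinedEnrichmentError,
)

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """ES with the 1-based position of the extreme deviation and,
    optionally, the whole running-sum trace."""

    es: float
    arg_position: int
    running_sum: Optional[np.ndarray] = None


def enrichment_score(
    probe_set: Iterable[str],
    pattern: RankedResponsePattern,
    p: float = 1.0,
    keep_running_sum: bool = False,
) -> EnrichmentResult:
    """Weighted-KS enrichment of ``probe_set`` within ``pattern``.

    Members absent from the pattern are dropped (count logged). The
    score is undefined when no member survives the intersection or the
    set covers the whole pattern. If every surviving hit has zero
    weight, the walk falls back to the unweighted form (p = 0) with a
    warning.
    """
    members = set(probe_set)
    n = len(pattern)
    hit = np.fromiter(
        (pid in members for pid in pattern.probe_ids), dtype=bool, count=n
    )
    n_hits = int(hit.sum())
    dropped = len(members) - n_hits
    if dropped:
        logger.debug("%d probe-set members absent from pattern, dropped", dropped)
    if n_hits == 0:
        raise UndefinedEnrichmentError(
            "enrichment undefined: no probe-set member present in the pattern"
        )
    if n_hits == n:
        raise UndefinedEnrichmentError(
            "enrichment undefined: probe set covers the entire pattern"
        )
    weights = np.abs(pattern.stat) ** p
    hit_weights = np.where(hit, weights, 0.0)
    total = hit_weights.sum()
    if total == 0.0:
        warnings.warn(
            "all hit weights are zero; falling back to unweighted (p=0) walk",
            stacklevel=2,
        )
        hit_weights = hit.astype(float)
        total = hit_weights.sum()
    p_hit = np.cumsum(hit_weights) / total
    p_miss = np.cumsum(~hit) / (n - n_hits)
    deviation = p_hit - p_miss
    pos_max = float(deviation.max())
    neg_min = float(deviation.min())
    # maximum absolute deviation; a tie favours the positive branch, and
    # equal values at several positions favour the earliest. Ties are
    # resolved with a small absolute tolerance because mathematically
    # exact ties (e.g. +1/2 vs -1/2) round differently depending on
    # summation order.
    if pos_max >= -neg_min - 1e-12:
        idx = int(np.argmax(deviation))
        es = pos_max
    else:
        idx = int(np.argmin(deviation))
        es = neg_min
    return EnrichmentResult(
        es=es,
        arg_position=idx + 1,
        running_sum=deviation if keep_running_sum else None,
    )


def directional_scores(
    signature: ResponseSignature,
    pattern: RankedResponsePattern,
    p: float = 1.0,
) -> tuple[Optional[float], Optional[float]]:
    """ES of the up- and down-regulated sets against one pattern.

    A direction that is empty, or empty after intersection with the
    pattern, yields ``None``; at least one direction must score.
    """
    es_up: Optional[float] = None
    es_down: Optional[float] = None
    if signature.up_probes:
        try:
            es_up = enrichment_score(signature.up_probes, pattern, p).es
        except UndefinedEnrichmentError:
            es_up = None
    if signature.down_probes:
        try:
            es_down = enrichment_score(signature.down_probes, pattern, p).es
        except UndefinedEnrichmentError:
            es_down = None
    if es_up is None and es_down is None:
        raise UndefinedEnrichmentError(
            f"signature {signature.perturbagen_id!r}: neither direction "
            "overlaps the pattern"
        )
    return es_up, es_down
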