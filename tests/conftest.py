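"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive the enrichment score and the KS association
score from their definitions by explicit loops; they deliberately share
no code with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirconnect import ExpressionProfile, RankedResponsePattern


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_profile(
    values,
    classes,
    kind: str = "miRNA",
    perturbagen_id: str = "pert-1",
    probe_ids=None,
    condition: str = "cond",
    source_id: str = "SRC",
) -> ExpressionProfile:
    values = np.asarray(values, dtype=float)
    if probe_ids is None:
        probe_ids = [f"P{i:04d}" for i in range(values.shape[0])]
    return ExpressionProfile(
        probe_ids=list(probe_ids),
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        sample_classes=list(classes),
        perturbagen_id=perturbagen_id,
        perturbagen_kind=kind,
        condition=condition,
        source_id=source_id,
    )


def brute_force_es(member_flags, stats, p=1.0):
    """Enrichment score by literal cumulative walk (independent oracle).

    ``member_flags[i]`` says whether position i of the ranked list is a
    hit; ``stats`` are the ranking statistics in list order. Returns
    (es, 1-based arg position).
    """
    n = len(stats)
    n_hits = sum(member_flags)
    assert 0 < n_hits < n
    denom_hit = sum(abs(stats[i]) ** p for i in range(n) if member_flags[i])
    if denom_hit == 0:
        denom_hit = float(n_hits)
        weights = [1.0 if member_flags[i] else 0.0 for i in range(n)]
    else:
        weights = [
            abs(stats[i]) ** p if member_flags[i] else 0.0 for i in range(n)
        ]
    # literal definition: P_hit(i) - P_miss(i), two separate running sums
    hit_sum = 0.0
    miss_count = 0
    deviations = []
    for i in range(n):
        if member_flags[i]:
            hit_sum += weights[i]
        else:
            miss_count += 1
        deviations.append(hit_sum / denom_hit - miss_count / (n - n_hits))
    pos_max = max(deviations)
    neg_min = min(deviations)
    # signed maximum absolute deviation; positive branch on a tie (within
    # float tolerance), earliest position among equals
    if pos_max >= -neg_min - 1e-12:
        return pos_max, deviations.index(pos_max) + 1
    return neg_min, deviations.index(neg_min) + 1


def brute_force_ks(positions, t, n):
    """KS association score by explicit evaluation of both maxima."""
    a = max(j / t - positions[j - 1] / n for j in range(1, t + 1))
    b = max(positions[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


def make_pattern(stats, probe_ids=None) -> RankedResponsePattern:
    if probe_ids is None:
        probe_ids = [f"g{i}" for i in range(len(stats))]
    return RankedResponsePattern(list(probe_ids), np.asarray(stats, dtype=float))
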