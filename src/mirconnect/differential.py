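"""Differential-response statistics: fold change, SAM, amplitude.

Each entry point converts an :class:`~mirconnect.core.ExpressionProfile`
into a :class:`ResponseSignature` (the up/down probe sets called
differentially expressed) plus a :class:`RankedResponsePattern` (every
probe ordered most up-regulated first by the same statistic).

Dispatch convention: unreplicated miRNA experiments (one sample in
either class) use the fold-change path with a twofold cutoff;
replicated ones (>= 2 per class) use a SAM-style regularized t with a
permutation FDR; small-molecule instances always use the amplitude
statistic with the 2/3 boundary, which corresponds exactly to a
twofold change.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from typing import Optional

import numpy as np

from .core import (
    DomainError,
    ExpressionProfile,
    MIRNA,
    RankedResponsePattern,
    ResponseSignature,
    SMALL_MOLECULE,
    ValidationError,
)

logger = logging.getLogger(__name__)

FC_THRESHOLD = 2.0
SAM_FDR = 0.05
AMP_THRESHOLD = 2.0 / 3.0


def amplitude(t, c):
    """Amplitude a = (t - c) / ((t + c)/2) of treatment vs control.

    For positive linear-scale expression this lies in (-2, 2);
    a > 2/3 iff t > 2c (twofold increase) and a < -2/3 iff t < c/2.
    Accepts scalars or arrays; both must be strictly positive.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(t <= 0) or np.any(c <= 0):
        raise DomainError("amplitude requires strictly positive t and c")
    result = (t - c) / ((t + c) / 2.0)
    return result if result.ndim else float(result)


def _class_means(profile: ExpressionProfile) -> tuple[np.ndarray, np.ndarray]:
    return (
        profile.treatment_values.mean(axis=1),
        profile.control_values.mean(axis=1),
    )


def fold_change_signature(
    profile: ExpressionProfile, fc_threshold: float = FC_THRESHOLD
) -> tuple[ResponseSignature, RankedResponsePattern]:
    """Twofold-change signature for an unreplicated design.

    A probe is up-regulated when t/c >= ``fc_threshold`` and
    down-regulated when t/c <= 1/``fc_threshold`` (symmetric reciprocal
    rule). The pattern ranks every probe by log2(t/c) descending.
    """
    nt, nc = profile.n_per_class()
    if nt >= 2 and nc >= 2:
        raise ValidationError(
            "replicated design (>=2 samples per class): use sam_signature"
        )
    if fc_threshold <= 1:
        raise ValidationError("fc_threshold must exceed 1")
    t, c = _class_means(profile)
    if np.any(t <= 0) or np.any(c <= 0):
        raise DomainError("fold change requires strictly positive expression")
    ratio = t / c
    log_ratio = np.log2(ratio)
    up = {p for p, r in zip(profile.probe_ids, ratio) if r >= fc_threshold}
    down = {p for p, r in zip(profile.probe_ids, ratio) if r <= 1.0 / fc_threshold}
    sig = ResponseSignature(
        profile.perturbagen_id,
        frozenset(up),
        frozenset(down),
        method="fold_change",
        thresholds={"fc_threshold": fc_threshold},
    )
    pattern = RankedResponsePattern.from_scores(profile.probe_ids, log_ratio)
    return sig, pattern


def sam_d(treat, control, s0: float):
    """SAM regularized difference statistic d = (mean_t - mean_c)/(s + s0).

    ``s`` is the pooled standard error of the mean difference
    (two-class unpaired); ``s0`` is the fudge constant that damps
    low-variance probes. Inputs are 1-D vectors (one probe) or 2-D
    probes x samples matrices (row-wise result).
    """
    treat = np.atleast_2d(np.asarray(treat, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    nt, nc = treat.shape[1], control.shape[1]
    if nt < 2 or nc < 2:
        raise ValidationError(
            "SAM needs >= 2 replicates per class; use the fold-change path"
        )
    diff = treat.mean(axis=1) - control.mean(axis=1)
    s = _pooled_se(treat, control)
    d = diff / (s + s0)
    return d if d.size > 1 else float(d[0])


def _pooled_se(treat: np.ndarray, control: np.ndarray) -> np.ndarray:
    nt, nc = treat.shape[1], control.shape[1]
    ss = ((treat - treat.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / nt + 1.0 / nc) * ss / (nt + nc - 2))


def _label_assignments(
    n_samples: int, n_treat: int, n_perms: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct treatment-column index sets used as permuted labelings."""
    total = math.comb(n_samples, n_treat)
    if total < 10:
        warnings.warn(
            f"only {total} distinct label assignments; enumerating all of them",
            stacklevel=3,
        )
    if total <= max(n_perms, 10):
        return [
            np.array(c, dtype=int)
            for c in itertools.combinations(range(n_samples), n_treat)
        ]
    chosen: set[tuple[int, ...]] = set()
    out = []
    while len(out) < n_perms:
        c = tuple(sorted(rng.choice(n_samples, size=n_treat, replace=False)))
        if c in chosen:
            continue
        chosen.add(c)
        out.append(np.array(c, dtype=int))
    return out


def sam_signature(
    profile: ExpressionProfile,
    fdr_cutoff: float = SAM_FDR,
    n_label_perms: int = 100,
    seed: int = 0,
) -> tuple[ResponseSignature, RankedResponsePattern]:
    """SAM signature for a replicated design at a permutation FDR.

    Per-probe d uses s0 = median of the per-probe pooled standard
    errors. The null d-distribution comes from relabeling samples; the
    symmetric cutoff is the smallest |d| threshold whose estimated
    median FDR is <= ``fdr_cutoff``. The pattern ranks probes by d.
    """
    nt, nc = profile.n_per_class()
    if nt < 2 or nc < 2:
        raise ValidationError(
            "SAM needs >= 2 samples per class; use fold_change_signature"
        )
    values = profile.values
    treat_idx = np.array(
        [i for i, c in enumerate(profile.sample_classes) if c == "treatment"]
    )
    ctrl_idx = np.array(
        [i for i, c in enumerate(profile.sample_classes) if c == "control"]
    )
    s = _pooled_se(values[:, treat_idx], values[:, ctrl_idx])
    s0 = float(np.median(s))
    d = (values[:, treat_idx].mean(axis=1) - values[:, ctrl_idx].mean(axis=1)) / (
        s + s0
    )

    rng = np.random.default_rng(seed)
    n = values.shape[1]
    abs_null = []
    for treat_cols in _label_assignments(n, nt, n_label_perms, rng):
        mask = np.zeros(n, dtype=bool)
        mask[treat_cols] = True
        pt, pc = values[:, mask], values[:, ~mask]
        sp = _pooled_se(pt, pc)
        dp = (pt.mean(axis=1) - pc.mean(axis=1)) / (sp + s0)
        abs_null.append(np.sort(np.abs(dp)))
    abs_null = np.asarray(abs_null)  # perms x probes, each row ascending

    abs_d = np.abs(d)
    candidates = np.unique(abs_d)
    n_probes = d.size
    # called count and median null exceedance count at every candidate cutoff
    n_called = n_probes - np.searchsorted(np.sort(abs_d), candidates, side="left")
    exceed = np.array(
        [n_probes - np.searchsorted(row, candidates, side="left")
         for row in abs_null]
    )
    fdr = np.median(exceed, axis=0) / np.maximum(n_called, 1)
    ok = (fdr <= fdr_cutoff) & (n_called >= 1)
    delta = float(candidates[ok][0]) if ok.any() else None  # smallest valid cutoff
    if delta is None:
        up: frozenset[str] = frozenset()
        down: frozenset[str] = frozenset()
    else:
        called = abs_d >= delta
        up = frozenset(
            p for p, di, c in zip(profile.probe_ids, d, called) if c and di > 0
        )
        down = frozenset(
            p for p, di, c in zip(profile.probe_ids, d, called) if c and di < 0
        )
    sig = ResponseSignature(
        profile.perturbagen_id,
        up,
        down,
        method="sam",
        thresholds={"fdr_cutoff": fdr_cutoff, "s0": s0,
                    "delta": None if delta is None else float(delta)},
    )
    pattern = RankedResponsePattern.from_scores(profile.probe_ids, d)
    return sig, pattern


def amplitude_signature(
    profile: ExpressionProfile, amp_threshold: float = AMP_THRESHOLD
) -> tuple[ResponseSignature, RankedResponsePattern]:
    """Amplitude signature for a small-molecule instance.

    Up-regulated: a > ``amp_threshold``; down-regulated:
    a < -``amp_threshold``. The default 2/3 boundary equals a twofold
    change in either direction. The pattern ranks probes by a.
    """
    t, c = _class_means(profile)
    a = amplitude(t, c)
    up = {p for p, ai in zip(profile.probe_ids, a) if ai > amp_threshold}
    down = {p for p, ai in zip(profile.probe_ids, a) if ai < -amp_threshold}
    sig = ResponseSignature(
        profile.perturbagen_id,
        frozenset(up),
        frozenset(down),
        method="amplitude",
        thresholds={"amp_threshold": amp_threshold},
    )
    pattern = RankedResponsePattern.from_scores(profile.probe_ids, a)
    return sig, pattern


def build_signature(
    profile: ExpressionProfile,
    fc_threshold: float = FC_THRESHOLD,
    sam_fdr: float = SAM_FDR,
    amp_threshold: float = AMP_THRESHOLD,
    seed: int = 0,
) -> tuple[ResponseSignature, RankedResponsePattern]:
    """Route a profile to the statistic its design calls for.

    Small-molecule instances take the amplitude path. miRNA experiments
    take SAM when both classes have replicates, otherwise fold change.
    """
    if profile.perturbagen_kind == SMALL_MOLECULE:
        sig, pat = amplitude_signature(profile, amp_threshold)
    else:
        nt, nc = profile.n_per_class()
        if nt >= 2 and nc >= 2:
            sig, pat = sam_signature(profile, fdr_cutoff=sam_fdr, seed=seed)
        else:
            sig, pat = fold_change_signature(profile, fc_threshold)
    logger.info(
        "signature %s: method=%s up=%d down=%d",
        profile.profile_key,
        sig.method,
        *sig.sizes(),
    )
    return sig, pat
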