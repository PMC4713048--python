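"""Permutation significance of an Association Score.

The null model keeps everything about a (molecule, miRNA) pair fixed
except the identity of the signature probes: for each permutation the
miRNA signature and each of the molecule's instance signatures are
replaced by uniform random probe sets of the same sizes drawn from
their own ranked patterns, the enrichment/TES chain is recomputed for
the focal molecule's instances, the instance ranking rebuilt, and the
Association Score recorded. The p-value is the fraction of random
scores whose absolute value strictly exceeds the observed one.

Only the focal molecule's TES values are recomputed per round;
the other instances keep their observed TES in the ranking.
"""

from __future__ import annotations

import logging
import zlib
from typing import Optional, Sequence

import numpy as np

from .core import (
    InstanceTES,
    PermutationResult,
    RankedResponsePattern,
    ResponseSignature,
    ValidationError,
)
from .association import ks_association, pair_tes, rank_instances

logger = logging.getLogger(__name__)

N_PERMUTATIONS = 1000


def permute_signature(
    pattern: RankedResponsePattern,
    n_up: int,
    n_down: int,
    rng: np.random.Generator,
    perturbagen_id: str = "random",
) -> ResponseSignature:
    """Random signature of fixed sizes drawn from a pattern's probes.

    ``n_up + n_down`` probes are sampled uniformly without replacement;
    the first ``n_up`` form the up set, the rest the down set, so the
    two sets are disjoint by construction.
    """
    if n_up < 0 or n_down < 0:
        raise ValidationError("signature sizes must be non-negative")
    total = n_up + n_down
    if total > len(pattern):
        raise ValidationError(
            f"requested {total} probes from a {len(pattern)}-probe pattern"
        )
    chosen = rng.choice(len(pattern), size=total, replace=False)
    probes = [pattern.probe_ids[i] for i in chosen]
    return ResponseSignature(
        perturbagen_id,
        frozenset(probes[:n_up]),
        frozenset(probes[n_up:]),
        method="permuted",
    )


def permutation_pvalue(
    observed: float, null_scores: Sequence[float], add_one: bool = False
) -> float:
    """Fraction of null scores with |null| strictly greater than |observed|.

    ``add_one`` applies the (k+1)/(m+1) correction so the minimum
    attainable p is positive; off by default.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ValidationError("null_scores must be non-empty")
    k = int((np.abs(null_scores) > abs(observed)).sum())
    if add_one:
        return (k + 1) / (null_scores.size + 1)
    return k / null_scores.size


def pair_rng(seed: int, molecule_id: str, mirna_profile_id: str) -> np.random.Generator:
    """Per-pair generator derived from (seed, molecule, profile) so each
    pair is independently reproducible regardless of processing order."""
    entropy = [
        int(seed) % (2**31),
        zlib.crc32(molecule_id.encode()),
        zlib.crc32(mirna_profile_id.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_permutation_test(
    molecule_id: str,
    mirna_profile: tuple[ResponseSignature, RankedResponsePattern],
    molecule_instances: dict[str, tuple[ResponseSignature, RankedResponsePattern]],
    all_instances: Sequence[InstanceTES],
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    rank_by: str = "signed",
    p: float = 1.0,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation test of one molecule's Association Score.

    ``molecule_instances`` maps the focal molecule's instance ids to
    their (signature, pattern); ``all_instances`` is the full observed
    InstanceTES cohort for the miRNA profile (used both for the observed
    score and, with focal entries swapped out, for each null ranking).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    mir_sig, mir_pat = mirna_profile
    mirna_profile_id = {it.mirna_profile_id for it in all_instances}
    if len(mirna_profile_id) != 1:
        raise ValidationError("all_instances must come from one miRNA profile")
    profile_id = mirna_profile_id.pop()

    ranked = rank_instances(all_instances, rank_by)
    obs_positions = [
        i + 1 for i, it in enumerate(ranked) if it.molecule_id == molecule_id
    ]
    if len(obs_positions) != len(molecule_instances):
        raise ValidationError(
            f"molecule {molecule_id!r}: {len(molecule_instances)} instances "
            f"supplied but {len(obs_positions)} found in the cohort"
        )
    n = len(ranked)
    observed = ks_association(obs_positions, len(obs_positions), n)

    non_focal = [it for it in all_instances if it.molecule_id != molecule_id]
    rng = pair_rng(seed, molecule_id, profile_id)
    mir_sizes = mir_sig.sizes()
    inst_sizes = {k: sig.sizes() for k, (sig, _) in molecule_instances.items()}

    null_as = []
    for _ in range(n_perm):
        perm_mir_sig = permute_signature(
            mir_pat, *mir_sizes, rng, perturbagen_id=mir_sig.perturbagen_id
        )
        focal = []
        for inst_id, (sig, pat) in molecule_instances.items():
            perm_sig = permute_signature(
                pat, *inst_sizes[inst_id], rng, perturbagen_id=molecule_id
            )
            focal.append(
                pair_tes(
                    (perm_sig, pat),
                    (perm_mir_sig, mir_pat),
                    p=p,
                    molecule_id=molecule_id,
                    instance_id=inst_id,
                    mirna_profile_id=profile_id,
                )
            )
        perm_ranked = rank_instances(non_focal + focal, rank_by)
        positions = [
            i + 1
            for i, it in enumerate(perm_ranked)
            if it.molecule_id == molecule_id
        ]
        null_as.append(ks_association(positions, len(positions), n))

    return PermutationResult(
        observed_as=observed,
        null_as=null_as,
        p_value=permutation_pvalue(observed, null_as, add_one=add_one),
        n_perm=n_perm,
        seed=seed,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional multiple-testing column)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
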