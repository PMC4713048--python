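"""Per-pair Total Enrichment Scores and the KS-type Association Score.

For one (small-molecule instance, miRNA profile) pair, four directional
enrichment scores are combined into two per-direction Total Enrichment
Scores (signature of the molecule scanned along the miRNA pattern and
vice versa), and their mean is the instance's TES. Because a molecule
has several instances (cell line, dose, batch), all n scored instances
for one miRNA profile are ranked by TES and a molecule's t positions
V(1..t) are summarized by a two-sided KS order statistic: the
Association Score, positive when the molecule's instances crowd the top
of the ranking and negative when they crowd the bottom.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .core import (
    AssociationRecord,
    InstanceTES,
    RankedResponsePattern,
    ResponseSignature,
    UndefinedEnrichmentError,
    ValidationError,
)
from .enrichment import directional_scores

logger = logging.getLogger(__name__)


def total_es(es_up: Optional[float], es_down: Optional[float]) -> float:
    """Combine the up- and down-set ES of one scan direction.

    Sign-opposition rule: when the two scores disagree in sign the
    combined score is (es_up - es_down)/2 — a coherent signature (up
    set at the top, down set at the bottom, or the reverse) scores far
    from zero, while same-sign scores indicate no coherent placement
    and combine to 0. A single surviving direction contributes half its
    score with the matching sign convention.
    """
    if es_up is None and es_down is None:
        raise ValidationError("both directional scores null: pair not scoreable")
    if es_up is None:
        return -es_down / 2.0
    if es_down is None:
        return es_up / 2.0
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def pair_tes(
    molecule_instance: tuple[ResponseSignature, RankedResponsePattern],
    mirna_profile: tuple[ResponseSignature, RankedResponsePattern],
    p: float = 1.0,
    molecule_id: str = "",
    instance_id: str = "",
    mirna_profile_id: str = "",
) -> InstanceTES:
    """Score one molecule instance against one miRNA profile.

    Computes the four directional ES (molecule signature in miRNA
    pattern, miRNA signature in molecule pattern), the two per-direction
    TES values, and their mean.
    """
    mol_sig, mol_pat = molecule_instance
    mir_sig, mir_pat = mirna_profile
    try:
        es_up_sm2mir, es_down_sm2mir = directional_scores(mol_sig, mir_pat, p)
        es_up_mir2sm, es_down_mir2sm = directional_scores(mir_sig, mol_pat, p)
    except UndefinedEnrichmentError as exc:
        raise UndefinedEnrichmentError(
            f"no probe overlap between molecule {mol_sig.perturbagen_id!r} "
            f"and miRNA {mir_sig.perturbagen_id!r}: {exc}"
        ) from exc
    tes_sm2mir = total_es(es_up_sm2mir, es_down_sm2mir)
    tes_mir2sm = total_es(es_up_mir2sm, es_down_mir2sm)
    return InstanceTES(
        molecule_id=molecule_id or mol_sig.perturbagen_id,
        instance_id=instance_id,
        mirna_profile_id=mirna_profile_id or mir_sig.perturbagen_id,
        es_up_sm2mir=es_up_sm2mir,
        es_down_sm2mir=es_down_sm2mir,
        es_up_mir2sm=es_up_mir2sm,
        es_down_mir2sm=es_down_mir2sm,
        tes_sm2mir=tes_sm2mir,
        tes_mir2sm=tes_mir2sm,
        tes=(tes_sm2mir + tes_mir2sm) / 2.0,
    )


def ks_association(positions: Sequence[int], t: int, n: int) -> float:
    """KS composite of a molecule's instance positions among all instances.

    ``positions`` are the strictly increasing 1-based ranks V(1..t) of
    the molecule's t instances within the ranking of all n instances.
    With a = max_j [ j/t - V(j)/n ] and b = max_j [ V(j)/n - (j-1)/t ],
    the score is a when a > b, else -b; it lies in (-1, 1).
    """
    v = np.asarray(positions, dtype=float)
    if v.size != t or not (1 <= t <= n):
        raise ValidationError(f"need 1 <= t={t} <= n={n} positions, got {v.size}")
    if np.any(v < 1) or np.any(v > n):
        raise ValidationError("positions must lie in 1..n")
    if np.any(np.diff(v) <= 0):
        raise ValidationError("positions must be strictly increasing (no duplicates)")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def rank_instances(
    instances: Sequence[InstanceTES], rank_by: str = "signed"
) -> list[InstanceTES]:
    """Order instances by TES descending.

    ``rank_by='signed'`` ranks by the signed TES (default);
    ``'absolute'`` by |TES|. Ties break by (molecule_id, instance_id)
    so the ranking is deterministic and independent of input order.
    """
    if rank_by == "signed":
        key = lambda it: (-it.tes, it.molecule_id, it.instance_id)
    elif rank_by == "absolute":
        key = lambda it: (-abs(it.tes), it.molecule_id, it.instance_id)
    else:
        raise ValidationError(f"rank_by must be 'signed' or 'absolute', got {rank_by!r}")
    return sorted(instances, key=key)


def associate(
    instances: Sequence[InstanceTES],
    molecule_id: str,
    rank_by: str = "signed",
) -> AssociationRecord:
    """Aggregate one molecule's instances into an Association Score.

    ``instances`` must hold every scored instance (all molecules) for
    one miRNA profile; n is their total count. Returns a record without
    a p-value (see :mod:`mirconnect.significance`).
    """
    if not instances:
        raise ValidationError("no instances to rank")
    profile_ids = {it.mirna_profile_id for it in instances}
    if len(profile_ids) != 1:
        raise ValidationError(
            f"instances span several miRNA profiles: {sorted(profile_ids)}"
        )
    ranked = rank_instances(instances, rank_by)
    positions = [
        i + 1 for i, it in enumerate(ranked) if it.molecule_id == molecule_id
    ]
    if not positions:
        raise ValidationError(f"molecule {molecule_id!r} absent from instance list")
    n = len(ranked)
    score = ks_association(positions, len(positions), n)
    mirna_id, condition, source_id = (profile_ids.pop().split("|") + ["", ""])[:3]
    return AssociationRecord(
        molecule_id=molecule_id,
        mirna_id=mirna_id,
        condition=condition,
        source_id=source_id,
        as_score=score,
        p_value=None,
        n_instances=len(positions),
    )
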