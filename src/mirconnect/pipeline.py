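"""End-to-end orchestration: signatures -> TES -> AS -> permutation p.

These functions are what the CLI subcommands and the worked examples
call; they operate on in-memory objects so that library users never
need to touch the file formats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .core import (
    AssociationRecord,
    ExpressionProfile,
    InstanceTES,
    PerturbagenCatalogue,
    RankedResponsePattern,
    ResponseSignature,
    UndefinedEnrichmentError,
    ValidationError,
)
from .association import associate, pair_tes
from .differential import AMP_THRESHOLD, FC_THRESHOLD, SAM_FDR, build_signature
from .significance import N_PERMUTATIONS, run_permutation_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a run, with the method's canonical defaults:
    twofold change, SAM FDR 0.05, amplitude boundary 2/3, weight
    exponent 1, 1000 permutations, alpha 0.05."""

    fc_threshold: float = FC_THRESHOLD
    sam_fdr: float = SAM_FDR
    amp_threshold: float = AMP_THRESHOLD
    weight_exponent: float = 1.0
    n_permutations: int = N_PERMUTATIONS
    alpha: float = 0.05
    seed: int = 0
    rank_by: str = "signed"

    def __post_init__(self) -> None:
        if min(self.fc_threshold, self.sam_fdr, self.amp_threshold,
               self.weight_exponent) <= 0:
            raise ValidationError("thresholds must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header_comment(self) -> str:
        return (
            f"mirconnect v{__version__} "
            f"config={self.config_hash()} seed={self.seed}"
        )


SigPattern = tuple[ResponseSignature, RankedResponsePattern]


def build_signatures(
    profiles: Sequence[ExpressionProfile], config: RunConfig
) -> dict[str, SigPattern]:
    """Signature + pattern per profile, keyed by profile_key.

    Profiles whose signature comes out empty are skipped with a warning
    (they cannot be scored); this never raises for that reason alone.
    """
    out: dict[str, SigPattern] = {}
    for prof in profiles:
        sig, pat = build_signature(
            prof,
            fc_threshold=config.fc_threshold,
            sam_fdr=config.sam_fdr,
            amp_threshold=config.amp_threshold,
            seed=config.seed,
        )
        if sig.is_empty:
            logger.warning("profile %s: empty signature, skipped", prof.profile_key)
            continue
        out[prof.profile_key] = (sig, pat)
    return out


def score_mirna_profile(
    mirna: SigPattern,
    mirna_profile_id: str,
    molecule_items: dict[str, dict[str, SigPattern]],
    config: RunConfig,
) -> tuple[list[InstanceTES], list[AssociationRecord]]:
    """Score every molecule instance against one miRNA profile and
    aggregate per-molecule Association Scores with permutation p-values.

    ``molecule_items``: molecule id -> {instance id -> (sig, pattern)}.
    Pairs with no probe overlap are skipped with a logged reason.
    """
    instances: list[InstanceTES] = []
    scoreable: dict[str, dict[str, SigPattern]] = {}
    for mol_id, inst_map in molecule_items.items():
        kept: dict[str, SigPattern] = {}
        for inst_id, item in inst_map.items():
            try:
                it = pair_tes(
                    item,
                    mirna,
                    p=config.weight_exponent,
                    molecule_id=mol_id,
                    instance_id=inst_id,
                    mirna_profile_id=mirna_profile_id,
                )
            except UndefinedEnrichmentError as exc:
                logger.warning("pair skipped: %s", exc)
                continue
            instances.append(it)
            kept[inst_id] = item
        if kept:
            scoreable[mol_id] = kept

    records: list[AssociationRecord] = []
    for mol_id, kept in sorted(scoreable.items()):
        record = associate(instances, mol_id, rank_by=config.rank_by)
        if config.n_permutations > 0:
            result = run_permutation_test(
                mol_id,
                mirna,
                kept,
                instances,
                n_perm=config.n_permutations,
                seed=config.seed,
                rank_by=config.rank_by,
                p=config.weight_exponent,
            )
            record = dataclasses.replace(record, p_value=result.p_value)
        records.append(record)
    return instances, records


def score_cohort(
    mirna_profiles: dict[str, SigPattern],
    molecule_items: dict[str, dict[str, SigPattern]],
    config: RunConfig,
) -> tuple[list[InstanceTES], list[AssociationRecord]]:
    """Score every (molecule, miRNA profile) pair in a cohort.

    Association rows are sorted by p-value ascending then |AS|
    descending (records without p sort after those with p).
    """
    all_instances: list[InstanceTES] = []
    all_records: list[AssociationRecord] = []
    for profile_id, mirna in sorted(mirna_profiles.items()):
        inst, recs = score_mirna_profile(mirna, profile_id, molecule_items, config)
        all_instances.extend(inst)
        all_records.extend(recs)
    all_records.sort(
        key=lambda r: (
            r.p_value if r.p_value is not None else 2.0,
            -abs(r.as_score),
            r.molecule_id,
            r.mirna_profile_id,
        )
    )
    return all_instances, all_records


def significant(
    records: Sequence[AssociationRecord], alpha: float = 0.05
) -> list[AssociationRecord]:
    """Rows whose permutation p-value is below ``alpha``."""
    return [r for r in records if r.p_value is not None and r.p_value < alpha]
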