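"""Synthetic perturbation cohorts with planted molecule–miRNA relations.

The generator emulates the two data classes the method consumes: a
miRNA transfection experiment (treatment vs control, replicated or
not) and a set of small-molecule "instances" (independent unreplicated
treatment/control profiles of the same molecule). Expression follows a
log-normal model: per-probe baseline log2-expression ~ Normal(7, 1),
planted signature probes shifted by +/- ``effect`` log2 units in the
treatment class, i.i.d. Normal(0, ``noise_sd``) log2 noise per sample,
then exponentiated to the linear scale. A molecule can be planted to
``mimic`` the miRNA signature (same probes, same directions), to
``reverse`` it, or to carry an unrelated (``null``) signature.

Defaults (1000 probes, 50+50 planted, effect 3 log2 units, noise 0.3,
20 molecules x 3 instances) give a clearly separable planted signal
while keeping a full pipeline run cheap.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    CONTROL,
    CatalogueEntry,
    ExpressionProfile,
    MIRNA,
    PerturbagenCatalogue,
    ResponseSignature,
    SMALL_MOLECULE,
    TREATMENT,
    ValidationError,
)

RELATIONS = ("mimic", "reversal", "null")

BASELINE_MEAN = 7.0
BASELINE_SD = 1.0


@dataclass
class SimulationDesign:
    """Knobs of one synthetic cohort."""

    n_probes: int = 1000
    n_up: int = 50
    n_down: int = 50
    effect: float = 3.0
    noise_sd: float = 0.3
    replicates: int = 1
    relation: str = "null"
    overlap: float = 1.0
    n_instances: int = 3
    n_molecules: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_probes:
            raise ValidationError("planted sets larger than the probe universe")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValidationError("overlap must lie in [0, 1]")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.relation not in RELATIONS:
            raise ValidationError(f"relation must be one of {RELATIONS}")
        if min(self.n_probes, self.n_instances, self.n_molecules,
               self.replicates) < 1:
            raise ValidationError("counts must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationDesign":
        return cls(**json.loads(text))


def probe_universe(n_probes: int) -> list[str]:
    width = max(6, len(str(n_probes)))
    return [f"P{i:0{width}d}" for i in range(1, n_probes + 1)]


def _profile(
    probes: list[str],
    up: set[str],
    down: set[str],
    design: SimulationDesign,
    rng: np.random.Generator,
    perturbagen_id: str,
    kind: str,
    replicates: int,
    condition: str,
    source_id: str,
) -> ExpressionProfile:
    n = len(probes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n)
    shift = np.zeros(n)
    up_mask = np.fromiter((p in up for p in probes), dtype=bool, count=n)
    down_mask = np.fromiter((p in down for p in probes), dtype=bool, count=n)
    shift[up_mask] = design.effect
    shift[down_mask] = -design.effect
    cols = []
    classes = []
    names = []
    for k in range(replicates):
        cols.append(baseline + shift + rng.normal(0, design.noise_sd, size=n))
        classes.append(TREATMENT)
        names.append(f"{perturbagen_id}_T{k + 1}")
    for k in range(replicates):
        cols.append(baseline + rng.normal(0, design.noise_sd, size=n))
        classes.append(CONTROL)
        names.append(f"{perturbagen_id}_C{k + 1}")
    values = np.power(2.0, np.column_stack(cols))
    return ExpressionProfile(
        probe_ids=list(probes),
        values=values,
        sample_ids=names,
        sample_classes=classes,
        perturbagen_id=perturbagen_id,
        perturbagen_kind=kind,
        condition=condition,
        source_id=source_id,
    )


def generate_mirna_experiment(
    design: SimulationDesign,
    mirna_id: str = "miR-sim-1",
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionProfile, ResponseSignature]:
    """One miRNA transfection profile plus its planted truth signature.

    With ``replicates == 1`` the profile feeds the fold-change path;
    with >= 2 the SAM path. The returned signature is the ground truth
    planted by the generator, not a fitted one.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    probes = probe_universe(design.n_probes)
    planted = rng.choice(design.n_probes, size=design.n_up + design.n_down,
                         replace=False)
    up = {probes[i] for i in planted[: design.n_up]}
    down = {probes[i] for i in planted[design.n_up:]}
    profile = _profile(
        probes, up, down, design, rng, mirna_id, MIRNA,
        replicates=design.replicates, condition="transfection_sim",
        source_id="SYN001",
    )
    truth = ResponseSignature(mirna_id, frozenset(up), frozenset(down),
                              method="planted")
    return profile, truth


def generate_molecule_instances(
    design: SimulationDesign,
    mirna_signature: ResponseSignature,
    molecule_id: str = "SM0000",
    relation: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[ExpressionProfile]:
    """Instance profiles for one molecule with a planted relation.

    ``mimic`` reuses a fraction ``overlap`` of the miRNA signature in
    the same directions; ``reversal`` plants the same probes with
    directions swapped; ``null`` plants a random signature disjoint
    from the miRNA's. Unused planted slots are filled with fresh random
    probes. All instances share the planted sets and differ only in
    noise.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    relation = relation if relation is not None else design.relation
    if relation not in RELATIONS:
        raise ValidationError(f"relation must be one of {RELATIONS}")
    probes = probe_universe(design.n_probes)
    mir_up = sorted(mirna_signature.up_probes)
    mir_down = sorted(mirna_signature.down_probes)
    k_up = round(design.overlap * len(mir_up))
    k_down = round(design.overlap * len(mir_down))

    if relation == "mimic":
        up = set(rng.choice(mir_up, k_up, replace=False)) if k_up else set()
        down = set(rng.choice(mir_down, k_down, replace=False)) if k_down else set()
    elif relation == "reversal":
        up = set(rng.choice(mir_down, k_down, replace=False)) if k_down else set()
        down = set(rng.choice(mir_up, k_up, replace=False)) if k_up else set()
    else:
        up, down = set(), set()

    taken = set(mir_up) | set(mir_down) | up | down
    free = [p for p in probes if p not in taken]
    need_up = design.n_up - len(up)
    need_down = design.n_down - len(down)
    if need_up + need_down > len(free):
        raise ValidationError(
            "overlap/relation demands more free probes than available"
        )
    extra = rng.choice(len(free), size=need_up + need_down, replace=False)
    up |= {free[i] for i in extra[:need_up]}
    down |= {free[i] for i in extra[need_up:]}

    return [
        _profile(
            probes, up, down, design, rng, molecule_id, SMALL_MOLECULE,
            replicates=1, condition=f"instance_{k + 1}", source_id="SYN002",
        )
        for k in range(design.n_instances)
    ]


def generate_cohort(
    design: SimulationDesign,
) -> tuple[
    PerturbagenCatalogue,
    ExpressionProfile,
    dict[str, list[ExpressionProfile]],
    Optional[str],
]:
    """One miRNA experiment plus ``n_molecules`` molecules of
    ``n_instances`` instances each.

    When ``design.relation`` is not ``null``, the first molecule is
    planted with that relation to the miRNA signature and the rest are
    null; its id is returned as the planted molecule (else ``None``).
    """
    rng = np.random.default_rng(design.seed)
    mirna_profile, truth = generate_mirna_experiment(design, rng=rng)
    molecules: dict[str, list[ExpressionProfile]] = {}
    planted_id: Optional[str] = None
    entries = [
        CatalogueEntry(
            perturbagen_id=mirna_profile.perturbagen_id,
            kind=MIRNA,
            condition=mirna_profile.condition,
            source_id=mirna_profile.source_id,
        )
    ]
    for m in range(design.n_molecules):
        mol_id = f"SM{m:04d}"
        relation = design.relation if m == 0 else "null"
        if m == 0 and design.relation != "null":
            planted_id = mol_id
        instances = generate_molecule_instances(
            design, truth, molecule_id=mol_id, relation=relation, rng=rng
        )
        molecules[mol_id] = instances
        for inst in instances:
            entries.append(
                CatalogueEntry(
                    perturbagen_id=mol_id,
                    kind=SMALL_MOLECULE,
                    condition=inst.condition,
                    source_id=inst.source_id,
                )
            )
    return PerturbagenCatalogue(entries), mirna_profile, molecules, planted_id


def id_only_catalogue(n_molecules: int, n_mirna_profiles: int) -> PerturbagenCatalogue:
    """Catalogue of bare ids (no matrices) for pair-enumeration studies."""
    entries = [
        CatalogueEntry(
            perturbagen_id=f"SM{m:04d}", kind=SMALL_MOLECULE, condition="c1",
            source_id="SYN",
        )
        for m in range(n_molecules)
    ]
    entries += [
        CatalogueEntry(
            perturbagen_id=f"miR-sim-{k + 1}", kind=MIRNA,
            condition=f"profile_{k + 1}", source_id="SYN",
        )
        for k in range(n_mirna_profiles)
    ]
    return PerturbagenCatalogue(entries)
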