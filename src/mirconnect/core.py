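"""Core containers for perturbation-response signature matching.

The central objects mirror the vocabulary of connectivity-map style
analyses: an :class:`ExpressionProfile` holds one treatment/control
experiment; a :class:`ResponseSignature` is the pair of up/down probe
sets called differentially expressed for one perturbagen instance; a
:class:`RankedResponsePattern` is the full probe list of that experiment
ordered from most up- to most down-regulated by the ranking statistic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

TREATMENT = "treatment"
CONTROL = "control"
VALID_CLASSES = (TREATMENT, CONTROL)

MIRNA = "miRNA"
SMALL_MOLECULE = "small_molecule"
VALID_KINDS = (MIRNA, SMALL_MOLECULE)


class MirconnectError(Exception):
    """Base class for all package errors."""


class FormatError(MirconnectError):
    """A file does not conform to its declared dialect."""


class ParseError(MirconnectError):
    """A cell or token could not be parsed; carries a location report."""


class ValidationError(MirconnectError):
    """Structurally well-formed input violating a semantic contract."""


class DomainError(MirconnectError, ValueError):
    """A numeric argument outside the statistic's domain (e.g. t <= 0)."""


class UndefinedEnrichmentError(MirconnectError):
    """Enrichment score undefined (empty hit set, or hits cover the list)."""


@dataclass
class ExpressionProfile:
    """Probe x sample expression matrix for one perturbation experiment.

    Values are linear-scale expression; ``sample_classes`` assigns each
    column to ``treatment`` or ``control``. A profile belongs to exactly
    one perturbagen (a miRNA transfection or a small-molecule instance).
    """

    probe_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    sample_classes: list[str]
    perturbagen_id: str
    perturbagen_kind: str
    condition: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValidationError(
                f"{len(self.probe_ids)} probe ids for {n_probes} matrix rows"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids in profile")
        if len(self.sample_ids) != n_samples or len(self.sample_classes) != n_samples:
            raise ValidationError("sample ids/classes must match matrix columns")
        bad = set(self.sample_classes) - set(VALID_CLASSES)
        if bad:
            raise ValidationError(f"unknown sample class tokens: {sorted(bad)}")
        if TREATMENT not in self.sample_classes or CONTROL not in self.sample_classes:
            raise ValidationError("need at least one treatment and one control sample")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")
        if self.perturbagen_kind not in VALID_KINDS:
            raise ValidationError(
                f"perturbagen_kind must be one of {VALID_KINDS}, "
                f"got {self.perturbagen_kind!r}"
            )

    def _class_columns(self, cls: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.sample_classes) if c == cls]
        return self.values[:, idx]

    @property
    def treatment_values(self) -> np.ndarray:
        return self._class_columns(TREATMENT)

    @property
    def control_values(self) -> np.ndarray:
        return self._class_columns(CONTROL)

    def n_per_class(self) -> tuple[int, int]:
        """(n treatment, n control) sample counts."""
        return (
            self.sample_classes.count(TREATMENT),
            self.sample_classes.count(CONTROL),
        )

    @property
    def profile_key(self) -> str:
        """Stable identifier for this profile (perturbagen, condition, source)."""
        return f"{self.perturbagen_id}|{self.condition}|{self.source_id}"


@dataclass
class RankedResponsePattern:
    """Full probe list ordered most up-regulated first, with its statistic.

    The statistic is whatever ranked the experiment (log2 fold change,
    SAM d, or amplitude a); it must be non-increasing down the list.
    Ties are broken lexicographically by probe id so that identical
    inputs yield identical patterns on every platform.
    """

    probe_ids: list[str]
    stat: np.ndarray

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        if self.stat.ndim != 1 or len(self.probe_ids) != self.stat.size:
            raise ValidationError("pattern probe ids and statistic lengths differ")
        if self.stat.size < 2:
            raise ValidationError("a ranked pattern needs at least two probes")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids in pattern")
        if not np.isfinite(self.stat).all():
            raise ValidationError("pattern statistic must be finite")
        if np.any(np.diff(self.stat) > 0):
            raise ValidationError("pattern statistic must be non-increasing")

    @classmethod
    def from_scores(
        cls, probe_ids: Sequence[str], scores: Iterable[float]
    ) -> "RankedResponsePattern":
        """Build a pattern by sorting scores descending, probe id ascending on ties."""
        scores = np.asarray(list(scores), dtype=float)
        probe_ids = list(probe_ids)
        order = sorted(range(len(probe_ids)), key=lambda i: (-scores[i], probe_ids[i]))
        return cls([probe_ids[i] for i in order], scores[order])

    def __len__(self) -> int:
        return self.stat.size

    def position_of(self) -> dict[str, int]:
        """Probe id -> 0-based position in the ranked list."""
        return {p: i for i, p in enumerate(self.probe_ids)}


@dataclass
class ResponseSignature:
    """Up- and down-regulated probe sets for one perturbagen instance."""

    perturbagen_id: str
    up_probes: frozenset[str]
    down_probes: frozenset[str]
    method: str = "unknown"
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up_probes = frozenset(self.up_probes)
        self.down_probes = frozenset(self.down_probes)
        if self.up_probes & self.down_probes:
            raise ValidationError("up and down probe sets must be disjoint")

    @property
    def is_empty(self) -> bool:
        return not (self.up_probes or self.down_probes)

    def sizes(self) -> tuple[int, int]:
        return len(self.up_probes), len(self.down_probes)


@dataclass
class InstanceTES:
    """Directional enrichment scores and combined TES for one
    (small-molecule instance, miRNA profile) pair.

    ``tes`` is exactly the mean of the two per-direction combined scores
    (signature-of-molecule in pattern-of-miRNA and vice versa).
    """

    molecule_id: str
    instance_id: str
    mirna_profile_id: str
    es_up_sm2mir: Optional[float]
    es_down_sm2mir: Optional[float]
    es_up_mir2sm: Optional[float]
    es_down_mir2sm: Optional[float]
    tes_sm2mir: float
    tes_mir2sm: float
    tes: float

    def __post_init__(self) -> None:
        for name in (
            "es_up_sm2mir",
            "es_down_sm2mir",
            "es_up_mir2sm",
            "es_down_mir2sm",
            "tes_sm2mir",
            "tes_mir2sm",
            "tes",
        ):
            v = getattr(self, name)
            if v is not None and not (-1.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [-1, 1]")
        expected = (self.tes_sm2mir + self.tes_mir2sm) / 2.0
        if self.tes != expected:
            raise ValidationError("tes must equal the mean of the two directions")


@dataclass
class AssociationRecord:
    """One (small molecule, miRNA profile) association row."""

    molecule_id: str
    mirna_id: str
    condition: str
    source_id: str
    as_score: float
    p_value: Optional[float]
    n_instances: int
    fda_approved: bool = False
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value={self.p_value} outside [0, 1]")
        if self.n_instances < 1:
            raise ValidationError("n_instances must be >= 1")

    @property
    def mirna_profile_id(self) -> str:
        return f"{self.mirna_id}|{self.condition}|{self.source_id}"


@dataclass
class CatalogueEntry:
    perturbagen_id: str
    kind: str
    condition: str = ""
    source_id: str = ""
    fda_approved: bool = False
    structure: str = ""
    atc_code: str = ""
    external_ids: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValidationError(f"unknown perturbagen kind {self.kind!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.perturbagen_id, self.condition, self.source_id)


@dataclass
class PerturbagenCatalogue:
    """Registry of perturbagens (molecules and miRNA profiles) in a run."""

    entries: list[CatalogueEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                "(perturbagen_id, condition, source_id) triples must be unique"
            )

    def molecules(self) -> list[CatalogueEntry]:
        return [e for e in self.entries if e.kind == SMALL_MOLECULE]

    def mirna_profiles(self) -> list[CatalogueEntry]:
        return [e for e in self.entries if e.kind == MIRNA]

    def molecule_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.molecules():
            seen.setdefault(e.perturbagen_id, None)
        return list(seen)

    def candidate_pairs(self) -> list[tuple[str, tuple[str, str, str]]]:
        """Enumerate every (molecule id, miRNA profile key) candidate pair.

        Each miRNA catalogue entry is one profile (a miRNA under one
        experimental condition); each distinct molecule id pairs with
        each profile.
        """
        return [
            (mol, mir.key)
            for mol in self.molecule_ids()
            for mir in self.mirna_profiles()
        ]


@dataclass
class PermutationResult:
    """Null distribution and empirical p-value for one association."""

    observed_as: float
    null_as: list[float]
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value outside [0, 1]")
        if len(self.null_as) != self.n_perm:
            raise ValidationError("null_as length must equal n_perm")
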