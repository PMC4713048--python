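"""Readers and writers for the dialects used around signature matching.

Supported formats: plain TSV expression matrices, GCT 1.2, two-column
class-label files, GMT signatures (one ``_up``/``_down`` line per
direction), RNK ranked patterns, perturbagen catalogues and association
tables as TSV. All files are UTF-8, tab-separated, LF-terminated.

Readers never reorder probes: order is file order. Writer/reader pairs
are lossless round trips for valid inputs; probe-universe mismatches
between files are left to scoring time.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CONTROL,
    TREATMENT,
    VALID_CLASSES,
    AssociationRecord,
    CatalogueEntry,
    FormatError,
    ParseError,
    PerturbagenCatalogue,
    RankedResponsePattern,
    ResponseSignature,
    ValidationError,
)

PathLike = Union[str, Path]

_ASSOC_COLUMNS = [
    "small_molecule",
    "fda_approved",
    "mirna",
    "source_id",
    "condition",
    "AS",
    "p_value",
    "n_instances",
]


def _open_lines(path: PathLike) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.splitlines()


def _parse_matrix_body(
    rows: list[list[str]], sample_names: list[str], first_body_line: int
) -> pd.DataFrame:
    probe_ids: list[str] = []
    data = np.empty((len(rows), len(sample_names)), dtype=float)
    for r, fields in enumerate(rows):
        if len(fields) != len(sample_names) + 1:
            raise FormatError(
                f"line {first_body_line + r}: expected "
                f"{len(sample_names) + 1} fields, found {len(fields)}"
            )
        probe_ids.append(fields[0])
        for c, tok in enumerate(fields[1:]):
            try:
                data[r, c] = float(tok)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric value {tok!r} at line {first_body_line + r}, "
                    f"column {c + 2} (sample {sample_names[c]!r})"
                ) from exc
    if len(set(probe_ids)) != len(probe_ids):
        dupes = sorted({p for p in probe_ids if probe_ids.count(p) > 1})
        raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
    return pd.DataFrame(data, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sample_names)


def read_expression_matrix(path: PathLike, dialect: str = "tsv") -> pd.DataFrame:
    """Read a probes x samples matrix, preserving file probe order.

    ``dialect`` is ``"tsv"`` (header of sample names, first column probe
    ids) or ``"gct"`` (GCT 1.2: ``#1.2`` version line, dims line,
    Name/Description columns).
    """
    lines = _open_lines(path)
    if dialect == "tsv":
        if not lines:
            raise FormatError(f"{path}: empty file")
        header = lines[0].split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must name at least one sample")
        sample_names = header[1:]
        rows = [ln.split("\t") for ln in lines[1:] if ln != ""]
        return _parse_matrix_body(rows, sample_names, first_body_line=2)
    if dialect == "gct":
        if len(lines) < 3 or lines[0].strip() != "#1.2":
            raise FormatError(f"{path}: missing GCT '#1.2' version line")
        dims = lines[1].split("\t")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed GCT dims line {lines[1]!r}") from exc
        header = lines[2].split("\t")
        if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
            raise FormatError(f"{path}: GCT header must start Name\\tDescription")
        sample_names = header[2:]
        if len(sample_names) != n_cols:
            raise FormatError(
                f"{path}: dims line says {n_cols} samples, header has "
                f"{len(sample_names)}"
            )
        body = [ln.split("\t") for ln in lines[3:] if ln != ""]
        if len(body) != n_rows:
            raise FormatError(
                f"{path}: dims line says {n_rows} rows, body has {len(body)}"
            )
        rows = [[f[0]] + f[2:] for f in body]  # drop Description column
        return _parse_matrix_body(rows, sample_names, first_body_line=4)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_expression_matrix(
    matrix: pd.DataFrame, path: PathLike, dialect: str = "tsv"
) -> None:
    """Write a probes x samples matrix in ``tsv`` or ``gct`` dialect."""
    path = Path(path)
    buf = io.StringIO()
    if dialect == "tsv":
        buf.write("probe_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for probe, row in zip(matrix.index, matrix.to_numpy()):
            buf.write(str(probe) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif dialect == "gct":
        buf.write("#1.2\n")
        buf.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        buf.write("Name\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for probe, row in zip(matrix.index, matrix.to_numpy()):
            buf.write(
                str(probe) + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_class_labels(
    path: PathLike, sample_ids: Optional[Sequence[str]] = None
) -> list[str]:
    """Read a two-column (sample, class) file.

    When ``sample_ids`` is given, labels are aligned to that order
    regardless of file order; a sample absent from the file is an error.
    Classes must be ``treatment`` or ``control``.
    """
    mapping: dict[str, str] = {}
    for i, ln in enumerate(_open_lines(path), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: line {i}: expected 2 fields")
        sample, cls = fields[0].strip(), fields[1].strip()
        if cls not in VALID_CLASSES:
            raise ValidationError(
                f"{path}: line {i}: unknown class token {cls!r} "
                f"(expected one of {VALID_CLASSES})"
            )
        if sample in mapping:
            raise ValidationError(f"{path}: duplicate sample {sample!r}")
        mapping[sample] = cls
    if sample_ids is None:
        return list(mapping.values())
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValidationError(f"{path}: samples missing from label file: {missing}")
    return [mapping[s] for s in sample_ids]


def write_class_labels(
    sample_ids: Sequence[str], classes: Sequence[str], path: PathLike
) -> None:
    lines = [f"{s}\t{c}" for s, c in zip(sample_ids, classes)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_signature(signature: ResponseSignature, path: PathLike) -> None:
    """Write a signature as GMT: one ``<id>_up`` / ``<id>_down`` line per
    non-empty direction (name, description, members)."""
    if signature.is_empty:
        raise ValidationError("cannot write an empty signature")
    lines = []
    desc = f"method={signature.method}"
    if signature.up_probes:
        lines.append(
            "\t".join([f"{signature.perturbagen_id}_up", desc]
                      + sorted(signature.up_probes))
        )
    if signature.down_probes:
        lines.append(
            "\t".join([f"{signature.perturbagen_id}_down", desc]
                      + sorted(signature.down_probes))
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_signature(path: PathLike) -> ResponseSignature:
    """Read a GMT signature written by :func:`write_signature`."""
    up: set[str] = set()
    down: set[str] = set()
    perturbagen_id = None
    method = "unknown"
    for i, ln in enumerate(_open_lines(path), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {i}: GMT line needs >= 3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        if desc.startswith("method="):
            method = desc.split("=", 1)[1]
        if name.endswith("_up"):
            base, target = name[:-3], up
        elif name.endswith("_down"):
            base, target = name[:-5], down
        else:
            raise FormatError(
                f"{path}: line {i}: set name must end in _up or _down"
            )
        if perturbagen_id is not None and base != perturbagen_id:
            raise ValidationError(
                f"{path}: mixed perturbagen ids {perturbagen_id!r} vs {base!r}"
            )
        perturbagen_id = base
        target.update(m for m in members if m)
    if perturbagen_id is None:
        raise FormatError(f"{path}: no GMT lines found")
    return ResponseSignature(perturbagen_id, frozenset(up), frozenset(down), method)


def write_pattern(pattern: RankedResponsePattern, path: PathLike) -> None:
    """Write a ranked pattern as a two-column RNK file, list order preserved."""
    lines = [f"{p}\t{float(s)!r}" for p, s in zip(pattern.probe_ids, pattern.stat)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pattern(path: PathLike) -> RankedResponsePattern:
    """Read an RNK file; probes are re-sorted descending (tie: probe id)."""
    probes: list[str] = []
    scores: list[float] = []
    for i, ln in enumerate(_open_lines(path), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: line {i}: RNK line needs 2 fields")
        probes.append(fields[0])
        try:
            scores.append(float(fields[1]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric score") from exc
    return RankedResponsePattern.from_scores(probes, scores)


def write_association_table(
    records: Iterable[AssociationRecord],
    path: PathLike,
    header_comment: Optional[str] = None,
) -> None:
    """Write association rows as TSV (AS at 6 decimals).

    Optional annotation keys (union over all records) become extra
    columns after the fixed header.
    """
    records = list(records)
    ann_keys: list[str] = []
    for r in records:
        for k in r.annotations:
            if k not in ann_keys:
                ann_keys.append(k)
    buf = io.StringIO()
    if header_comment:
        for ln in header_comment.splitlines():
            buf.write(f"# {ln}\n")
    buf.write("\t".join(_ASSOC_COLUMNS + ann_keys) + "\n")
    for r in records:
        p = "NA" if r.p_value is None else f"{r.p_value:.6f}"
        row = [
            r.molecule_id,
            "yes" if r.fda_approved else "no",
            r.mirna_id,
            r.source_id,
            r.condition,
            f"{r.as_score:.6f}",
            p,
            str(r.n_instances),
        ] + [str(r.annotations.get(k, "")) for k in ann_keys]
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_association_table(path: PathLike) -> list[AssociationRecord]:
    lines = [ln for ln in _open_lines(path) if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no header line")
    header = lines[0].split("\t")
    if header[: len(_ASSOC_COLUMNS)] != _ASSOC_COLUMNS:
        raise FormatError(f"{path}: unexpected association table header")
    ann_keys = header[len(_ASSOC_COLUMNS):]
    records = []
    for ln in lines[1:]:
        f = ln.split("\t")
        records.append(
            AssociationRecord(
                molecule_id=f[0],
                fda_approved=(f[1] == "yes"),
                mirna_id=f[2],
                source_id=f[3],
                condition=f[4],
                as_score=float(f[5]),
                p_value=None if f[6] == "NA" else float(f[6]),
                n_instances=int(f[7]),
                annotations={
                    k: v
                    for k, v in zip(ann_keys, f[len(_ASSOC_COLUMNS):])
                    if v != ""
                },
            )
        )
    return records


_TES_COLUMNS = [
    "molecule_id",
    "instance_id",
    "mirna_profile_id",
    "es_up_sm2mir",
    "es_down_sm2mir",
    "es_up_mir2sm",
    "es_down_mir2sm",
    "tes_sm2mir",
    "tes_mir2sm",
    "tes",
]


def write_instance_tes(
    instances: Iterable["InstanceTES"],
    path: PathLike,
    header_comment: Optional[str] = None,
) -> None:
    """Long-format TSV: one row per (molecule instance, miRNA profile)."""
    from .core import InstanceTES  # noqa: F401  (type for docs)

    buf = io.StringIO()
    if header_comment:
        for ln in header_comment.splitlines():
            buf.write(f"# {ln}\n")
    buf.write("\t".join(_TES_COLUMNS) + "\n")
    for it in instances:
        row = [it.molecule_id, it.instance_id, it.mirna_profile_id]
        for name in _TES_COLUMNS[3:]:
            v = getattr(it, name)
            row.append("NA" if v is None else repr(float(v)))
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_instance_tes(path: PathLike) -> list["InstanceTES"]:
    from .core import InstanceTES

    lines = [ln for ln in _open_lines(path) if ln and not ln.startswith("#")]
    if not lines or lines[0].split("\t") != _TES_COLUMNS:
        raise FormatError(f"{path}: unexpected instance-TES header")
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        vals = [None if tok == "NA" else float(tok) for tok in f[3:]]
        out.append(InstanceTES(f[0], f[1], f[2], *vals))
    return out


_CAT_COLUMNS = [
    "perturbagen_id",
    "kind",
    "condition",
    "source_id",
    "fda_approved",
    "structure",
    "atc_code",
    "external_ids",
]


def write_catalogue(catalogue: PerturbagenCatalogue, path: PathLike) -> None:
    buf = io.StringIO()
    buf.write("\t".join(_CAT_COLUMNS) + "\n")
    for e in catalogue.entries:
        buf.write(
            "\t".join(
                [
                    e.perturbagen_id,
                    e.kind,
                    e.condition,
                    e.source_id,
                    "yes" if e.fda_approved else "no",
                    e.structure,
                    e.atc_code,
                    e.external_ids,
                ]
            )
            + "\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_catalogue(path: PathLike) -> PerturbagenCatalogue:
    lines = [ln for ln in _open_lines(path) if ln and not ln.startswith("#")]
    if not lines or lines[0].split("\t") != _CAT_COLUMNS:
        raise FormatError(f"{path}: unexpected catalogue header")
    entries = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(_CAT_COLUMNS):
            raise FormatError(f"{path}: catalogue row with {len(f)} fields")
        entries.append(
            CatalogueEntry(
                perturbagen_id=f[0],
                kind=f[1],
                condition=f[2],
                source_id=f[3],
                fda_approved=(f[4] == "yes"),
                structure=f[5],
                atc_code=f[6],
                external_ids=f[7],
            )
        )
    return PerturbagenCatalogue(entries)
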