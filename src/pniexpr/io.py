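"""Readers and writers for every on-disk artifact the pipeline touches.

Formats: count-matrix TSV (probe id, probe class, one column per sample),
sample-annotation CSV, minimal NanoString RCC lane files, GMT gene-set
collections, and TSV/JSON result tables.  Readers reject malformed input
rather than coercing it; every writer/reader pair round-trips valid data
exactly (integer matrices bit-exactly).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    canonical_probe_class,
    validate_annotation,
)

# ---------------------------------------------------------------------------
# Count-matrix TSV
# ---------------------------------------------------------------------------


def write_counts_table(matrix: ExpressionMatrix, path) -> None:
    """Write probe_id <tab> probe_class <tab> sample columns."""
    path = Path(path)
    df = matrix.values.copy()
    out = pd.DataFrame(index=df.index)
    out.insert(0, "probe_class", matrix.probe_classes)
    out = pd.concat([out, df], axis=1)
    out.index.name = "probe_id"
    # repr-based float formatting keeps full precision for normalized data
    out.to_csv(path, sep="\t")


def read_counts_table(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a count/expression table; see :func:`write_counts_table`.

    The first column holds probe ids, the second the probe class
    (case-insensitive); remaining columns are samples.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise ValueError(f"{path}: empty counts file")
    header = rows[0]
    if len(header) < 2:
        raise ValueError(f"{path}: header needs probe id, probe class and sample columns")
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row at line {lineno} "
                             f"({len(row)} fields, expected {width})")
    probe_ids = [r[0] for r in rows[1:]]
    seen: set[str] = set()
    for pid in probe_ids:
        if pid in seen:
            raise ValueError(f"{path}: duplicate probe id {pid!r}")
        seen.add(pid)
    classes = [canonical_probe_class(r[1]) for r in rows[1:]]
    data = np.array([[float(v) for v in r[2:]] for r in rows[1:]], dtype=float)
    if data.size and np.all(data == np.round(data)):
        # integer-valued matrices are raw counts and must be nonnegative
        if (data < 0).any():
            raise ValueError(f"{path}: negative count in raw matrix")
        data = data.astype(np.int64)
    values = pd.DataFrame(data, index=pd.Index(probe_ids, name="probe_id"),
                          columns=header[2:])
    return ExpressionMatrix(values=values,
                            probe_classes=pd.Series(classes, index=values.index))


# ---------------------------------------------------------------------------
# Sample-annotation CSV
# ---------------------------------------------------------------------------


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(Path(path), index_label="sample_id")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(Path(path), index_col="sample_id")
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# Minimal RCC lane files
# ---------------------------------------------------------------------------


def write_rcc(matrix: ExpressionMatrix, directory, lane_ids=None) -> list[Path]:
    """Write one minimal RCC file per sample column; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not matrix.is_integer():
        raise ValueError("RCC files hold raw integer counts only")
    paths = []
    for lane, sample in enumerate(matrix.sample_ids, start=1):
        path = directory / f"{sample}.RCC"
        with open(path, "w") as fh:
            fh.write("<Header>\nFileVersion,1.7\nSoftwareVersion,4.0\n</Header>\n")
            fh.write(f"<Sample_Attributes>\nID,{sample}\nOwner,\nDate,\n"
                     "</Sample_Attributes>\n")
            fh.write(f"<Lane_Attributes>\nID,{lane}\nFovCount,280\n</Lane_Attributes>\n")
            fh.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
            for pid in matrix.probe_ids:
                cls = matrix.probe_classes[pid]
                count = int(matrix.values.at[pid, sample])
                fh.write(f"{cls},{pid},NA,{count}\n")
            fh.write("</Code_Summary>\n")
        paths.append(path)
    return paths


def _parse_rcc(path: Path):
    sections: dict[str, list[str]] = {}
    current = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("<") and line.endswith(">"):
            name = line.strip("<>")
            if name.startswith("/"):
                current = None
            else:
                current = name
                sections[current] = []
            continue
        if current is not None:
            sections[current].append(line)
    return sections


def read_rcc(paths) -> ExpressionMatrix:
    """Read one or more RCC lane files into a single matrix (one column each)."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no RCC files given")
    per_sample: dict[str, pd.Series] = {}
    classes_ref: pd.Series | None = None
    for path in paths:
        sections = _parse_rcc(path)
        if "Code_Summary" not in sections:
            raise ValueError(f"{path}: missing <Code_Summary> section")
        sample_id = path.stem
        for line in sections.get("Sample_Attributes", []):
            key, _, val = line.partition(",")
            if key == "ID" and val:
                sample_id = val
        probe_ids, classes, counts = [], [], []
        rows = sections["Code_Summary"]
        body = rows[1:] if rows and rows[0].lower().startswith("codeclass") else rows
        for line in body:
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed Code_Summary row {line!r}")
            cls, name, _acc, count = parts
            c = int(count)
            if c < 0:
                raise ValueError(f"{path}: negative count for probe {name!r}")
            probe_ids.append(name)
            classes.append(canonical_probe_class(cls))
            counts.append(c)
        col = pd.Series(counts, index=pd.Index(probe_ids, name="probe_id"), dtype=np.int64)
        cls_series = pd.Series(classes, index=col.index)
        if classes_ref is None:
            classes_ref = cls_series
        else:
            missing = classes_ref.index.symmetric_difference(col.index)
            if len(missing):
                raise ValueError(
                    f"{path}: probe set differs from first lane; offending probes "
                    f"{list(missing[:5])}"
                )
            col = col.reindex(classes_ref.index)
        if sample_id in per_sample:
            raise ValueError(f"duplicate sample id {sample_id!r} across RCC lanes")
        per_sample[sample_id] = col
    values = pd.DataFrame(per_sample)
    values.index.name = "probe_id"
    return ExpressionMatrix(values=values, probe_classes=classes_ref)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set_id <tab> description <tab> member genes..."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            sid, desc = parts[0], parts[1]
            if sid in sets:
                raise ValueError(f"{path}: duplicate set id {sid!r} at line {lineno}")
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {sid!r} has no members")
            sets[sid] = members
            names[sid] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(Path(path), "w") as fh:
        for sid, members in collection:
            desc = collection.names.get(sid, "")
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Result tables / metadata
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(Path(path), sep="\t", index_label=index_label)


def write_json(obj, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, (Path,)):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
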