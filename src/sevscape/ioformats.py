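"""Readers and writers for every on-disk artifact.

Formats: gene×sample TSV matrices; MatrixMarket (MTX) triplets for
single-cell data; GMT gene-set collections; one-gene-per-line lists;
sample-metadata TSV; JSON result reports; YAML/JSON configs. TSV dialect
is UTF-8, tab-separated, no quoting, feature ids in column 1, '\n' line
ends — bit-exact and diff-friendly. Gene identifiers are opaque
case-sensitive strings: no symbol or alias resolution happens here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .containers import (
    ExpressionMatrix,
    SampleMetadata,
    SCHEMA_VERSION,
)


class FormatError(ValueError):
    """An on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# expression matrices


def write_matrix_tsv(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df = values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix_tsv(path: str | Path, kind: str = "count") -> ExpressionMatrix:
    """Read a gene×sample TSV: header row of sample ids, feature ids in col 1."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found (line 1)")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s) {dup}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]].tolist()
        raise FormatError(f"{path}: non-numeric values in column(s) {bad}")
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise FormatError(
            f"{path}: non-finite value at feature {df.index[i]!r} (line {i + 2})"
        )
    if kind == "count" and (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative count at feature {df.index[i]!r} (line {i + 2})"
        )
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return ExpressionMatrix(df, kind=kind)


def read_matrix(path: str | Path, format: str = "tsv", kind: str = "count", **kw) -> ExpressionMatrix:
    if format == "tsv":
        return read_matrix_tsv(path, kind=kind)
    if format == "mtx":
        df = read_mtx_triplet(path, **kw)
        return ExpressionMatrix(df, kind=kind)
    raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# MatrixMarket triplets (single-cell convention: features × barcodes)


def write_mtx_triplet(
    df: pd.DataFrame,
    directory: str | Path,
    matrix_name: str = "matrix.mtx",
    features_name: str = "features.tsv",
    barcodes_name: str = "barcodes.tsv",
) -> None:
    """Write a features×barcodes DataFrame as an MTX triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / matrix_name, sparse.csr_matrix(df.to_numpy()))
    (directory / features_name).write_text("\n".join(map(str, df.index)) + "\n")
    (directory / barcodes_name).write_text("\n".join(map(str, df.columns)) + "\n")


def read_mtx_triplet(
    directory: str | Path,
    matrix_name: str = "matrix.mtx",
    features_name: str = "features.tsv",
    barcodes_name: str = "barcodes.tsv",
) -> pd.DataFrame:
    """Read an MTX triplet back into a features×barcodes DataFrame."""
    directory = Path(directory)
    try:
        m = spio.mmread(directory / matrix_name)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{directory / matrix_name}: invalid MatrixMarket file: {exc}") from exc
    features = [
        ln.split("\t")[0]
        for ln in (directory / features_name).read_text().splitlines()
        if ln
    ]
    barcodes = [ln for ln in (directory / barcodes_name).read_text().splitlines() if ln]
    m = np.asarray(m.todense()) if sparse.issparse(m) else np.asarray(m)
    if m.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{directory}: matrix is {m.shape} but features/barcodes files "
            f"declare ({len(features)}, {len(barcodes)})"
        )
    return pd.DataFrame(m, index=features, columns=barcodes)


# ---------------------------------------------------------------------------
# sample metadata


def write_metadata_tsv(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "patient_id": m.patient_id,
            "source": m.source,
            "group": "" if m.group is None else m.group,
        }
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata_tsv(path: str | Path) -> list[SampleMetadata]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "patient_id", "source"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: metadata must have columns {sorted(required)}")
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample_id {sid!r} (line {i + 2})")
        seen.add(sid)
        try:
            out.append(
                SampleMetadata(
                    sample_id=sid,
                    patient_id=row["patient_id"],
                    source=row["source"],
                    group=row.get("group") or None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# gene sets and gene lists


def read_gmt(path: str | Path) -> dict[str, dict[str, Any]]:
    """Read a GMT collection: name, description, members per line.

    Returns an ordered mapping set-name → {"description": str,
    "members": set[str]}; members are deduplicated within a set.
    """
    path = Path(path)
    sets: dict[str, dict[str, Any]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: GMT lines need name, description and ≥1 member"
            )
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = {"description": desc, "members": set(m for m in members if m)}
    return sets


def write_gmt(sets: Mapping[str, Mapping[str, Any]], path: str | Path) -> None:
    lines = []
    for name, entry in sets.items():
        members = sorted(entry["members"])
        lines.append("\t".join([name, entry.get("description", "")] + members))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if not g or g.startswith("#"):
            continue
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# reports and configs


def write_report(result: Any, path: str | Path) -> None:
    """Serialize a pipeline result (anything with ``to_dict``) to JSON."""
    d = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    d.setdefault("schema_version", SCHEMA_VERSION)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def write_differential_tsv(result, path: str | Path) -> None:
    """Tabular view of a DifferentialResult: feature, fc, p, p_adj, direction."""
    cols = ["feature", "fold_change", "log2_fc", "p_value", "p_adjusted", "direction"]
    result.table[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        loaded = yaml.safe_load(text)
    else:
        loaded = json.loads(text)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return loaded
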