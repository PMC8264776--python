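"""Readers and writers for the pipeline's on-disk text formats.

Every format is UTF-8, tab-separated, with ``#`` comment lines ignored.
Writers are deterministic: two writes of the same object are
byte-identical. Expression matrices carry an optional structured
``#condition`` comment line assigning a control/stress-style label to
each sample.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    LabelSet,
    PipelineConfig,
    RankedEdgeList,
    RegulatorSet,
)

PathLike = Union[str, Path]

_FLOAT_FMT = "%.10g"

CONDITION_PREFIX = "#condition"


def _read_lines(path: PathLike) -> list[tuple[int, str]]:
    """Return (1-based line number, line) pairs, skipping blanks and comments."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((i, line))
    return out


# -- expression matrices ------------------------------------------------------

def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids)."""
    condition = None
    with open(path, encoding="utf-8") as fh:
        raw = fh.read()
    kept: list[str] = []
    for line in raw.splitlines():
        if line.startswith(CONDITION_PREFIX + "\t"):
            condition = line.split("\t")[1:]
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        kept.append(line)
    if not kept:
        raise FormatError(f"{path}: empty expression file")
    header = kept[0].split("\t")[1:]
    seen: set[str] = set()
    for sample in header:  # pandas silently renames duplicate columns
        if sample in seen:
            raise FormatError(f"{path}: duplicate sample id {sample!r}")
        seen.add(sample)
    df = pd.read_csv(_io.StringIO("\n".join(kept)), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate gene id {dup[0]!r}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy() & df.notna().to_numpy())
    if len(bad):
        r, c = bad[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    cond = None
    if condition is not None:
        if len(condition) != values.shape[1]:
            raise FormatError(
                f"{path}: condition line has {len(condition)} labels for "
                f"{values.shape[1]} samples"
            )
        cond = pd.Series(condition, index=values.columns)
    return ExpressionMatrix(values=values.astype(float), condition=cond)


def write_expression_matrix(expr: ExpressionMatrix, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if expr.condition is not None:
            fh.write(CONDITION_PREFIX + "\t" + "\t".join(expr.condition.astype(str)) + "\n")
        expr.values.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n")


# -- ranked edge lists --------------------------------------------------------

def read_edge_list(path: PathLike, method: str = "unknown") -> RankedEdgeList:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"regulator": str, "target": str})
    missing = [c for c in ("regulator", "target", "score", "rank") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df["score"] = df["score"].astype(float)
    try:
        return RankedEdgeList(method=method, edges=df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_edge_list(edges: RankedEdgeList, path: PathLike) -> None:
    edges.edges.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                       lineterminator="\n")


# -- gene set collections (GMT) ----------------------------------------------

def read_gmt(path: PathLike) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in _read_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        sid, desc, genes = fields[0], fields[1], tuple(g for g in fields[2:] if g)
        if sid in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
        if not genes:
            raise FormatError(f"{path}:{lineno}: set {sid!r} has no genes")
        sets[sid] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, (desc, genes) in collection.sets.items():
            fh.write("\t".join((sid, desc) + tuple(genes)) + "\n")


# -- TF lists and labels ------------------------------------------------------

def read_tf_list(path: PathLike) -> RegulatorSet:
    tfs = [line.split("\t")[0].strip() for _, line in _read_lines(path)]
    if not tfs:
        raise FormatError(f"{path}: no TF identifiers found")
    return RegulatorSet(tfs)


def write_tf_list(tfs: RegulatorSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf in tfs:
            fh.write(tf + "\n")


def read_labels(path: PathLike) -> LabelSet:
    assignments: dict[str, str] = {}
    family: dict[str, str] = {}
    rows = _read_lines(path)
    for lineno, line in rows:
        fields = line.split("\t")
        if fields[0] == "tf_id":  # header
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected tf_id<TAB>label")
        tf, label = fields[0], fields[1]
        if label not in ("positive", "negative"):
            raise FormatError(f"{path}:{lineno}: label must be positive/negative, "
                              f"got {label!r}")
        if tf in assignments:
            raise FormatError(f"{path}:{lineno}: duplicate tf_id {tf!r}")
        assignments[tf] = label
        if len(fields) >= 3 and fields[2]:
            family[tf] = fields[2]
    return LabelSet(assignments=assignments, family=family or None)


def write_labels(labels: LabelSet, path: PathLike) -> None:
    fam = labels.family or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf_id\tlabel\tfamily\n")
        for tf in sorted(labels.assignments):
            fh.write(f"{tf}\t{labels.assignments[tf]}\t{fam.get(tf, '')}\n")


# -- reference edge pairs -----------------------------------------------------

def read_pair_list(path: PathLike) -> set[tuple[str, str]]:
    """Read plain (tf, gene) pairs, one per line, ignoring any extra columns."""
    pairs = set()
    for lineno, line in _read_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected tf<TAB>gene")
        pairs.add((fields[0], fields[1]))
    return pairs


def write_pair_list(pairs: Iterable[tuple[str, str]], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf, gene in sorted(set(pairs)):
            fh.write(f"{tf}\t{gene}\n")


# -- configuration ------------------------------------------------------------

def read_config(path: PathLike) -> PipelineConfig:
    """Parse a flat YAML key-value config; unknown keys are an error."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key-value document")
    try:
        return PipelineConfig.from_dict(data)
    except (ValidationError, TypeError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_config(config: PipelineConfig, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
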