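"""Readers and writers for the tab-delimited tables the pipeline consumes.

Formats
-------
Expression / CNV / methylation
    TSV, genes in rows (first column = gene symbol), samples in columns
    (header row).  Expression values are RMA-scale (nonnegative); CNV values
    are log2 ratios; methylation values are beta values in [0, 1].
Clinical
    TSV with header ``sample_id<TAB>time<TAB>event`` — time in days (> 0),
    event 1 = death observed, 0 = censored.
Pathways
    TSV with columns ``pathway_id, interaction_id, gene, role`` where role is
    one of ``promoter``, ``inhibitor``, ``output``; one row per gene slot per
    interaction.  An optional ``pathway_name`` column carries display names.

Validation is strict: a missing header or unknown role is a
:class:`~pathstrat.exceptions.FormatError`, a non-numeric cell is a
:class:`~pathstrat.exceptions.ParseError` naming the offending row/column, and
domain violations (negative times, methylation outside [0, 1]) are
:class:`~pathstrat.exceptions.RangeError` /
:class:`~pathstrat.exceptions.ValidationError`.  Rows with missing cells are
dropped and logged rather than imputed.  Duplicate gene rows (multiple probes
per symbol) are collapsed by their per-cell mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, RangeError, ValidationError
from .pathways import Interaction, PathwaySet

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "AlterationSource",
    "ClinicalTable",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_pathway_set",
    "write_pathway_set",
    "align_samples",
]

_MATRIX_KINDS = ("expression", "cnv", "methylation")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative RMA-scale expression."""

    data: pd.DataFrame  # index = gene symbols, columns = sample ids

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class AlterationSource:
    """Genes x samples matrix of CNV log2 ratios or methylation betas."""

    kind: str  # "cnv" | "methylation"
    data: pd.DataFrame

    def __post_init__(self):
        if self.kind not in ("cnv", "methylation"):
            raise ValueError(f"unknown alteration kind {self.kind!r}")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """Survival table: one row per sample with (time, event)."""

    data: pd.DataFrame  # index = sample_id, columns = [time, event]

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def _read_raw_table(path) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.columns.empty:
        raise FormatError(f"{path}: no sample columns found")
    for col in raw.columns:
        try:
            float(col)
        except (TypeError, ValueError):
            continue
        raise FormatError(
            f"{path}: header row appears numeric (token {col!r}); "
            "first line must contain sample identifiers"
        )
    return raw


def _to_numeric(raw: pd.DataFrame, path) -> pd.DataFrame:
    # column-wise astype(float) uses the correctly-rounded parser, so a
    # write/read cycle reproduces doubles exactly (round-trip invariant)
    cols = {}
    for c in raw.columns:
        try:
            cols[c] = raw[c].astype(float)
        except (TypeError, ValueError):
            for r, val in raw[c].items():
                if isinstance(val, str) and val.strip() != "":
                    try:
                        float(val)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric value {val!r} at gene "
                            f"{r!r}, sample {c!r}") from None
            raise  # unreachable for well-formed string frames
    return pd.DataFrame(cols, index=raw.index)


def read_matrix(path, kind: str = "expression") -> Union[ExpressionMatrix, AlterationSource]:
    """Read a genes x samples TSV as expression, CNV or methylation data.

    Rows containing missing cells are dropped (and logged); duplicate gene
    rows are collapsed by mean; kind-specific range constraints are enforced.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"kind must be one of {_MATRIX_KINDS}, got {kind!r}")
    raw = _read_raw_table(path)
    num = _to_numeric(raw, path)

    missing = num.isna().any(axis=1)
    if missing.any():
        logger.info("%s: dropped %d rows with missing values", path, int(missing.sum()))
        num = num.loc[~missing]

    num.index = num.index.astype(str).str.upper()
    if num.index.has_duplicates:
        n_dup = int(num.index.duplicated().sum())
        num = num.groupby(level=0, sort=False).mean()
        logger.info("%s: collapsed %d duplicate gene rows by mean", path, n_dup)

    if kind == "methylation":
        vals = num.to_numpy()
        out = (vals < 0) | (vals > 1)
        if out.any():
            r, c = np.argwhere(out)[0]
            raise RangeError(
                f"{path}: methylation beta {vals[r, c]!r} outside [0, 1] at gene "
                f"{num.index[r]!r}, sample {num.columns[c]!r}"
            )
        return AlterationSource(kind="methylation", data=num)
    if kind == "cnv":
        finite = np.isfinite(num.to_numpy()).all(axis=1)
        if not finite.all():
            logger.info("%s: dropped %d rows with non-finite CNV values",
                        path, int((~finite).sum()))
            num = num.loc[finite]
        return AlterationSource(kind="cnv", data=num)

    neg = (num.to_numpy() < 0).any(axis=1)
    if neg.any():
        logger.info("%s: dropped %d expression rows with negative values",
                    path, int(neg.sum()))
        num = num.loc[~neg]
    return ExpressionMatrix(data=num)


def write_matrix(matrix, path) -> None:
    """Write an ExpressionMatrix or AlterationSource as TSV (full precision)."""
    df = matrix.data
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    """Read a survival table; rejects invalid times, events, duplicate ids."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate sample_id(s): {sorted(set(dup))}")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    bad_time = df.loc[time.isna() | (time <= 0), "sample_id"].tolist()
    if bad_time:
        raise ValidationError(f"{path}: non-positive or non-numeric time for {bad_time}")
    bad_event = df.loc[~event.isin([0, 1]), "sample_id"].tolist()
    if bad_event:
        raise ValidationError(f"{path}: event not in {{0,1}} for {bad_event}")
    out = pd.DataFrame({"time": time.to_numpy(dtype=float),
                        "event": event.to_numpy(dtype=int)},
                       index=pd.Index(df["sample_id"].to_numpy(), name="sample_id"))
    return ClinicalTable(data=out)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


_ROLES = ("promoter", "inhibitor", "output")


def read_pathway_set(path) -> PathwaySet:
    """Read the pathway TSV dialect into a :class:`PathwaySet`.

    A converter for simple-interaction-format (SIF) input is intentionally not
    provided; SIF lacks the promoter/inhibitor/output role typing this dialect
    requires, so conversion needs curation upstream.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "interaction_id", "gene", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    bad_roles = sorted(set(df["role"]) - set(_ROLES))
    if bad_roles:
        raise FormatError(f"{path}: unknown role token(s) {bad_roles}; expected {_ROLES}")
    names = {}
    if "pathway_name" in df.columns:
        names = dict(df.groupby("pathway_id")["pathway_name"].first())
    pathways = {}
    for (pid, iid), grp in df.groupby(["pathway_id", "interaction_id"], sort=False):
        roles = {role: tuple(grp.loc[grp["role"] == role, "gene"]) for role in _ROLES}
        ia = Interaction(  # raises FormatError when no inputs
            interaction_id=iid,
            promoter_genes=roles["promoter"],
            inhibitor_genes=roles["inhibitor"],
            output_genes=roles["output"],
        )
        pathways.setdefault(pid, []).append(ia)
    return PathwaySet(pathways=pathways, names=names)


def write_pathway_set(pathway_set: PathwaySet, path) -> None:
    rows = []
    for pid, interactions in pathway_set.pathways.items():
        name = pathway_set.names.get(pid, pid)
        for ia in interactions:
            for role, genes in (("promoter", ia.promoter_genes),
                                ("inhibitor", ia.inhibitor_genes),
                                ("output", ia.output_genes)):
                for g in genes:
                    rows.append((pid, name, ia.interaction_id, g, role))
    pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "interaction_id",
                                "gene", "role"]).to_csv(path, sep="\t", index=False)


def align_samples(*tables):
    """Common sample ids across tables, in the first table's order (logged)."""
    common = None
    for t in tables:
        ids = t.sample_ids
        common = set(ids) if common is None else common & set(ids)
    first = tables[0].sample_ids
    aligned = [s for s in first if s in common]
    logger.info("sample alignment: %s -> %d common samples",
                "/".join(str(len(t.sample_ids)) for t in tables), len(aligned))
    return aligned
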