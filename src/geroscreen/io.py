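"""Readers and writers for the screen's on-disk formats.

Signature matrices travel as text GCT version 1.3: a ``#1.3`` header, a
dimension line ``n_rows n_cols n_row_meta n_col_meta``, one table-header
line, ``n_col_meta`` column-metadata lines, and ``n_rows`` data lines, all
tab-separated.  Column metadata keys ``pert_type``, ``cell_line`` and
``target_gene`` populate :class:`~geroscreen.types.Perturbagen` fields; row
metadata columns are preserved as gene annotations.  Drug-target and
intervention tables are plain TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (
    GeneSpace,
    InterventionList,
    Intervention,
    PertType,
    Perturbagen,
    SignatureSet,
    TargetAnnotation,
    ValidationError,
)

__all__ = [
    "GCTParseError",
    "read_gct",
    "write_gct",
    "read_target_annotations",
    "read_intervention_list",
]

log = logging.getLogger(__name__)

_MISSING = {"", "na", "NA", "NaN", "nan", "-666"}  # -666 is the GCT null sentinel

PathLike = Union[str, Path]


class GCTParseError(ValidationError):
    """Malformed GCT input; the message names the offending line number."""


def _split(line: str) -> list[str]:
    return line.rstrip("\r\n").split("\t")


def read_gct(path: PathLike) -> SignatureSet:
    """Parse a text GCT 1.3 file into a validated :class:`SignatureSet`.

    Raises :class:`GCTParseError` (naming the 1-based line number) on a bad
    header, a dimension line that disagrees with the body, duplicate gene
    identifiers, or non-numeric data cells.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    if not lines or _split(lines[0])[0] != "#1.3":
        raise GCTParseError(f"{path}: line 1: expected GCT header '#1.3'")
    if len(lines) < 3:
        raise GCTParseError(f"{path}: line 2: missing dimension line")
    dims = _split(lines[1])
    if len(dims) != 4:
        raise GCTParseError(
            f"{path}: line 2: dimension line must have 4 fields, got {len(dims)}"
        )
    try:
        n_rows, n_cols, n_rmeta, n_cmeta = (int(d) for d in dims)
    except ValueError:
        raise GCTParseError(f"{path}: line 2: non-integer dimension field") from None

    header = _split(lines[2])
    expected_width = 1 + n_rmeta + n_cols
    if len(header) != expected_width:
        raise GCTParseError(
            f"{path}: line 3: header has {len(header)} fields, expected "
            f"{expected_width} (1 id + {n_rmeta} row-meta + {n_cols} columns)"
        )
    rmeta_names = header[1 : 1 + n_rmeta]
    col_ids = header[1 + n_rmeta :]

    # column-metadata block
    col_meta: dict[str, list[str]] = {}
    for i in range(n_cmeta):
        ln = 4 + i
        if ln - 1 >= len(lines):
            raise GCTParseError(f"{path}: line {ln}: missing column-metadata row")
        fields = _split(lines[ln - 1])
        if len(fields) != expected_width:
            raise GCTParseError(
                f"{path}: line {ln}: column-metadata row has {len(fields)} "
                f"fields, expected {expected_width}"
            )
        col_meta[fields[0]] = fields[1 + n_rmeta :]

    # data block
    first_data = 3 + n_cmeta
    body = [ln for ln in lines[first_data:] if ln.strip() != ""]
    if len(body) != n_rows:
        raise GCTParseError(
            f"{path}: line {first_data + 1}: declared {n_rows} data rows but "
            f"found {len(body)}"
        )
    gene_ids: list[str] = []
    rmeta_rows: list[list[str]] = []
    values = np.empty((n_rows, n_cols), dtype=float)
    for r, line in enumerate(body):
        ln = first_data + 1 + r
        fields = _split(line)
        if len(fields) != expected_width:
            raise GCTParseError(
                f"{path}: line {ln}: data row has {len(fields)} fields, "
                f"expected {expected_width}"
            )
        gene_ids.append(fields[0])
        rmeta_rows.append(fields[1 : 1 + n_rmeta])
        try:
            values[r, :] = [float(x) for x in fields[1 + n_rmeta :]]
        except ValueError:
            raise GCTParseError(
                f"{path}: line {ln}: non-numeric data cell"
            ) from None

    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        for r, g in enumerate(gene_ids):
            if g in seen:
                raise GCTParseError(
                    f"{path}: line {first_data + 1 + r}: duplicate gene "
                    f"identifier {g!r}"
                )
            seen.add(g)

    def meta(key: str, j: int, default: str = "") -> str:
        vals = col_meta.get(key)
        if vals is None:
            return default
        v = vals[j]
        return default if v in _MISSING else v

    perturbagens = tuple(
        Perturbagen(
            pert_id=col_ids[j],
            pert_type=PertType.parse(meta("pert_type", j, "compound")),
            cell_line=meta("cell_line", j, "default"),
            target_gene=meta("target_gene", j, "") or None,
        )
        for j in range(n_cols)
    )
    annotations = None
    if n_rmeta:
        annotations = pd.DataFrame(rmeta_rows, columns=rmeta_names, index=gene_ids)
    return SignatureSet(
        gene_space=GeneSpace(tuple(gene_ids)),
        perturbagens=perturbagens,
        values=values,
        gene_annotations=annotations,
    )


def write_gct(sigset: SignatureSet, path: PathLike) -> Path:
    """Serialize to text GCT 1.3.

    Values are written with ``repr`` precision, so a write/read round trip
    reproduces the matrix bit-for-bit.
    """
    path = Path(path)
    ann = sigset.gene_annotations
    rmeta_names = list(ann.columns) if ann is not None else []
    n_rmeta = len(rmeta_names)
    cmeta_keys = ["pert_type", "cell_line", "target_gene"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.3\n")
        fh.write(
            f"{sigset.n_genes}\t{sigset.n_perturbagens}\t{n_rmeta}\t{len(cmeta_keys)}\n"
        )
        header = ["id", *rmeta_names, *(p.pert_id for p in sigset.perturbagens)]
        fh.write("\t".join(header) + "\n")
        pad = ["na"] * n_rmeta
        for key in cmeta_keys:
            if key == "pert_type":
                vals = [p.pert_type.value for p in sigset.perturbagens]
            elif key == "cell_line":
                vals = [p.cell_line for p in sigset.perturbagens]
            else:
                vals = [p.target_gene or "na" for p in sigset.perturbagens]
            fh.write("\t".join([key, *pad, *vals]) + "\n")
        for r, gene in enumerate(sigset.gene_space.gene_ids):
            rmeta = [str(ann.iloc[r][c]) for c in rmeta_names] if ann is not None else []
            row = [repr(float(v)) for v in sigset.values[r, :]]
            fh.write("\t".join([gene, *rmeta, *row]) + "\n")
    return path


def _read_tsv(path: PathLike, expected_header: list[str]) -> pd.DataFrame:
    """Read a TSV that may or may not carry the canonical header line."""
    path = Path(path)
    try:
        peek = pd.read_csv(path, sep="\t", header=None, dtype=str, nrows=1)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=expected_header)
    has_header = list(peek.iloc[0].astype(str)) == expected_header
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        dtype=str,
        keep_default_na=False,
    )
    if df.shape[1] != len(expected_header):
        raise ValidationError(
            f"{path}: expected {len(expected_header)} columns "
            f"({', '.join(expected_header)}), found {df.shape[1]}"
        )
    df.columns = expected_header
    return df


def read_target_annotations(path: PathLike) -> TargetAnnotation:
    """Read a two-column TSV (compound_id, target_gene) into a target map.

    Multiple rows per compound aggregate to a target *set*.  Rows with an
    empty target field are rejected; the count of rejected rows is logged.
    """
    df = _read_tsv(path, ["compound_id", "target_gene"])
    rejected = int((df["target_gene"].str.strip() == "").sum())
    if rejected:
        log.warning(
            "read_target_annotations: rejected %d row(s) with empty target "
            "field in %s", rejected, path,
        )
    df = df[df["target_gene"].str.strip() != ""]
    mapping: dict[str, set[str]] = {}
    for cid, gene in zip(df["compound_id"], df["target_gene"]):
        mapping.setdefault(cid, set()).add(gene.strip())
    return TargetAnnotation({c: frozenset(g) for c, g in mapping.items()})


def read_intervention_list(path: PathLike) -> InterventionList:
    """Read a three-column TSV (intervention_id, gene, direction).

    Direction must be ``knockdown`` or ``overexpression``; anything else is a
    validation error, as is a duplicated intervention_id.
    """
    df = _read_tsv(path, ["intervention_id", "gene", "direction"])
    rows = []
    for _, rec in df.iterrows():
        d = PertType.parse(rec["direction"])
        if d is PertType.COMPOUND:
            raise ValidationError(
                f"{path}: intervention {rec['intervention_id']!r}: direction "
                "must be knockdown or overexpression"
            )
        rows.append(Intervention(rec["intervention_id"], rec["gene"], d))
    return InterventionList(tuple(rows))


def write_target_annotations(ann: TargetAnnotation, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound_id\ttarget_gene\n")
        for cid in sorted(ann.mapping):
            for gene in sorted(ann.mapping[cid]):
                fh.write(f"{cid}\t{gene}\n")
    return path


def write_intervention_list(interventions: InterventionList, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("intervention_id\tgene\tdirection\n")
        for row in interventions:
            fh.write(f"{row.intervention_id}\t{row.gene}\t{row.direction.value}\n")
    return path
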