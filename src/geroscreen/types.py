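"""Core data model shared by every stage of the screen.

A *signature* is a per-gene differential-expression z-score vector measured
for one perturbagen (a compound treatment, a gene knockdown, or a gene
overexpression) in one cell line.  A :class:`SignatureSet` bundles many such
signatures over a common :class:`GeneSpace` and is the screen's reference
universe ("touchstone").  Gene identifiers are opaque strings; no
symbol/Entrez translation is attempted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "PertType",
    "GeneSpace",
    "Perturbagen",
    "SignatureSet",
    "TargetAnnotation",
    "Intervention",
    "InterventionList",
]


class ValidationError(ValueError):
    """Raised when an input violates the data-model contracts."""


class PertType(str, enum.Enum):
    """The three perturbagen classes profiled in the reference universe."""

    COMPOUND = "compound"
    KNOCKDOWN = "knockdown"
    OVEREXPRESSION = "overexpression"

    @classmethod
    def parse(cls, value: "str | PertType") -> "PertType":
        if isinstance(value, PertType):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(
                f"unknown perturbagen type {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class GeneSpace:
    """An ordered universe of unique gene identifiers."""

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValidationError(f"duplicate gene identifier {dup!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: object) -> bool:
        return gene in self.index

    def __iter__(self) -> Iterator[str]:
        return iter(self.gene_ids)

    @property
    def index(self) -> Mapping[str, int]:
        """gene id -> position, built lazily and cached."""
        cached = self.__dict__.get("_index")
        if cached is None:
            cached = {g: i for i, g in enumerate(self.gene_ids)}
            self.__dict__["_index"] = cached
        return cached


@dataclass(frozen=True)
class Perturbagen:
    """One profiled perturbation in one cell line.

    Knockdown/overexpression perturbagens carry the perturbed gene in
    ``target_gene``; for compounds it is unset (drug targets live in
    :class:`TargetAnnotation` instead).
    """

    pert_id: str
    pert_type: PertType
    cell_line: str = "default"
    target_gene: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pert_type", PertType.parse(self.pert_type))
        if self.pert_type is not PertType.COMPOUND and not self.target_gene:
            raise ValidationError(
                f"{self.pert_type.value} perturbagen {self.pert_id!r} must "
                "declare target_gene (the perturbed gene)"
            )


@dataclass
class SignatureSet:
    """genes x perturbagens matrix of signature z-scores with metadata.

    Invariants enforced at construction: matrix dimensions match the gene
    space and perturbagen list, all values are finite, and
    (pert_id, cell_line) pairs are unique.
    """

    gene_space: GeneSpace
    perturbagens: tuple[Perturbagen, ...]
    values: np.ndarray
    gene_annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.perturbagens = tuple(self.perturbagens)
        self.values = np.asarray(self.values, dtype=float)
        n_genes, n_perts = len(self.gene_space), len(self.perturbagens)
        if self.values.shape != (n_genes, n_perts):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n_genes} genes x {n_perts} perturbagens"
            )
        if self.values.size and not np.isfinite(self.values).all():
            raise ValidationError("signature values must all be finite")
        keys = [(p.pert_id, p.cell_line) for p in self.perturbagens]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValidationError(f"duplicate (pert_id, cell_line) pair {dup!r}")
        if self.gene_annotations is not None:
            if list(self.gene_annotations.index) != list(self.gene_space.gene_ids):
                raise ValidationError(
                    "gene_annotations index must equal the gene space order"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_space)

    @property
    def n_perturbagens(self) -> int:
        return len(self.perturbagens)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.perturbagens:
            if p.cell_line not in out:
                out.append(p.cell_line)
        return tuple(out)

    def column_index(self, pert_id: str, cell_line: str) -> int:
        for j, p in enumerate(self.perturbagens):
            if p.pert_id == pert_id and p.cell_line == cell_line:
                return j
        raise KeyError(f"no signature for ({pert_id!r}, {cell_line!r})")

    def columns(
        self,
        pert_type: "PertType | str | None" = None,
        cell_line: Optional[str] = None,
    ) -> list[int]:
        """Indices of perturbagen columns matching the given filters."""
        want = PertType.parse(pert_type) if pert_type is not None else None
        return [
            j
            for j, p in enumerate(self.perturbagens)
            if (want is None or p.pert_type is want)
            and (cell_line is None or p.cell_line == cell_line)
        ]

    def profile(self, column: int) -> np.ndarray:
        return self.values[:, column]


@dataclass(frozen=True)
class TargetAnnotation:
    """Drug -> known target gene(s).  Compounds may be unannotated (absent)."""

    mapping: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for cid, genes in dict(self.mapping).items():
            genes = frozenset(str(g) for g in genes if str(g))
            if not genes:
                raise ValidationError(
                    f"compound {cid!r} annotated with an empty target set"
                )
            clean[str(cid)] = genes
        object.__setattr__(self, "mapping", clean)

    def targets(self, compound_id: str) -> frozenset[str]:
        return self.mapping.get(compound_id, frozenset())

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, compound_id: object) -> bool:
        return compound_id in self.mapping

    def items(self):
        return self.mapping.items()


@dataclass(frozen=True)
class Intervention:
    """One genetic longevity intervention: a gene perturbed in a direction."""

    intervention_id: str
    gene: str
    direction: PertType

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", PertType.parse(self.direction))
        if self.direction is PertType.COMPOUND:
            raise ValidationError(
                f"intervention {self.intervention_id!r}: direction must be "
                "knockdown or overexpression"
            )


@dataclass(frozen=True)
class InterventionList:
    rows: tuple[Intervention, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        ids = [r.intervention_id for r in self.rows]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate intervention_id {dup!r}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[Intervention]:
        return iter(self.rows)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, "str | PertType"]]
    ) -> "InterventionList":
        return cls(tuple(Intervention(i, g, d) for i, g, d in records))
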