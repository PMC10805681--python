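"""Differential expression and the multi-tissue consensus overlap.

Counts from a treated-vs-control contrast in each tissue pass through the
stated quantification rules — keep genes with more than ``min_count`` reads
in at least ``min_samples`` samples, transform to log2 counts-per-million —
and a per-gene Welch t-test with Benjamini-Hochberg correction.  The Welch
test on logCPM is a deliberately simple stand-in for a moderated linear
model: this module's contribution is the filtering and consensus logic,
and externally produced DE tables are accepted just the same.

The consensus step splits each tissue's significant genes by fold-change
direction, intersects across the three tissues, tabulates every non-empty
tissue combination (the upset counts), and emits a genes x tissues heatmap
matrix of log fold changes clamped to +/-2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSpace, ValidationError

__all__ = [
    "CountMatrix",
    "DEResult",
    "ConsensusResult",
    "filter_genes",
    "log_cpm",
    "simple_de",
    "bh_adjust",
    "consensus_overlap",
    "cap_logfc",
    "read_counts",
    "read_de_table",
    "write_de_table",
]

PathLike = Union[str, Path]

DE_COLUMNS = ["gene", "logFC", "pvalue", "adj_pvalue"]


@dataclass
class CountMatrix:
    """Non-negative integer read counts (genes x samples) with sample labels.

    ``sample_info`` is indexed by sample id and carries at least a ``group``
    column (e.g. treated/control); a ``tissue`` column is conventional.
    """

    counts: pd.DataFrame
    sample_info: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size:
            if (vals < 0).any():
                raise ValidationError("counts must be non-negative")
            if not np.equal(np.mod(vals, 1), 0).all():
                raise ValidationError("counts must be integral")
        if list(self.counts.columns) != list(self.sample_info.index):
            raise ValidationError(
                "count matrix columns must match sample_info index (same order)"
            )
        if "group" not in self.sample_info.columns:
            raise ValidationError("sample_info must carry a 'group' column")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in count matrix")

    @property
    def gene_space(self) -> GeneSpace:
        return GeneSpace(tuple(self.counts.index.astype(str)))


@dataclass
class DEResult:
    """Per-gene effect size and (adjusted) p-values for one tissue contrast."""

    table: pd.DataFrame  # DE_COLUMNS, one row per gene
    tissue: str

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"DE table missing columns {missing}")


@dataclass
class ConsensusResult:
    shared_up: frozenset[str]
    shared_down: frozenset[str]
    upset: pd.DataFrame      # direction, tissues (+-joined combo), n_genes
    heatmap: pd.DataFrame    # shared genes x tissues, capped logFC
    per_tissue: dict = field(default_factory=dict)  # tissue -> {"up": set, "down": set}


def filter_genes(
    counts: CountMatrix, min_count: int = 2, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with more than ``min_count`` reads in >= ``min_samples`` samples.

    Both comparisons follow the stated rule exactly: the per-sample test is
    strict (count > min_count) and the sample tally is inclusive.
    """
    if min_count < 0 or min_samples < 0:
        raise ValidationError("filter thresholds must be >= 0")
    keep = (counts.counts > min_count).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError(
            "gene filter removed every gene; review min_count/min_samples"
        )
    return CountMatrix(counts=counts.counts.loc[keep], sample_info=counts.sample_info)


def log_cpm(counts: CountMatrix, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudo-count.

    logCPM[g, s] = log2((count + prior) / (library_size + 2 * prior) * 1e6).
    """
    lib = counts.counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValidationError("zero library size; cannot compute logCPM")
    mat = counts.counts.to_numpy(dtype=float)
    out = np.log2((mat + prior) / (lib + 2.0 * prior) * 1e6)
    return pd.DataFrame(out, index=counts.counts.index, columns=counts.counts.columns)


def simple_de(
    logcpm: pd.DataFrame,
    groups: Sequence[str],
    treated: str,
    control: str,
    tissue: str = "",
) -> DEResult:
    """Per-gene Welch t-test on logCPM values.

    logFC is the treated-minus-control group-mean difference of logCPM
    (i.e. an approximate log2 fold change); p-values come from the t
    distribution with Welch-Satterthwaite degrees of freedom and are
    BH-adjusted.  Genes with zero variance in both groups get p = 1 when
    the means agree (no evidence) and p = 0 when they differ exactly.
    """
    groups = np.asarray(list(groups))
    if len(groups) != logcpm.shape[1]:
        raise ValidationError("group labels must match logCPM columns")
    a = logcpm.loc[:, groups == treated].to_numpy(dtype=float)
    b = logcpm.loc[:, groups == control].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need >= 2 samples per group for the Welch test")
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    pvals[degenerate & (lfc == 0)] = 1.0
    pvals[degenerate & (lfc != 0)] = 0.0
    pvals = np.nan_to_num(pvals, nan=1.0)
    table = pd.DataFrame(
        {
            "gene": logcpm.index.astype(str),
            "logFC": lfc,
            "pvalue": pvals,
            "adj_pvalue": bh_adjust(pvals),
        }
    )
    return DEResult(table=table, tissue=tissue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min over j >= i (ascending order) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


Threshold = tuple[str, float]  # (column: "pvalue" | "adj_pvalue", cut)


def _significant(result: DEResult, threshold: Threshold) -> tuple[set, set]:
    column, cut = threshold
    if column not in ("pvalue", "adj_pvalue"):
        raise ValidationError(
            f"threshold column must be 'pvalue' or 'adj_pvalue', got {column!r}"
        )
    t = result.table
    passing = t[column] < cut  # strict, matching "p value < 0.05"
    up = set(t.loc[passing & (t["logFC"] > 0), "gene"])
    down = set(t.loc[passing & (t["logFC"] < 0), "gene"])
    return up, down


def consensus_overlap(
    results: Sequence[DEResult],
    thresholds: Mapping[str, Threshold],
    cap: float = 2.0,
) -> ConsensusResult:
    """Direction-split three-way overlap of significant genes across tissues.

    Per tissue, significant genes split into up (logFC > 0) and down
    (logFC < 0) under that tissue's own threshold (raw or adjusted p,
    strict).  ``shared_up``/``shared_down`` are the three-way intersections;
    the upset table counts genes falling in each of the 7 non-empty tissue
    combinations per direction (exact membership, so a gene up in two
    tissues and down in the third lands in the two-tissue cell of "up").
    The heatmap holds the shared genes' logFC per tissue, clamped to
    [-cap, cap].

    Tables need not list identical genes: each tissue's expression filter
    runs before testing, so a gene absent from one table was untestable
    there and simply cannot be significant in that tissue.  Shared genes
    are, by construction, present in all three tables.
    """
    if len(results) != 3:
        raise ValidationError("consensus requires exactly three tissue contrasts")
    tissues = [r.tissue for r in results]
    if len(set(tissues)) != 3:
        raise ValidationError("tissue labels must be distinct")
    for t in tissues:
        if t not in thresholds:
            raise ValidationError(f"no threshold given for tissue {t!r}")
    for r in results:
        if r.table.empty:
            raise ValidationError(f"DE table for tissue {r.tissue!r} is empty")

    membership: dict[str, dict[str, set]] = {"up": {}, "down": {}}
    for r in results:
        up, down = _significant(r, thresholds[r.tissue])
        membership["up"][r.tissue] = up
        membership["down"][r.tissue] = down

    shared_up = frozenset(set.intersection(*(membership["up"][t] for t in tissues)))
    shared_down = frozenset(set.intersection(*(membership["down"][t] for t in tissues)))

    upset_rows = []
    for direction in ("up", "down"):
        sets = membership[direction]
        for r in range(1, 4):
            for combo in itertools.combinations(tissues, r):
                inside = set.intersection(*(sets[t] for t in combo))
                outside = set.union(
                    *(sets[t] for t in tissues if t not in combo), set()
                )
                upset_rows.append(
                    dict(
                        direction=direction,
                        tissues="+".join(combo),
                        n_genes=len(inside - outside),
                    )
                )
    upset = pd.DataFrame.from_records(upset_rows)

    shared_genes = sorted(shared_up) + sorted(shared_down)
    lfc = pd.DataFrame(index=shared_genes, columns=tissues, dtype=float)
    for r in results:
        series = r.table.set_index("gene")["logFC"]
        lfc[r.tissue] = series.reindex(shared_genes)
    heatmap = cap_logfc(lfc, cap=cap)

    return ConsensusResult(
        shared_up=shared_up,
        shared_down=shared_down,
        upset=upset,
        heatmap=heatmap,
        per_tissue={
            t: {"up": membership["up"][t], "down": membership["down"][t]}
            for t in tissues
        },
    )


def cap_logfc(matrix: pd.DataFrame, cap: float = 2.0) -> pd.DataFrame:
    """Clamp log fold changes elementwise to [-cap, cap] (display contract)."""
    if cap <= 0:
        raise ValidationError("cap must be positive")
    return matrix.clip(lower=-cap, upper=cap)


def read_counts(counts_path: PathLike, samples_path: PathLike) -> CountMatrix:
    """Read a genes x samples counts TSV plus its sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    info = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
    return CountMatrix(counts=counts, sample_info=info.loc[counts.columns])


def read_de_table(path: PathLike, tissue: str) -> DEResult:
    table = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return DEResult(table=table, tissue=tissue)


def write_de_table(result: DEResult, path: PathLike) -> Path:
    path = Path(path)
    result.table[DE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path
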