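"""The in-silico screen: query building, scoring, filtering, ranking.

The screen asks, for each genetic longevity intervention, which compounds'
transcriptional signatures mimic it.  Stages, in order:

* ``build_query`` — derive an up/down query gene-set pair per cell line from
  the intervention's own perturbation signature (top-k / bottom-k genes).
* ``score_compounds`` — run the full connectivity chain for every
  (query, perturbagen) pair sharing a cell line and consolidate per-line tau
  values into one summary score per pair.
* ``apply_cutoff`` — a compound is a hit candidate when its summary score
  strictly exceeds the cutoff (default 90).
* ``target_concordance_filter`` — keep a candidate only if knocking down one
  of the compound's annotated targets also scores above the cutoff against
  the same intervention; unannotated compounds never survive.
* ``tally_and_rank`` — count the interventions each compound mimics and
  dense-rank compounds by that tally (ties share a rank).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    QueryGeneSets,
    RankedProfile,
    enrichment_score,
    rank_profile,
    summarize_cell_lines,
    wtcs,
)
from .types import (
    Intervention,
    InterventionList,
    PertType,
    SignatureSet,
    TargetAnnotation,
    ValidationError,
)

__all__ = [
    "MissingSignatureError",
    "QuerySpec",
    "ScoreTable",
    "HitMatrix",
    "build_query",
    "build_queries",
    "build_self_query",
    "score_compounds",
    "apply_cutoff",
    "target_concordance_filter",
    "tally_and_rank",
    "run_screen",
    "ScreenResult",
]

log = logging.getLogger(__name__)

DETAIL_COLUMNS = [
    "query_id", "pert_id", "pert_type", "target_gene", "cell_line",
    "es_up", "es_down", "wtcs", "ncs", "tau",
]
SUMMARY_COLUMNS = ["query_id", "pert_id", "pert_type", "target_gene", "summary_score"]


class MissingSignatureError(ValidationError):
    """The intervention's perturbagen is absent from the signature set."""


@dataclass(frozen=True)
class QuerySpec:
    """Per-cell-line up/down query sets for one intervention."""

    intervention_id: str
    k: int
    sets: dict  # cell_line -> QueryGeneSets

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("query size k must be >= 1")
        if not self.sets:
            raise ValidationError(
                f"query {self.intervention_id!r} covers no cell lines"
            )

    def reversed(self) -> "QuerySpec":
        return QuerySpec(
            intervention_id=self.intervention_id,
            k=self.k,
            sets={cl: s.reversed() for cl, s in self.sets.items()},
        )


@dataclass
class ScoreTable:
    """Long-form per-cell-line scores plus the consolidated summary table."""

    detail: pd.DataFrame   # DETAIL_COLUMNS
    summary: pd.DataFrame  # SUMMARY_COLUMNS


@dataclass
class HitMatrix:
    """interventions x compounds boolean hits with per-cell provenance."""

    matrix: pd.DataFrame      # bool, index=query ids, columns=compound ids
    provenance: pd.DataFrame  # per candidate: scores and filter decisions


def _sets_from_ranking(prof: RankedProfile, k: int) -> QueryGeneSets:
    if 2 * k > len(prof):
        raise ValidationError(
            f"query size k={k} too large for {len(prof)} genes (need 2k <= n)"
        )
    return QueryGeneSets(
        up=frozenset(prof.gene_ids[:k]), down=frozenset(prof.gene_ids[-k:])
    )


def build_query(
    sigset: SignatureSet,
    intervention: Intervention,
    k: int,
    mode: str = "per_cell_line",
) -> QuerySpec:
    """Derive an intervention's query sets from its own signature.

    ``per_cell_line`` ranks each available cell line's signature separately;
    ``consensus`` ranks the mean signature across the available cell lines
    and applies the same sets to each of them.  Raises
    :class:`MissingSignatureError` if the intervention's perturbagen (gene +
    direction) is profiled in no cell line, mirroring the attrition between
    curated interventions and those with usable signatures.
    """
    cols = [
        j
        for j, p in enumerate(sigset.perturbagens)
        if p.pert_type is intervention.direction
        and p.target_gene == intervention.gene
    ]
    if not cols:
        raise MissingSignatureError(
            f"no {intervention.direction.value} signature for gene "
            f"{intervention.gene!r} (intervention {intervention.intervention_id!r})"
        )
    if mode == "per_cell_line":
        sets = {
            sigset.perturbagens[j].cell_line: _sets_from_ranking(
                rank_profile(sigset, j), k
            )
            for j in cols
        }
    elif mode == "consensus":
        mean_z = sigset.values[:, cols].mean(axis=1)
        genes = np.asarray(sigset.gene_space.gene_ids, dtype=object)
        order = np.lexsort((genes, -mean_z))
        prof = RankedProfile(gene_ids=genes[order], z=mean_z[order])
        shared = _sets_from_ranking(prof, k)
        sets = {sigset.perturbagens[j].cell_line: shared for j in cols}
    else:
        raise ValidationError(f"unknown query mode {mode!r}")
    return QuerySpec(intervention_id=intervention.intervention_id, k=k, sets=sets)


def build_queries(
    sigset: SignatureSet,
    interventions: InterventionList,
    k: int,
    mode: str = "per_cell_line",
) -> tuple[list[QuerySpec], list[str]]:
    """Build queries for every intervention with an available signature.

    Returns (queries, ids of interventions excluded for lack of a signature).
    """
    queries: list[QuerySpec] = []
    missing: list[str] = []
    for intervention in interventions:
        try:
            queries.append(build_query(sigset, intervention, k, mode=mode))
        except MissingSignatureError:
            log.info(
                "intervention %s: no signature available; excluded",
                intervention.intervention_id,
            )
            missing.append(intervention.intervention_id)
    return queries, missing


def build_self_query(
    sigset: SignatureSet, pert_id: str, k: int, query_id: Optional[str] = None
) -> QuerySpec:
    """Query a perturbagen with its own top-k/bottom-k genes per cell line."""
    cols = [
        j for j, p in enumerate(sigset.perturbagens) if p.pert_id == pert_id
    ]
    if not cols:
        raise MissingSignatureError(f"perturbagen {pert_id!r} not in signature set")
    sets = {
        sigset.perturbagens[j].cell_line: _sets_from_ranking(
            rank_profile(sigset, j), k
        )
        for j in cols
    }
    return QuerySpec(intervention_id=query_id or f"self:{pert_id}", k=k, sets=sets)


def _group_ncs_tau(w: np.ndarray, inclusive: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ncs + tau within one (cell line, perturbagen type) group."""
    ncs_vals = np.zeros_like(w)
    pos, neg = w > 0, w < 0
    if pos.any():
        ncs_vals[pos] = w[pos] / w[pos].mean()
    if neg.any():
        ncs_vals[neg] = w[neg] / (-w[neg]).mean()
    taus = np.zeros_like(w)
    side = "right" if inclusive else "left"
    for mask, sign in ((pos, 1.0), (neg, -1.0)):
        if mask.any():
            mags = np.abs(ncs_vals[mask])
            ranks = np.searchsorted(np.sort(mags), mags, side=side)
            taus[mask] = sign * 100.0 * ranks / mags.size
    return ncs_vals, taus


def score_compounds(
    queries: Sequence[QuerySpec],
    sigset: SignatureSet,
    pert_types: Sequence[str] = ("compound", "knockdown"),
    percentiles: tuple[float, float] = (33.0, 67.0),
    tau_inclusive: bool = True,
) -> ScoreTable:
    """Score every (query, perturbagen) pair sharing a cell line.

    Produces the per-cell-line connectivity chain (es_up, es_down, wtcs,
    ncs, tau) and one consolidated summary score per (query, perturbagen).
    Normalization and percentile references are stratified by cell line and
    perturbagen type, so compounds and knockdowns are scaled within their
    own class.  Pairs with no shared cell line are dropped.
    """
    if not queries:
        raise ValidationError("score_compounds: no queries given")
    wanted = tuple(PertType.parse(t) for t in pert_types)
    needed_lines = {cl for q in queries for cl in q.sets}
    columns: dict[str, list[int]] = {cl: [] for cl in needed_lines}
    for j, p in enumerate(sigset.perturbagens):
        if p.pert_type in wanted and p.cell_line in columns:
            columns[p.cell_line].append(j)
    profiles: dict[int, RankedProfile] = {}

    detail_frames: list[pd.DataFrame] = []
    summary_rows: list[dict] = []
    for query in queries:
        recs: list[dict] = []
        for cell_line in sorted(query.sets):
            sets = query.sets[cell_line]
            for j in columns.get(cell_line, ()):
                prof = profiles.get(j)
                if prof is None:
                    prof = profiles[j] = rank_profile(sigset, j)
                es_up = enrichment_score(prof, sets.up, weighted=True)
                es_down = enrichment_score(prof, sets.down, weighted=True)
                p = sigset.perturbagens[j]
                recs.append(
                    dict(
                        query_id=query.intervention_id,
                        pert_id=p.pert_id,
                        pert_type=p.pert_type.value,
                        target_gene=p.target_gene or "",
                        cell_line=cell_line,
                        es_up=es_up,
                        es_down=es_down,
                        wtcs=wtcs(es_up, es_down),
                    )
                )
        if not recs:
            continue
        df = pd.DataFrame.from_records(recs)
        df["ncs"] = 0.0
        df["tau"] = 0.0
        for (_, _), idx in df.groupby(["cell_line", "pert_type"], sort=True).groups.items():
            w = df.loc[idx, "wtcs"].to_numpy(dtype=float)
            ncs_vals, taus = _group_ncs_tau(w, tau_inclusive)
            df.loc[idx, "ncs"] = ncs_vals
            df.loc[idx, "tau"] = taus
        detail_frames.append(df[DETAIL_COLUMNS])
        for (pid, ptype, tgene), sub in df.groupby(
            ["pert_id", "pert_type", "target_gene"], sort=True
        ):
            summary_rows.append(
                dict(
                    query_id=query.intervention_id,
                    pert_id=pid,
                    pert_type=ptype,
                    target_gene=tgene,
                    summary_score=summarize_cell_lines(
                        sub["tau"].to_numpy(), percentiles
                    ),
                )
            )
    detail = (
        pd.concat(detail_frames, ignore_index=True)
        if detail_frames
        else pd.DataFrame(columns=DETAIL_COLUMNS)
    )
    summary = pd.DataFrame.from_records(summary_rows, columns=SUMMARY_COLUMNS)
    return ScoreTable(detail=detail, summary=summary)


def apply_cutoff(summary: pd.DataFrame, cutoff: float = 90.0) -> pd.DataFrame:
    """Flag hit candidates: summary score strictly greater than the cutoff.

    The inequality is strict, so a boundary score exactly equal to the
    cutoff is *not* a candidate.
    """
    if not -100.0 <= cutoff <= 100.0:
        raise ValidationError(f"cutoff {cutoff} outside [-100, 100]")
    out = summary.copy()
    out["candidate"] = out["summary_score"] > cutoff
    return out


def target_concordance_filter(
    candidates: pd.DataFrame,
    annotations: TargetAnnotation,
    knockdown_summary: pd.DataFrame,
    cutoff: float = 90.0,
) -> HitMatrix:
    """Keep candidates whose annotated target's knockdown also passes.

    A candidate (intervention I, compound c) survives iff some annotated
    target gene of c has a knockdown perturbagen whose summary score against
    I's query strictly exceeds the cutoff.  Any passing target suffices for
    multi-target drugs (each hit's matched targets are recorded in the
    provenance).  Unannotated compounds never survive.
    """
    if len(annotations) == 0:
        warnings.warn("target_concordance_filter: empty annotation table; no hits")
    cand = candidates
    if "pert_type" in cand.columns:
        cand = cand[cand["pert_type"] == PertType.COMPOUND.value]
    kd = knockdown_summary
    if "pert_type" in kd.columns:
        kd = kd[kd["pert_type"] == PertType.KNOCKDOWN.value]
    kd_pass: dict[tuple[str, str], bool] = {}
    for _, row in kd.iterrows():
        if row["target_gene"] and row["summary_score"] > cutoff:
            kd_pass[(row["query_id"], row["target_gene"])] = True

    prov_rows: list[dict] = []
    for _, row in cand.iterrows():
        qid, cid = row["query_id"], row["pert_id"]
        matched = sorted(
            g for g in annotations.targets(cid) if kd_pass.get((qid, g))
        )
        is_cand = bool(row["candidate"])
        prov_rows.append(
            dict(
                query_id=qid,
                pert_id=cid,
                summary_score=row["summary_score"],
                candidate=is_cand,
                target_concordant=bool(matched),
                hit=is_cand and bool(matched),
                matched_targets=";".join(matched),
            )
        )
    provenance = pd.DataFrame.from_records(
        prov_rows,
        columns=[
            "query_id", "pert_id", "summary_score", "candidate",
            "target_concordant", "hit", "matched_targets",
        ],
    )
    if provenance.empty:
        matrix = pd.DataFrame(dtype=bool)
    else:
        matrix = (
            provenance.pivot_table(
                index="query_id", columns="pert_id", values="hit",
                aggfunc="any", fill_value=False,
            )
            .astype(bool)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
    return HitMatrix(matrix=matrix, provenance=provenance)


def tally_and_rank(hits: HitMatrix, include_zero: bool = False) -> pd.DataFrame:
    """Tally interventions mimicked per compound; dense-rank descending.

    Equal tallies share a rank and the next distinct tally takes the next
    integer (dense ranking).  Compounds mimicking nothing are omitted unless
    ``include_zero`` is set.
    """
    if hits.matrix.empty:
        return pd.DataFrame(columns=["pert_id", "tally", "rank"])
    tallies = hits.matrix.sum(axis=0).astype(int)
    if not include_zero:
        tallies = tallies[tallies > 0]
    if tallies.empty:
        return pd.DataFrame(columns=["pert_id", "tally", "rank"])
    out = tallies.rename("tally").rename_axis("pert_id").reset_index()
    out["rank"] = (
        out["tally"].rank(method="dense", ascending=False).astype(int)
    )
    return out.sort_values(["rank", "pert_id"], kind="stable").reset_index(drop=True)


@dataclass
class ScreenResult:
    """Everything the screen produced, stage by stage."""

    queries: list[QuerySpec]
    missing_interventions: list[str]
    scores: ScoreTable
    candidates: pd.DataFrame
    hits: HitMatrix
    ranking: pd.DataFrame
    counts: dict = field(default_factory=dict)


def run_screen(
    sigset: SignatureSet,
    interventions: InterventionList,
    annotations: TargetAnnotation,
    cutoff: float = 90.0,
    k: int = 50,
    query_mode: str = "per_cell_line",
    percentiles: tuple[float, float] = (33.0, 67.0),
    tau_inclusive: bool = True,
    include_zero: bool = False,
) -> ScreenResult:
    """Execute the whole screen and report per-stage attrition counts."""
    queries, missing = build_queries(sigset, interventions, k, mode=query_mode)
    if not queries:
        raise ValidationError("no intervention has an available signature")
    scores = score_compounds(
        queries,
        sigset,
        pert_types=("compound", "knockdown"),
        percentiles=percentiles,
        tau_inclusive=tau_inclusive,
    )
    compound_summary = scores.summary[
        scores.summary["pert_type"] == PertType.COMPOUND.value
    ]
    candidates = apply_cutoff(compound_summary, cutoff)
    hits = target_concordance_filter(candidates, annotations, scores.summary, cutoff)
    ranking = tally_and_rank(hits, include_zero=include_zero)
    counts = {
        "interventions_listed": len(interventions),
        "interventions_with_signatures": len(queries),
        "compounds_scored": int(compound_summary["pert_id"].nunique()),
        "candidate_pairs": int(candidates["candidate"].sum()),
        "hit_pairs": int(hits.provenance["hit"].sum()) if not hits.provenance.empty else 0,
        "compounds_ranked": int(len(ranking)),
    }
    for stage, n in counts.items():
        log.info("screen: %s = %d", stage, n)
    return ScreenResult(
        queries=queries,
        missing_interventions=missing,
        scores=scores,
        candidates=candidates,
        hits=hits,
        ranking=ranking,
        counts=counts,
    )
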