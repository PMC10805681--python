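"""Signature-query similarity: the weighted-KS connectivity chain.

The chain turns one signature (per-gene z-scores for a perturbagen in one
cell line) and one bidirectional query (an up and a down gene set) into a
summary score on the [-100, 100] scale used for screening:

1. ``enrichment_score`` — a GSEA-style running-sum statistic.  Walking down
   the z-ranked gene list, hitting a query gene adds weight proportional to
   |z| (or 1/|set| unweighted) and missing one subtracts 1/(N - |set|); the
   score is the running sum's extremum of largest magnitude, in [-1, 1].
2. ``wtcs`` — the bidirectional combination (es_up - es_down)/2, forced to 0
   when the two enrichment scores share a sign (an incoherent query).
3. ``ncs`` — wtcs normalized by the mean same-sign wtcs within one cell line
   and perturbagen type, making magnitudes comparable across cell lines.
4. ``tau`` — signed percentile of |ncs| against the same-sign touchstone
   magnitudes (same cell line and perturbagen type); a strict same-sign
   maximum maps to +/-100.
5. ``summarize_cell_lines`` — per-compound consolidation across cell lines:
   the 67th/33rd percentile of the per-line tau values, whichever is larger
   in magnitude.

A score of 100 means the perturbagen's transcriptional response mimics the
query signature as strongly as anything in the touchstone; -100 means it
opposes it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Collection, Iterable, Optional, Sequence

import numpy as np

from .types import SignatureSet, ValidationError

__all__ = [
    "RankedProfile",
    "QueryGeneSets",
    "ConnectivityRecord",
    "rank_profile",
    "enrichment_score",
    "wtcs",
    "ncs",
    "tau",
    "summarize_cell_lines",
]

log = logging.getLogger(__name__)


@dataclass
class RankedProfile:
    """A signature's genes ordered by descending z-score.

    Ties are broken lexicographically by gene id so the order is
    deterministic across platforms.
    """

    gene_ids: np.ndarray  # ordered, descending z
    z: np.ndarray         # aligned z values
    _pos: Optional[dict] = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def positions(self) -> dict:
        """gene id -> rank position (0-based), cached."""
        if self._pos is None:
            self._pos = {g: i for i, g in enumerate(self.gene_ids)}
        return self._pos


@dataclass(frozen=True)
class QueryGeneSets:
    """The up/down gene-set pair forming one bidirectional query."""

    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if not self.up or not self.down:
            raise ValidationError("both query gene sets must be non-empty")
        if self.up & self.down:
            raise ValidationError("up and down query sets must be disjoint")

    def reversed(self) -> "QueryGeneSets":
        return QueryGeneSets(up=self.down, down=self.up)


@dataclass(frozen=True)
class ConnectivityRecord:
    """The full per-cell-line score chain for one (query, perturbagen) pair."""

    es_up: float
    es_down: float
    wtcs: float
    ncs: float
    tau: float
    cell_line: str


def rank_profile(sigset: SignatureSet, column: int) -> RankedProfile:
    """Order one signature's genes by descending z, ties by gene id."""
    z = sigset.profile(column)
    if not np.isfinite(z).all():
        raise ValidationError(
            f"signature column {column} contains non-finite values"
        )
    genes = np.asarray(sigset.gene_space.gene_ids, dtype=object)
    order = np.lexsort((genes, -z))  # primary: z descending, secondary: id
    return RankedProfile(gene_ids=genes[order], z=z[order])


def _es_from_hits(positions: np.ndarray, hit_weights: np.ndarray, n: int) -> float:
    """Running-sum extremum given sorted 0-based hit rank positions.

    ``hit_weights`` must sum to 1.  Between hits the walk only decreases, so
    the global extremes are attained just before a hit (minima) or just
    after one (maxima); only those 2k points are evaluated.
    """
    k = len(positions)
    miss = 1.0 / (n - k)
    before = np.concatenate(([0.0], np.cumsum(hit_weights)[:-1]))
    before = before - (positions - np.arange(k)) * miss
    after = before + hit_weights
    lo = before.min()
    hi = after.max()
    # |hi| vs |lo|; ties (to 1e-12, absorbing summation-order noise on exact
    # rational ties) resolve to the positive extremum
    return float(hi) if abs(hi) >= abs(lo) - 1e-12 else float(lo)


def enrichment_score(
    profile: RankedProfile,
    gene_set: Collection[str],
    weighted: bool = True,
) -> float:
    """Signed KS enrichment of ``gene_set`` in a ranked profile, in [-1, 1].

    Weighted mode deposits hit mass proportional to |z| (exponent 1);
    unweighted mode deposits 1/|set| per hit.  A profile whose query hits all
    carry zero |z| has no directional evidence and scores 0.
    """
    genes = set(gene_set)
    n = len(profile)
    if not genes:
        raise ValidationError("query gene set is empty")
    if len(genes) >= n:
        raise ValidationError("query gene set must be a strict subset of the gene space")
    pos_map = profile.positions
    try:
        positions = np.sort(np.array([pos_map[g] for g in genes]))
    except KeyError as exc:
        raise ValidationError(f"query gene {exc.args[0]!r} not in gene space") from None
    k = len(positions)
    if weighted:
        w = np.abs(profile.z[positions])
        total = w.sum()
        if total == 0.0:
            return 0.0
        w = w / total
    else:
        w = np.full(k, 1.0 / k)
    return _es_from_hits(positions, w, n)


def wtcs(es_up: float, es_down: float) -> float:
    """Bidirectional combination of the two enrichment scores.

    Zero when both scores share a sign (the query's up and down sets agree,
    which is incoherent); otherwise (es_up - es_down) / 2.
    """
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def ncs(w: float, reference: Iterable[float]) -> float:
    """Normalize a wtcs value by the mean same-sign wtcs of its reference.

    The reference is the wtcs values of the same cell line and perturbagen
    type (and includes ``w`` itself).  Zero maps to zero; if no same-sign
    reference values exist, returns 0 with a warning.
    """
    if w == 0.0:
        return 0.0
    ref = np.asarray(list(reference), dtype=float)
    same = ref[ref > 0] if w > 0 else -ref[ref < 0]
    if same.size == 0:
        warnings.warn("ncs: no same-sign reference values; returning 0")
        return 0.0
    return float(w / same.mean())


def tau(n: float, reference: Iterable[float], inclusive: bool = True) -> float:
    """Signed percentile of |ncs| against same-sign touchstone magnitudes.

    ``reference`` holds the |ncs| magnitudes of the same sign, cell line and
    perturbagen type, including |n|.  With the default inclusive (<=) tie
    rule a strict same-sign maximum attains exactly +/-100; the exclusive
    (<) rule is available for sensitivity checks.
    """
    if n == 0.0:
        return 0.0
    ref = np.asarray(list(reference), dtype=float)
    if ref.size == 0:
        raise ValidationError("tau: empty reference")
    if inclusive:
        count = int(np.count_nonzero(ref <= abs(n)))
    else:
        count = int(np.count_nonzero(ref < abs(n)))
    return float(np.sign(n) * 100.0 * count / ref.size)


def summarize_cell_lines(
    per_line_taus: Sequence[float],
    percentiles: tuple[float, float] = (33.0, 67.0),
) -> float:
    """Consolidate per-cell-line tau values into one summary score.

    Returns the 67th percentile if its magnitude is at least that of the
    33rd percentile, else the 33rd (linear interpolation).  A constant
    collection returns its constant; a singleton returns itself.
    """
    taus = np.asarray(list(per_line_taus), dtype=float)
    if taus.size == 0:
        raise ValidationError("summarize_cell_lines: empty tau collection")
    lo_p, hi_p = percentiles
    q_lo = float(np.percentile(taus, lo_p))
    q_hi = float(np.percentile(taus, hi_p))
    return q_hi if abs(q_hi) >= abs(q_lo) else q_lo
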