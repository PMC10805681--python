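"""Synthetic inputs with known ground truth.

Two generators stand in for the screen's two external data sources:

* ``simulate_signature_universe`` builds a LINCS-like touchstone — z-score
  signatures for compounds, gene knockdowns and overexpressions across
  multiple cell lines — with mimicry planted as *correlation in z*: a
  planted compound and the interventions it mimics share a latent core
  profile per cell line, mixed with idiosyncratic noise at strength
  ``mimic_strength`` (pairwise correlation alpha; alpha = 1 means identical
  signatures).  Correlation, not gene-set overlap, so recovering the plant
  exercises the full weighted-KS scoring chain.  When concordance is
  planted, the compound's annotated target gets a knockdown signature
  correlated the same way.

* ``simulate_counts`` builds negative-binomial RNA-seq count matrices for a
  treated-vs-control contrast in three tissues (gene means log-normal,
  gene-wise dispersion), with differential expression planted as a
  2**logFC mean ratio — some genes in single tissues, a designated subset
  shared across all three with a common sign.

All randomness flows through one seed, split per sub-generator (and per
cell line / tissue) by named keys, so adding a generator never perturbs the
draws of an existing one.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .de import CountMatrix
from .types import (
    GeneSpace,
    Intervention,
    InterventionList,
    PertType,
    Perturbagen,
    SignatureSet,
    TargetAnnotation,
    ValidationError,
)

__all__ = [
    "SimulationParams",
    "PlantedCompound",
    "PlantedTruth",
    "keyed_rng",
    "simulate_signature_universe",
    "simulate_counts",
]

CORE_CELL_LINES = ("PC3", "VCAP", "A375", "HA1E", "HCC515", "HT29", "MCF7", "HEPG2")


def keyed_rng(seed: int, *names: str) -> np.random.Generator:
    """A generator derived from ``seed`` and a stable key path."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(n.encode("utf-8")) for n in names
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class PlantedCompound:
    """One compound planted to mimic a set of interventions."""

    compound_id: str
    mimics: tuple[str, ...]  # intervention ids, or ("*",) for all
    concordant_target: bool = True


@dataclass
class SimulationParams:
    """Study-condition knobs for both generators.

    Signature-universe defaults emulate the screened touchstone at desk
    scale: 500 genes, 200 background compounds, 25 interventions over the
    eight core cell lines, one planted compound mimicking every
    intervention with a concordant annotated target, mimic strength 0.9.
    Count defaults emulate the three-tissue mouse design: 6 animals per
    group, log-normal gene means, NB dispersion 0.01-0.16, planted |logFC| 2
    with a 50-gene subset shared across kidney, brain and heart.
    """

    # signature universe
    n_genes: int = 500
    n_background_compounds: int = 200
    n_interventions: int = 25
    cell_lines: tuple[str, ...] = CORE_CELL_LINES
    mimic_strength: float = 0.9
    noise_scale: float = 1.0
    planted_compounds: tuple[PlantedCompound, ...] = (
        PlantedCompound("CPD_MIMIC", ("*",), True),
    )
    background_annotated_fraction: float = 0.5
    query_size: int = 25  # used only to validate that queries will fit

    # counts
    n_genes_counts: int = 2000
    samples_per_group: int = 6
    tissues: tuple[str, ...] = ("kidney", "brain", "heart")
    n_shared_up: int = 25
    n_shared_down: int = 25
    n_specific_per_tissue: int = 50
    planted_logfc: float = 2.0
    mean_log_mu: float = float(np.log(100.0))
    mean_log_sigma: float = 1.0
    dispersion_range: tuple[float, float] = (0.01, 0.16)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mimic_strength <= 1.0:
            raise ValidationError("mimic_strength must lie in [0, 1]")
        if self.noise_scale <= 0:
            raise ValidationError("noise_scale must be positive")
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise ValidationError("dispersion_range must be positive and ordered")
        if self.n_genes < 2 * self.query_size:
            raise ValidationError(
                f"n_genes={self.n_genes} must be >= 2 * query_size="
                f"{self.query_size}"
            )
        if self.planted_logfc < 0:
            raise ValidationError("planted_logfc is a magnitude; must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, for recovery tests."""

    planted_hits: dict = field(default_factory=dict)   # compound -> set of intervention ids
    concordant: dict = field(default_factory=dict)     # compound -> bool
    target_genes: dict = field(default_factory=dict)   # compound -> target gene
    tissue_up: dict = field(default_factory=dict)      # tissue -> set of genes
    tissue_down: dict = field(default_factory=dict)
    shared_up: set = field(default_factory=set)
    shared_down: set = field(default_factory=set)

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, (set, frozenset)):
                return sorted(v)
            return v

        payload = {k: {kk: enc(vv) for kk, vv in v.items()} if isinstance(v, dict) else enc(v)
                   for k, v in asdict(self).items()}
        return json.dumps(payload, indent=2, sort_keys=True)


def _mix(core: np.ndarray, alpha: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(core.shape)
    return alpha * core + np.sqrt(1.0 - alpha**2) * sigma * noise


def simulate_signature_universe(
    params: SimulationParams, seed: int
) -> tuple[SignatureSet, TargetAnnotation, InterventionList, PlantedTruth]:
    """Generate a touchstone with planted compound<->intervention mimicry.

    Intervention directions alternate knockdown/overexpression.  Annotated
    drug targets receive their own knockdown perturbagens in every cell
    line (correlated with the planted core when concordance is planted,
    independent noise otherwise).  Deterministic under ``seed``.
    """
    genes = tuple(f"G{i + 1:05d}" for i in range(params.n_genes))
    gene_space = GeneSpace(genes)

    n_int = params.n_interventions
    interventions = InterventionList.from_records(
        [
            (
                f"INT{i + 1:02d}",
                genes[i],
                PertType.KNOCKDOWN if i % 2 == 0 else PertType.OVEREXPRESSION,
            )
            for i in range(n_int)
        ]
    )
    int_ids = [r.intervention_id for r in interventions]
    by_id = {r.intervention_id: r for r in interventions}

    planted = []
    for pc in params.planted_compounds:
        mimics = tuple(int_ids) if pc.mimics == ("*",) else tuple(pc.mimics)
        unknown = set(mimics) - set(int_ids)
        if unknown:
            raise ValidationError(f"planted compound mimics unknown interventions {unknown}")
        planted.append(PlantedCompound(pc.compound_id, mimics, pc.concordant_target))

    # gene identities for planted and background drug targets
    next_gene = n_int
    target_of: dict[str, str] = {}
    for pc in planted:
        target_of[pc.compound_id] = genes[next_gene]
        next_gene += 1
    bg_ids = [f"CPD{i + 1:04d}" for i in range(params.n_background_compounds)]
    rng_ann = keyed_rng(seed, "universe", "annotations")
    n_annot = int(round(params.background_annotated_fraction * len(bg_ids)))
    annotated_bg = sorted(rng_ann.choice(bg_ids, size=n_annot, replace=False))
    for cid in annotated_bg:
        target_of[cid] = genes[next_gene]
        next_gene += 1
    if next_gene > params.n_genes:
        raise ValidationError(
            "n_genes too small to assign distinct intervention and target genes"
        )

    alpha, sigma = params.mimic_strength, params.noise_scale
    mimicked_by: dict[str, str] = {}
    for pc in planted:
        for iid in pc.mimics:
            mimicked_by[iid] = pc.compound_id

    perturbagens: list[Perturbagen] = []
    blocks: list[np.ndarray] = []
    truth = PlantedTruth()
    for pc in planted:
        truth.planted_hits[pc.compound_id] = set(pc.mimics)
        truth.concordant[pc.compound_id] = pc.concordant_target
        truth.target_genes[pc.compound_id] = target_of[pc.compound_id]

    for line in params.cell_lines:
        cores = {
            pc.compound_id: keyed_rng(seed, "universe", "core", pc.compound_id, line)
            .standard_normal(params.n_genes)
            for pc in planted
        }
        cols: list[np.ndarray] = []
        # interventions (knockdown/overexpression perturbagens)
        for iid in int_ids:
            row = by_id[iid]
            rng = keyed_rng(seed, "universe", "intervention", iid, line)
            if iid in mimicked_by:
                sig = _mix(cores[mimicked_by[iid]], alpha, sigma, rng)
            else:
                sig = sigma * rng.standard_normal(params.n_genes)
            perturbagens.append(
                Perturbagen(iid, row.direction, cell_line=line, target_gene=row.gene)
            )
            cols.append(sig)
        # drug-target knockdowns
        for cid in sorted(target_of):
            gene = target_of[cid]
            rng = keyed_rng(seed, "universe", "target_kd", cid, line)
            concordant = any(
                pc.compound_id == cid and pc.concordant_target for pc in planted
            )
            if concordant:
                sig = _mix(cores[cid], alpha, sigma, rng)
            else:
                sig = sigma * rng.standard_normal(params.n_genes)
            perturbagens.append(
                Perturbagen(
                    f"KD_{gene}", PertType.KNOCKDOWN, cell_line=line, target_gene=gene
                )
            )
            cols.append(sig)
        # compounds
        for pc in planted:
            perturbagens.append(
                Perturbagen(pc.compound_id, PertType.COMPOUND, cell_line=line)
            )
            cols.append(cores[pc.compound_id].copy())
        for cid in bg_ids:
            rng = keyed_rng(seed, "universe", "background", cid, line)
            perturbagens.append(Perturbagen(cid, PertType.COMPOUND, cell_line=line))
            cols.append(sigma * rng.standard_normal(params.n_genes))
        blocks.append(np.column_stack(cols))

    values = np.concatenate(blocks, axis=1)
    sigset = SignatureSet(
        gene_space=gene_space, perturbagens=tuple(perturbagens), values=values
    )
    annotations = TargetAnnotation(
        {cid: frozenset({gene}) for cid, gene in target_of.items()}
    )
    return sigset, annotations, interventions, truth


def simulate_counts(
    params: SimulationParams, seed: int, null: bool = False
) -> tuple[dict, PlantedTruth]:
    """Generate per-tissue NB count matrices with planted (shared) DE.

    Returns ({tissue: CountMatrix}, truth).  With ``null=True`` no effects
    are planted (all logFC = 0), for calibration checks.  Deterministic
    under ``seed``.
    """
    g = params.n_genes_counts
    genes = [f"G{i + 1:05d}" for i in range(g)]
    rng_base = keyed_rng(seed, "counts", "baseline")
    mu = np.exp(params.mean_log_mu + params.mean_log_sigma * rng_base.standard_normal(g))
    lo, hi = params.dispersion_range
    phi = rng_base.uniform(lo, hi, size=g)

    truth = PlantedTruth()
    lfc = {t: np.zeros(g) for t in params.tissues}
    if not null:
        rng_plant = keyed_rng(seed, "counts", "planted")
        n_planted = (
            params.n_shared_up
            + params.n_shared_down
            + params.n_specific_per_tissue * len(params.tissues)
        )
        if n_planted > g:
            raise ValidationError("more planted genes than genes simulated")
        chosen = rng_plant.choice(g, size=n_planted, replace=False)
        pos = 0
        shared_up = chosen[pos : pos + params.n_shared_up]; pos += params.n_shared_up
        shared_down = chosen[pos : pos + params.n_shared_down]; pos += params.n_shared_down
        truth.shared_up = {genes[i] for i in shared_up}
        truth.shared_down = {genes[i] for i in shared_down}
        for t in params.tissues:
            spec = chosen[pos : pos + params.n_specific_per_tissue]
            pos += params.n_specific_per_tissue
            signs = rng_plant.choice([-1.0, 1.0], size=spec.size)
            lfc[t][shared_up] = params.planted_logfc
            lfc[t][shared_down] = -params.planted_logfc
            lfc[t][spec] = signs * params.planted_logfc
            truth.tissue_up[t] = truth.shared_up | {
                genes[i] for i, s in zip(spec, signs) if s > 0
            }
            truth.tissue_down[t] = truth.shared_down | {
                genes[i] for i, s in zip(spec, signs) if s < 0
            }
    else:
        for t in params.tissues:
            truth.tissue_up[t] = set()
            truth.tissue_down[t] = set()

    n = params.samples_per_group
    matrices: dict[str, CountMatrix] = {}
    for t in params.tissues:
        rng = keyed_rng(seed, "counts", "tissue", t)
        mean_ctrl = np.repeat(mu[:, None], n, axis=1)
        mean_trt = np.repeat((mu * 2.0 ** lfc[t])[:, None], n, axis=1)
        r = 1.0 / np.repeat(phi[:, None], n, axis=1)

        def draw(mean: np.ndarray) -> np.ndarray:
            p = r / (r + mean)
            return rng.negative_binomial(r, p)

        ctrl = draw(mean_ctrl)
        trt = draw(mean_trt)
        samples = [f"{t}_control_{i + 1}" for i in range(n)] + [
            f"{t}_treated_{i + 1}" for i in range(n)
        ]
        counts = pd.DataFrame(
            np.concatenate([ctrl, trt], axis=1), index=genes, columns=samples
        )
        info = pd.DataFrame(
            {
                "group": ["control"] * n + ["treated"] * n,
                "tissue": [t] * 2 * n,
            },
            index=pd.Index(samples, name="sample"),
        )
        matrices[t] = CountMatrix(counts=counts, sample_info=info)
    return matrices, truth
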