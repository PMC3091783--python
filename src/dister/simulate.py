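"""Seeded generator of genomes with known operon structure, plus the
analytic Bayes-optimal oracle.

The generator emulates the data the pipeline consumes in real use — an
annotated circular genome, predicted terminator calls, and per-gene log
expression — with the ground truth attached:

* TU lengths are geometric with parameter ``p_stu`` (P(L = n) =
  p^(n-1)(1-p)), truncated at the chromosome end; mean length 1/(1-p).
* Each TU gets one strand; consecutive TUs switch strand with probability
  ``p_strand_switch``.
* Within-TU (STU) and between-TU (DTU) intergenic distances are drawn from
  class-conditional distributions over 10-bp bins (defaults emulate the
  compact-operon peak: STU concentrated around -20..+39 bp, DTU spread and
  decaying over 0..309 bp).
* A Rho-independent terminator is placed in the intergenic gap with a
  class-conditional probability — but only where intergenic sequence exists
  (distance >= 1), since a hairpin needs sequence to sit in.  The truth
  joint therefore carries a feasibility factor: P(term | bin) = p_term *
  P(distance >= 1 | bin), which the analytic oracle enumerates exactly.
* Expression is exchangeable within TUs: x = baseline + sd * (sqrt(rho) *
  z_TU + sqrt(1-rho) * eps_gene), giving within-TU correlation exactly rho
  and i.i.d. noise at rho = 0.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import GeneRecord, GenomeAnnotation, TerminatorCall
from .operon import OperonMap, map_from_partition
from .pairs import AdjacentPair, SAME_STRAND, score_class

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "BayesRates",
    "simulate_genome",
    "simulate_expression",
    "bayes_optimal_rates",
]

_DEF_STU_BINS = {-2: 0.10, -1: 0.15, 0: 0.30, 1: 0.25, 2: 0.12, 3: 0.08}


def _default_dtu_bins() -> dict[int, float]:
    bins = np.arange(0, 31)
    w = np.exp(-bins / 20.0)
    w = w / w.sum()
    return {int(b): float(p) for b, p in zip(bins, w)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome.

    ``p_stu`` defaults to 0.53 (mean TU length ~2.13 genes, the compact
    reduced-genome regime); terminators follow ~5% of within-TU gaps and
    ~60% of TU boundaries, with confidences uniform on [50, 100].
    """

    n_genes: int = 500
    p_stu: float = 0.53
    stu_distance_model: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEF_STU_BINS)
    )
    dtu_distance_model: Mapping[int, float] = field(
        default_factory=_default_dtu_bins
    )
    p_term_given_class: Mapping[str, float] = field(
        default_factory=lambda: {"STU": 0.05, "DTU": 0.60}
    )
    term_confidence_range: tuple[float, float] = (50.0, 100.0)
    p_strand_switch: float = 0.5
    gene_length_range: tuple[int, int] = (300, 1500)
    rho: float = 0.0
    gene_sd: float = 1.0
    expression_baseline: float = 8.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_stu", "p_strand_switch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for c, v in self.p_term_given_class.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p_term_given_class[{c}]={v} outside [0, 1]")
        for name, model in (
            ("stu_distance_model", self.stu_distance_model),
            ("dtu_distance_model", self.dtu_distance_model),
        ):
            if abs(sum(model.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho={self.rho} outside [0, 1)")


@dataclass(frozen=True)
class SimulatedGenome:
    annotation: GenomeAnnotation
    truth_map: OperonMap
    pairs: tuple[AdjacentPair, ...]  # feature-complete, truth-labeled
    terminators: tuple[TerminatorCall, ...]


def _draw_tu_lengths(
    n_genes: int, p_stu: float, rng: np.random.Generator
) -> list[int]:
    lengths = []
    remaining = n_genes
    while remaining > 0:
        L = int(rng.geometric(1.0 - p_stu)) if p_stu > 0 else 1
        lengths.append(min(L, remaining))  # final TU truncated at the end
        remaining -= lengths[-1]
    return lengths


def simulate_genome(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedGenome:
    """Generate a circular genome with a known TU partition.

    Returns the annotation, the truth operon map, the truth-labeled
    feature-complete pair table (wrap-around pair included) and the
    terminator calls.  Byte-identical for identical (config, seed).
    """
    if config.n_genes < 4:
        raise ValueError("need at least 4 genes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes
    tu_lengths = _draw_tu_lengths(n, config.p_stu, rng)

    strands = []
    s = "+" if rng.random() < 0.5 else "-"
    for _ in tu_lengths:
        strands.append(s)
        if rng.random() < config.p_strand_switch:
            s = "+" if s == "-" else "-"

    # per-gene strand and per-pair true class, chromosome order
    gene_strand: list[str] = []
    pair_is_stu: list[bool] = []
    for L, st in zip(tu_lengths, strands):
        gene_strand.extend([st] * L)
        pair_is_stu.extend([True] * (L - 1) + [False])
    # the final False is the wrap-around boundary back to TU 0 (unless the
    # whole genome is one TU)
    if len(tu_lengths) == 1:
        pair_is_stu[-1] = True

    stu_bins = sorted(config.stu_distance_model)
    stu_probs = np.array([config.stu_distance_model[b] for b in stu_bins])
    dtu_bins = sorted(config.dtu_distance_model)
    dtu_probs = np.array([config.dtu_distance_model[b] for b in dtu_bins])

    distances: list[int] = []
    for i in range(n):
        if pair_is_stu[i]:
            b = stu_bins[rng.choice(len(stu_bins), p=stu_probs)]
        else:
            b = dtu_bins[rng.choice(len(dtu_bins), p=dtu_probs)]
        d = b * 10 + int(rng.integers(0, 10))
        if i == n - 1 and d < 1:
            d = 1  # the wrap gap must leave room between last end and origin
        distances.append(d)

    # Terminators sit at TU 3' ends: a within-TU gap may carry a readthrough
    # terminator on the TU's strand; a boundary gap carries the upstream TU's
    # terminator when that TU is on "+" and/or the downstream TU's when it is
    # on "-" (so a convergent gap can host two and a divergent gap none).
    p_term = config.p_term_given_class
    term_plan: list[list[str]] = []  # strands of terminators in each gap
    for i in range(n):
        d = distances[i]
        plan: list[str] = []
        if d >= 1:
            up_s = gene_strand[i]
            down_s = gene_strand[(i + 1) % n]
            if pair_is_stu[i]:
                if rng.random() < p_term["STU"]:
                    plan.append(up_s)
            else:
                if up_s == "+" and rng.random() < p_term["DTU"]:
                    plan.append("+")
                if down_s == "-" and rng.random() < p_term["DTU"]:
                    plan.append("-")
        term_plan.append(plan)

    lo, hi = config.gene_length_range
    gene_lengths = rng.integers(lo, hi + 1, size=n)
    starts = np.empty(n, dtype=np.int64)
    starts[0] = 1
    for i in range(1, n):
        starts[i] = starts[i - 1] + gene_lengths[i - 1] + distances[i - 1]
    ends = starts + gene_lengths - 1
    genome_length = int(ends[-1] + distances[-1])

    genes = tuple(
        GeneRecord(
            gene_id=f"g{i:05d}",
            start=int(starts[i]),
            end=int(ends[i]),
            strand=gene_strand[i],
        )
        for i in range(n)
    )
    annotation = GenomeAnnotation(
        replicon_id="sim", length=genome_length, genes=genes, circular=True
    )

    terminators = []
    conf_lo, conf_hi = config.term_confidence_range
    pairs = []
    for i in range(n):
        up, down = genes[i], genes[(i + 1) % n]
        d = distances[i]
        orientation = (
            SAME_STRAND
            if up.strand == down.strand
            else ("convergent" if up.strand == "+" else "divergent")
        )
        matched_conf = None  # the call strand-matched to the upstream gene
        for strand in term_plan[i]:
            conf = float(rng.uniform(conf_lo, conf_hi))
            width = min(d, 20)
            offset = int(rng.integers(0, d - width + 1))
            t_start = up.end + 1 + offset
            terminators.append(
                TerminatorCall(
                    start=t_start,
                    end=t_start + width - 1,
                    strand=strand,
                    confidence=conf,
                    hairpin_energy=float(-rng.uniform(4.0, 16.0)),
                )
            )
            if strand == up.strand and (
                matched_conf is None or conf > matched_conf
            ):
                matched_conf = conf
        label = "STU" if pair_is_stu[i] else "DTU"
        if orientation != SAME_STRAND:
            label = "DTU"
        pairs.append(
            AdjacentPair(
                upstream=up.gene_id,
                downstream=down.gene_id,
                orientation=orientation,
                distance=d,
                terminator_present=matched_conf is not None,
                terminator_score_class=(
                    score_class(matched_conf) if matched_conf is not None else "absent"
                ),
                terminator_confidence=matched_conf,
                label=label,
            )
        )

    groups = []
    i = 0
    for L in tu_lengths:
        groups.append([f"g{j:05d}" for j in range(i, i + L)])
        i += L
    truth_map = map_from_partition(annotation, groups)
    return SimulatedGenome(
        annotation=annotation,
        truth_map=truth_map,
        pairs=tuple(pairs),
        terminators=tuple(terminators),
    )


def simulate_expression(
    truth_map: OperonMap, config: SimulationConfig, seed: int | None = None
) -> dict[str, float]:
    """Per-gene log expression with within-TU correlation exactly rho."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rho, sd, mu = config.rho, config.gene_sd, config.expression_baseline
    out: dict[str, float] = {}
    for tu in truth_map.tus:
        z = rng.standard_normal()
        for g in tu.gene_ids:
            eps = rng.standard_normal()
            out[g] = mu + sd * (np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps)
    return out


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesRates:
    se: float
    sp: float
    accuracy: float
    prior: float


def _feasibility(b: int) -> float:
    """P(distance >= 1 | bin b) with the uniform within-bin offset."""
    if b < 0:
        return 0.0
    if b == 0:
        return 0.9
    return 1.0


def same_strand_prior(config: SimulationConfig) -> float:
    """P(STU | same-strand adjacent pair) under the generating model.

    Every within-TU pair is same-strand; a TU boundary is same-strand with
    probability 1 - p_strand_switch.
    """
    p = config.p_stu
    q = 1.0 - config.p_strand_switch
    return p / (p + (1.0 - p) * q)


def _score_class_probs(config: SimulationConfig) -> dict[str, float]:
    lo, hi = config.term_confidence_range
    span = hi - lo

    def mass(a: float, b: float) -> float:
        return max(0.0, (min(b, hi) - max(a, lo))) / span

    return {"low": mass(lo, 76.0), "mid": mass(76.0, 90.0), "high": mass(90.0, hi)}


def bayes_optimal_rates(
    config: SimulationConfig,
    threshold: float = 0.5,
    model_config: int = 2,
    prior: float | None = None,
) -> BayesRates:
    """Exact Se/Sp of the true-posterior classifier at a threshold.

    Enumerates every (distance bin, terminator state) cell of the generating
    mixture — no sampling.  The default prior is the same-strand-conditional
    P(STU); pass ``prior`` to evaluate a classifier operating under a
    different prior (e.g. the unconditional geometric p).
    """
    p = same_strand_prior(config) if prior is None else prior
    models = {"STU": config.stu_distance_model, "DTU": config.dtu_distance_model}
    bins = sorted(set(models["STU"]) | set(models["DTU"]))
    if model_config == 3:
        sc = _score_class_probs(config)
        states = ["absent", "low", "mid", "high"]
    else:
        states = ["absent", "present"]

    cond: dict[str, dict[tuple[int, str], float]] = {}
    for c in ("STU", "DTU"):
        pt = config.p_term_given_class[c]
        tbl: dict[tuple[int, str], float] = {}
        for b in bins:
            pb = models[c].get(b, 0.0)
            p_term = _feasibility(b) * pt
            tbl[(b, "absent")] = pb * (1.0 - p_term)
            if model_config == 3:
                for s in ("low", "mid", "high"):
                    tbl[(b, s)] = pb * p_term * sc[s]
            else:
                tbl[(b, "present")] = pb * p_term
        cond[c] = tbl

    se = sp = 0.0
    for b in bins:
        for s in states:
            l_stu = cond["STU"][(b, s)]
            l_dtu = cond["DTU"][(b, s)]
            den = p * l_stu + (1.0 - p) * l_dtu
            if den == 0.0:
                continue
            post = p * l_stu / den
            if post > threshold:
                se += l_stu
            else:
                sp += l_dtu
    return BayesRates(
        se=se, sp=sp, accuracy=p * se + (1.0 - p) * sp, prior=p
    )
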