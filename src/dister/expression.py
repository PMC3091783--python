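"""Expression-based validation of an operon map.

If an operon map is right, genes sharing a polycistronic TU sit on one
mRNA and should vary together; so a one-way ANOVA of per-gene log
expression with TU membership as the single factor should explain much of
the variance.  Monocistronic TUs are excluded (a group of one gene carries
no within-group information and inflates the factor).  Because adjacent
genes are correlated for reasons other than co-transcription (shared
chromosomal neighborhood), significance is assessed against a
proximity-preserving permutation null: the multiset of polycistronic TU
lengths is shuffled and re-laid as contiguous blocks over the
chromosome-ordered gene list, so simulated co-members remain neighbors, and
the observed F is compared with the simulated F distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .operon import OperonMap

__all__ = ["AnovaResult", "PermutationResult", "anova_tu", "permutation_pvalue"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    R2: float
    R2_adj: float
    n: int  # genes analyzed
    g: int  # groups (polycistronic TUs)
    missing_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class PermutationResult:
    observed_F: float
    observed_R2_adj: float
    n_perm: int
    n_exceed: int
    p_value: float
    seed: int | None
    shuffle_mode: str

    def __post_init__(self) -> None:
        if not 0 <= self.n_exceed <= self.n_perm:
            raise ValueError("n_exceed outside [0, n_perm]")

    @property
    def p_display(self) -> str:
        """Human-readable p; zero exceedances reported as a bound."""
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"


def _poly_genes_in_order(operon_map: OperonMap) -> tuple[list[str], list[int]]:
    """Genes of polycistronic TUs in chromosome order, plus TU block sizes."""
    ann = operon_map.annotation
    tus = operon_map.polycistronic()
    if ann is not None:
        tus = sorted(
            tus, key=lambda tu: min(ann.gene(g).start for g in tu.gene_ids)
        )
        ordered = [
            sorted(tu.gene_ids, key=lambda g: ann.gene(g).start) for tu in tus
        ]
    else:
        ordered = [list(tu.gene_ids) for tu in tus]
    genes = [g for group in ordered for g in group]
    sizes = [len(group) for group in ordered]
    return genes, sizes


def _f_and_r2(values: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """One-way decomposition over contiguous blocks of the given sizes."""
    n = values.size
    g = sizes.size
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    sums = np.add.reduceat(values, starts)
    grand = values.sum()
    sst = float(np.sum(values * values) - grand * grand / n)
    ssb = float(np.sum(sums * sums / sizes) - grand * grand / n)
    ssw = sst - ssb
    if sst <= 0.0:
        return 0.0, 0.0
    r2 = ssb / sst
    if ssw <= 1e-300 * max(1.0, ssb):
        return math.inf, r2
    f = (ssb / (g - 1)) / (ssw / (n - g))
    return f, r2


def anova_tu(
    expression: Mapping[str, float], operon_map: OperonMap
) -> AnovaResult:
    """One-way ANOVA of log expression with polycistronic TU as the factor.

    Returns F, R2 = SSB/SST and adjusted R2 = 1 - (1-R2)(n-1)/(n-g).  Genes
    of the map without an expression value are listed and excluded.  Perfect
    separation (zero within-TU variance with between-TU spread) yields
    F = inf with R2 = 1.
    """
    tus = operon_map.polycistronic()
    if len(tus) < 2:
        raise ValueError("need at least 2 polycistronic TUs for the ANOVA")
    values, sizes, missing = [], [], []
    for tu in tus:
        vals = []
        for gid in tu.gene_ids:
            if gid in expression:
                v = float(expression[gid])
                if not math.isfinite(v):
                    raise ValueError(f"non-finite expression value for {gid}")
                vals.append(v)
            else:
                missing.append(gid)
        if vals:
            values.extend(vals)
            sizes.append(len(vals))
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} mapped genes lack expression values and were "
            "excluded",
            stacklevel=2,
        )
    sizes_arr = np.array(sizes)
    n, g = int(sizes_arr.sum()), len(sizes)
    if g < 2 or n - g < 1:
        raise ValueError("zero within-group degrees of freedom")
    f, r2 = _f_and_r2(np.asarray(values, dtype=float), sizes_arr)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - g)
    return AnovaResult(
        F=f, R2=r2, R2_adj=r2_adj, n=n, g=g, missing_genes=tuple(missing)
    )


def permutation_pvalue(
    expression: Mapping[str, float],
    operon_map: OperonMap,
    n_perm: int = 10_000,
    seed: int | None = None,
    shuffle_mode: str = "blocks_in_order",
) -> PermutationResult:
    """Length-preserving TU-label permutation test of the ANOVA F.

    blocks_in_order (default): the polycistronic TU lengths are permuted and
    re-laid as contiguous blocks over the chromosome-ordered polycistronic
    gene list, preserving gene proximity within simulated TUs.  free_relabel:
    genes are permuted freely among groups of the conserved sizes.  The
    p-value is the proportion of simulated F strictly greater than the
    observed F (ties do not count as exceedances).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if shuffle_mode not in ("blocks_in_order", "free_relabel"):
        raise ValueError(f"unknown shuffle mode {shuffle_mode!r}")
    observed = anova_tu(expression, operon_map)
    genes, sizes = _poly_genes_in_order(operon_map)
    values = np.array(
        [float(expression[g]) for g in genes if g in expression], dtype=float
    )
    sizes_arr = np.array(
        [
            sum(1 for g in group_genes if g in expression)
            for group_genes in _grouped(genes, sizes)
        ]
    )
    sizes_arr = sizes_arr[sizes_arr > 0]
    # the reference F goes through the same summation path as the simulated
    # ones, so an identical relayout ties exactly instead of differing in the
    # last float bits (the strict ">" rule depends on exact ties)
    f_obs, _ = _f_and_r2(values, sizes_arr)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        if shuffle_mode == "blocks_in_order":
            perm_sizes = rng.permutation(sizes_arr)
            f, _ = _f_and_r2(values, perm_sizes)
        else:
            f, _ = _f_and_r2(rng.permutation(values), sizes_arr)
        if f > f_obs:
            n_exceed += 1
    return PermutationResult(
        observed_F=f_obs,
        observed_R2_adj=observed.R2_adj,
        n_perm=n_perm,
        n_exceed=n_exceed,
        p_value=n_exceed / n_perm,
        seed=seed,
        shuffle_mode=shuffle_mode,
    )


def _grouped(genes: list[str], sizes: list[int]):
    i = 0
    for s in sizes:
        yield genes[i : i + s]
        i += s
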