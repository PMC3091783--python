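"""Operon-map assembly from per-pair calls, and map-level statistics.

Transcription units are maximal runs of consecutive same-strand genes whose
internal adjacent pairs are all called STU; the map partitions the gene set
(every gene in exactly one TU).  On a circular replicon the wrap-around pair
can merge the first and last runs; on a non-degenerate circular assembly the
TU count obeys #TUs = N - #STU calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import AnnotationError, GenomeAnnotation
from .pairs import SAME_STRAND, AdjacentPair, enumerate_adjacent_pairs

__all__ = [
    "TranscriptionUnit",
    "OperonMap",
    "assemble_map",
    "map_from_partition",
    "map_stats",
    "compare_length_distributions",
    "fit_geometric",
    "intergenic_summaries",
    "map_diff",
    "stu_pair_set",
]


@dataclass(frozen=True)
class TranscriptionUnit:
    """An ordered run of co-transcribed genes (transcription order)."""

    tu_id: str
    gene_ids: tuple[str, ...]
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"TU {self.tu_id}: empty gene list")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TU {self.tu_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return len(self.gene_ids)

    @property
    def polycistronic(self) -> bool:
        return self.length > 1


@dataclass(frozen=True)
class OperonMap:
    replicon_id: str
    tus: tuple[TranscriptionUnit, ...]
    annotation: GenomeAnnotation | None = None
    provenance: dict = field(default_factory=dict)
    degenerate: bool = False  # a single TU spanning the whole circle
    validate_partition: bool = True

    def __post_init__(self) -> None:
        if self.validate_partition:
            seen: set[str] = set()
            for tu in self.tus:
                for g in tu.gene_ids:
                    if g in seen:
                        raise AnnotationError(f"gene {g} appears in two TUs")
                    seen.add(g)
            if self.annotation is not None and len(seen) != len(self.annotation):
                raise AnnotationError(
                    f"map covers {len(seen)} genes but the annotation has "
                    f"{len(self.annotation)}"
                )

    @property
    def n_genes(self) -> int:
        return sum(tu.length for tu in self.tus)

    def polycistronic(self) -> tuple[TranscriptionUnit, ...]:
        return tuple(tu for tu in self.tus if tu.polycistronic)

    def tu_of(self) -> dict[str, str]:
        return {g: tu.tu_id for tu in self.tus for g in tu.gene_ids}


def _make_tu(genes: Sequence, strand: str) -> TranscriptionUnit:
    ordered = [g.gene_id for g in genes]
    if strand == "-":
        ordered = ordered[::-1]  # transcription runs right-to-left
    return TranscriptionUnit(
        tu_id=f"TU_{ordered[0]}", gene_ids=tuple(ordered), strand=strand
    )


def assemble_map(
    annotation: GenomeAnnotation,
    calls: Mapping[tuple[str, str], str],
    provenance: dict | None = None,
) -> OperonMap:
    """Chain adjacent-pair calls into a TU partition of the genome.

    ``calls`` maps (upstream_id, downstream_id) for every adjacent pair to
    "STU" or "DTU".  An STU call on an opposite-strand pair is a contract
    violation.  The all-STU circle collapses to a single TU flagged
    degenerate.
    """
    pairs = enumerate_adjacent_pairs(annotation)
    genes = annotation.genes
    n = len(genes)
    joined: list[bool] = []
    n_stu = 0
    for pair in pairs:
        key = (pair.upstream, pair.downstream)
        if key not in calls:
            raise AnnotationError(f"no call for adjacent pair {key}")
        call = calls[key]
        if call not in ("STU", "DTU"):
            raise ValueError(f"bad call {call!r} for pair {key}")
        if call == "STU" and pair.orientation != SAME_STRAND:
            raise AnnotationError(
                f"STU call on opposite-strand pair {key}: impossible by definition"
            )
        joined.append(call == "STU")
        n_stu += call == "STU"

    prov = dict(provenance or {})
    prov.setdefault("n_stu_calls", n_stu)

    if annotation.circular and all(joined):
        tu = _make_tu(genes, genes[0].strand)
        return OperonMap(
            replicon_id=annotation.replicon_id,
            tus=(tu,),
            annotation=annotation,
            provenance=prov,
            degenerate=True,
        )

    # cut after gene i whenever pair (i, i+1) is DTU; for a linear replicon
    # there is an implicit cut after the last gene
    if not annotation.circular:
        joined.append(False)
    cuts = [i for i, j in enumerate(joined) if not j]
    tus = []
    for k, cut in enumerate(cuts):
        start = (cuts[k - 1] + 1) % n if annotation.circular or k > 0 else 0
        if k == 0 and annotation.circular:
            start = (cuts[-1] + 1) % n
        idx = []
        i = start
        while True:
            idx.append(i)
            if i == cut:
                break
            i = (i + 1) % n
        run = [genes[i] for i in idx]
        tus.append(_make_tu(run, run[0].strand))
    # deterministic order: by chromosomal start of the first (leftmost) gene
    tus.sort(key=lambda tu: min(annotation.gene(g).start for g in tu.gene_ids))
    return OperonMap(
        replicon_id=annotation.replicon_id,
        tus=tuple(tus),
        annotation=annotation,
        provenance=prov,
    )


def map_from_partition(
    annotation: GenomeAnnotation, tu_gene_lists: Sequence[Sequence[str]]
) -> OperonMap:
    """Build a map from explicit gene groupings (e.g. a simulation truth)."""
    tus = []
    for group in tu_gene_lists:
        recs = [annotation.gene(g) for g in group]
        tus.append(_make_tu(recs, recs[0].strand))
    return OperonMap(
        replicon_id=annotation.replicon_id,
        tus=tuple(tus),
        annotation=annotation,
        provenance={"source": "partition"},
    )


# ---------------------------------------------------------------------------
# Map statistics
# ---------------------------------------------------------------------------

def map_stats(operon_map: OperonMap) -> dict:
    """Counts and length summaries of a map.

    mean TU length = genes / TUs; mean polycistronic length =
    (genes - #mono) / #poly (absent when the map is all-monocistronic).
    """
    lengths = [tu.length for tu in operon_map.tus]
    if not lengths:
        raise ValueError("empty operon map")
    n_genes = sum(lengths)
    n_tus = len(lengths)
    n_mono = sum(1 for L in lengths if L == 1)
    n_poly = n_tus - n_mono
    hist: dict[int, int] = {}
    for L in lengths:
        hist[L] = hist.get(L, 0) + 1
    return {
        "n_genes": n_genes,
        "n_tus": n_tus,
        "n_monocistronic": n_mono,
        "n_polycistronic": n_poly,
        "mean_tu_length": n_genes / n_tus,
        "mean_polycistronic_length": (
            (n_genes - n_mono) / n_poly if n_poly else None
        ),
        "length_histogram": dict(sorted(hist.items())),
    }


def compare_length_distributions(map_a: OperonMap, map_b: OperonMap) -> dict:
    """Two-sided rank-sum comparison of the two maps' TU-length vectors."""
    la = [tu.length for tu in map_a.tus]
    lb = [tu.length for tu in map_b.tus]
    stat, p = stats.mannwhitneyu(la, lb, alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p)}


def fit_geometric(operon_map: OperonMap) -> dict:
    """Moment fit of the geometric TU-length model to a map.

    p_hat = (mean - 1)/mean; expected counts n * p^(k-1)(1-p) are reported
    alongside the observed length histogram for a goodness-of-fit summary.
    """
    lengths = np.array([tu.length for tu in operon_map.tus], dtype=float)
    mean = float(lengths.mean())
    p_hat = (mean - 1.0) / mean
    n = len(lengths)
    max_len = int(lengths.max())
    observed = {k: int(np.sum(lengths == k)) for k in range(1, max_len + 1)}
    expected = {
        k: n * (p_hat ** (k - 1)) * (1.0 - p_hat) for k in range(1, max_len + 1)
    }
    return {
        "p_hat": p_hat,
        "mean_length": mean,
        "n_tus": n,
        "observed": observed,
        "expected": expected,
    }


def intergenic_summaries(pairs: Sequence[AdjacentPair]) -> dict:
    """Per-orientation intergenic-distance and terminator summaries.

    Rows mirror the same-strand / convergent / divergent layout; each gives
    the pair count, the distance list, and the count and fraction of pairs
    with a strand-matched predicted terminator.
    """
    out = {}
    for orientation in (SAME_STRAND, "convergent", "divergent"):
        subset = [p for p in pairs if p.orientation == orientation]
        n = len(subset)
        n_term = sum(1 for p in subset if p.terminator_present)
        out[orientation] = {
            "n": n,
            "distances": [p.distance for p in subset],
            "n_terminator": n_term,
            "terminator_fraction": (n_term / n) if n else 0.0,
        }
    return out


# ---------------------------------------------------------------------------
# Map comparison plumbing
# ---------------------------------------------------------------------------

def stu_pair_set(operon_map: OperonMap) -> set[frozenset[str]]:
    """The co-transcribed adjacent pairs implied by a map."""
    out: set[frozenset[str]] = set()
    for tu in operon_map.tus:
        for a, b in zip(tu.gene_ids, tu.gene_ids[1:]):
            out.add(frozenset((a, b)))
    return out


def map_diff(map_a: OperonMap, map_b: OperonMap) -> dict:
    """Pairs classified STU by one map and DTU by the other."""
    sa, sb = stu_pair_set(map_a), stu_pair_set(map_b)
    return {
        "stu_in_a_only": sorted(tuple(sorted(p)) for p in sa - sb),
        "stu_in_b_only": sorted(tuple(sorted(p)) for p in sb - sa),
        "stu_in_both": len(sa & sb),
    }
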