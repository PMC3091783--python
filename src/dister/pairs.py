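"""Adjacent gene pairs on a circular genome and their classifier features.

The pair classifier works on pairs of chromosomally adjacent genes.  On a
circular replicon with N genes there are exactly N such pairs (including the
wrap-around pair from the last gene back to the first); a linear replicon has
N-1.  Each pair carries:

* orientation — same_strand, convergent (+ then -) or divergent (- then +);
* intergenic distance — bases strictly between the two genes, negative when
  they overlap (start(down) - end(up) - 1);
* distance bin — floor(distance / 10), the 10-bp discretization;
* terminator evidence — whether a strand-matched predicted terminator falls
  in the intergenic interval, and a coarse confidence class for it;
* training label — STU (same transcription unit), DTU (different TUs),
  NK (computational evidence only) or unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import (
    AnnotationError,
    GeneRecord,
    GenomeAnnotation,
    KnownTUTable,
    TerminatorCall,
)

__all__ = [
    "AdjacentPair",
    "enumerate_adjacent_pairs",
    "intergenic_distance",
    "bin_distance",
    "assign_terminator",
    "attach_terminators",
    "label_pairs",
    "training_pairs",
    "write_pair_table",
    "read_pair_table",
]

SAME_STRAND = "same_strand"
CONVERGENT = "convergent"
DIVERGENT = "divergent"

# terminator confidence classes (model 3); TransTermHP treats >90 as
# high-confidence, 76 splits the remaining mass roughly in half
SCORE_LOW_MAX = 76.0   # low: confidence < 76
SCORE_MID_MAX = 90.0   # mid: 76 <= confidence <= 90; high: > 90


@dataclass(frozen=True)
class AdjacentPair:
    upstream: str
    downstream: str
    orientation: str
    distance: int
    terminator_present: bool = False
    terminator_score_class: str = "absent"
    terminator_confidence: float | None = None
    label: str = "unlabeled"
    leader_excluded: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in (SAME_STRAND, CONVERGENT, DIVERGENT):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.label not in ("STU", "DTU", "NK", "unlabeled"):
            raise ValueError(f"bad label {self.label!r}")
        if self.label in ("STU", "NK") and self.orientation != SAME_STRAND:
            raise ValueError(
                f"{self.upstream}/{self.downstream}: label {self.label} "
                "requires same-strand orientation"
            )
        if (self.terminator_score_class == "absent") != (not self.terminator_present):
            raise ValueError("terminator_score_class inconsistent with presence flag")

    @property
    def distance_bin(self) -> int:
        return bin_distance(self.distance)


def _orientation(up: GeneRecord, down: GeneRecord) -> str:
    if up.strand == down.strand:
        return SAME_STRAND
    return CONVERGENT if up.strand == "+" else DIVERGENT


def intergenic_distance(
    upstream: GeneRecord,
    downstream: GeneRecord,
    annotation: GenomeAnnotation,
) -> int:
    """Bases strictly separating two adjacent genes; negative when overlapping.

    The wrap-around pair of a circular replicon unrolls the downstream start
    by the genome length.
    """
    down_start = downstream.start
    if down_start <= upstream.start:  # wrap-around pair
        if not annotation.circular:
            raise AnnotationError(
                f"{upstream.gene_id}/{downstream.gene_id}: wrap-around pair "
                "on a linear replicon"
            )
        down_start += annotation.length
    return down_start - upstream.end - 1


def bin_distance(distance: int) -> int:
    """The 10-bp discretization: floor(distance / 10).

    Bin 0 covers 0..9 bp, bin -1 covers -10..-1 (overlaps), bin 1 covers
    10..19, and so on.  Clamping of bins outside a trained range happens at
    prediction time, not here.
    """
    return distance // 10


def enumerate_adjacent_pairs(annotation: GenomeAnnotation) -> list[AdjacentPair]:
    """All adjacent gene pairs in chromosome order.

    Circular replicons yield one pair per gene (the last pair wraps around to
    the first gene); linear replicons yield N-1 pairs.
    """
    genes = annotation.genes
    if len(genes) < 2:
        raise AnnotationError("need at least 2 genes to form adjacent pairs")
    n = len(genes)
    last = n if annotation.circular else n - 1
    pairs = []
    for i in range(last):
        up, down = genes[i], genes[(i + 1) % n]
        pairs.append(
            AdjacentPair(
                upstream=up.gene_id,
                downstream=down.gene_id,
                orientation=_orientation(up, down),
                distance=intergenic_distance(up, down, annotation),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Terminator assignment
# ---------------------------------------------------------------------------

def score_class(confidence: float) -> str:
    if confidence < SCORE_LOW_MAX:
        return "low"
    if confidence <= SCORE_MID_MAX:
        return "mid"
    return "high"


def assign_terminator(
    pair: AdjacentPair,
    terminators: Sequence[TerminatorCall],
    annotation: GenomeAnnotation,
) -> AdjacentPair:
    """Attach terminator evidence to one pair.

    A terminator counts for the pair iff its interval intersects the open
    intergenic interval between the two genes AND its strand equals the
    upstream gene's strand (a Rho-independent terminator acts at the 3' end
    of the transcript running into the gap).  Among several matching calls
    the highest-confidence one is kept.  Overlapping genes have an empty
    intergenic interval, hence never a terminator.
    """
    up = annotation.gene(pair.upstream)
    if pair.distance < 1:
        return replace(
            pair,
            terminator_present=False,
            terminator_score_class="absent",
            terminator_confidence=None,
        )
    lo = up.end + 1
    hi = up.end + pair.distance  # == start(down) - 1, unrolled for the wrap pair
    L = annotation.length
    best: TerminatorCall | None = None
    for term in terminators:
        if term.strand != up.strand:
            continue
        hits = term.start <= hi and term.end >= lo
        if not hits and annotation.circular:
            # wrap-around interval may extend past the origin
            hits = term.start + L <= hi and term.end + L >= lo
        if hits and (best is None or term.confidence > best.confidence):
            best = term
    if best is None:
        return replace(
            pair,
            terminator_present=False,
            terminator_score_class="absent",
            terminator_confidence=None,
        )
    return replace(
        pair,
        terminator_present=True,
        terminator_score_class=score_class(best.confidence),
        terminator_confidence=best.confidence,
    )


def attach_terminators(
    pairs: Sequence[AdjacentPair],
    terminators: Sequence[TerminatorCall],
    annotation: GenomeAnnotation,
) -> list[AdjacentPair]:
    return [assign_terminator(p, terminators, annotation) for p in pairs]


# ---------------------------------------------------------------------------
# Training labels from a curated TU table
# ---------------------------------------------------------------------------

def _adjacent_in(tu_genes: tuple[str, ...], a: str, b: str) -> bool:
    for x, y in zip(tu_genes, tu_genes[1:]):
        if {x, y} == {a, b}:
            return True
    return False


def label_pairs(
    pairs: Sequence[AdjacentPair],
    tus: KnownTUTable,
    annotation: GenomeAnnotation,
) -> list[AdjacentPair]:
    """Fill training labels from a curated TU table.

    * STU — some experimentally-evidenced polycistronic TU contains the two
      genes adjacently (at least one such TU suffices; overlapping
      alternative TUs cannot demote an STU).
    * DTU — the genes run in opposite directions, or experimental TU
      membership separates them (one or both genes sit in experimental TUs
      none of which contains the partner).
    * NK — the only TUs containing both genes are computational predictions.
    * unlabeled — no evidence either way.

    Pairs touching any gene of a leader-peptide-carrying TU are flagged
    ``leader_excluded`` and dropped by :func:`training_pairs` (attenuation
    operons are structurally unrepresentative of genomes that lack
    attenuation).
    """
    tus.validate_against(annotation)
    exp_membership: dict[str, set[str]] = {}
    leader_genes: set[str] = set()
    for tu in tus:
        if tu.leader_peptide:
            leader_genes.update(tu.gene_ids)
        if tu.evidence == "experimental":
            for gid in tu.gene_ids:
                exp_membership.setdefault(gid, set()).add(tu.tu_id)
    exp_tus = {t.tu_id: t for t in tus if t.evidence == "experimental"}
    comp_tus = [t for t in tus if t.evidence == "computational"]

    out = []
    for pair in pairs:
        a, b = pair.upstream, pair.downstream
        leader = a in leader_genes or b in leader_genes
        if pair.orientation != SAME_STRAND:
            out.append(replace(pair, label="DTU", leader_excluded=leader))
            continue
        stu = any(
            _adjacent_in(exp_tus[tid].gene_ids, a, b)
            for tid in exp_membership.get(a, set()) & exp_membership.get(b, set())
        )
        if stu:
            label = "STU"
        elif any(_adjacent_in(t.gene_ids, a, b) for t in comp_tus):
            # a computational TU joins the pair: co-transcription is
            # plausible but unverified, so the pair must stay out of the
            # training set even when one gene has experimental membership
            label = "NK"
        elif exp_membership.get(a) or exp_membership.get(b):
            # experimental evidence places the genes in different TUs
            # (or places one inside a TU that excludes the other)
            label = "DTU"
        else:
            label = "unlabeled"
        out.append(replace(pair, label=label, leader_excluded=leader))
    return out


def training_pairs(pairs: Sequence[AdjacentPair]) -> list[AdjacentPair]:
    """The classifier's training subset: labeled same-strand pairs.

    NK and unlabeled pairs, opposite-strand pairs (DTU by definition, no
    posterior needed) and leader-peptide pairs are excluded.
    """
    return [
        p
        for p in pairs
        if p.orientation == SAME_STRAND
        and p.label in ("STU", "DTU")
        and not p.leader_excluded
    ]


# ---------------------------------------------------------------------------
# Pair table TSV
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "upstream",
    "downstream",
    "orientation",
    "distance",
    "distance_bin",
    "term_present",
    "term_score_class",
    "term_confidence",
    "label",
    "leader_excluded",
]


def write_pair_table(pairs: Sequence[AdjacentPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "upstream": [p.upstream for p in pairs],
            "downstream": [p.downstream for p in pairs],
            "orientation": [p.orientation for p in pairs],
            "distance": [p.distance for p in pairs],
            "distance_bin": [p.distance_bin for p in pairs],
            "term_present": [str(p.terminator_present) for p in pairs],
            "term_score_class": [p.terminator_score_class for p in pairs],
            "term_confidence": [
                "." if p.terminator_confidence is None else p.terminator_confidence
                for p in pairs
            ],
            "label": [p.label for p in pairs],
            "leader_excluded": [str(p.leader_excluded) for p in pairs],
        },
        columns=_PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[AdjacentPair]:
    from .io import ParseError

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not set(_PAIR_COLUMNS).issubset(df.columns):
        raise ParseError(
            f"{path}: pair table needs columns {_PAIR_COLUMNS}"
        )
    pairs = []
    for row in df.itertuples(index=False):
        conf = None if row.term_confidence == "." else float(row.term_confidence)
        pairs.append(
            AdjacentPair(
                upstream=row.upstream,
                downstream=row.downstream,
                orientation=row.orientation,
                distance=int(row.distance),
                terminator_present=str(row.term_present).lower() == "true",
                terminator_score_class=row.term_score_class,
                terminator_confidence=conf,
                label=row.label,
                leader_excluded=str(row.leader_excluded).lower() == "true",
            )
        )
    return pairs
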