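"""Comparative TU evolution between a reduced genome and a reference.

Given an orthology map between genome A (the reduced genome under study) and
a reference genome B, each A transcription unit is assigned one of five
evolutionary types relative to the reference map:

* identical — an exact orthologous replicate exists in the reference;
* similar — the single matching reference TU is longer, but its extra genes
  have no orthologue anywhere in A (gene loss in the A lineage, or gain in
  the reference lineage);
* split — the single matching reference TU is longer and at least one extra
  gene's orthologue sits in another A TU (TU fission through local sequence
  evolution);
* merged — A's genes map onto several reference TUs and no leftover
  reference gene has an orthologue elsewhere in A (TU fusion);
* reorganized — several reference TUs are touched and at least one leftover
  has an orthologue in another A TU (genome rearrangement).

The module also flags ancestral adjacent pairs (orthologues adjacent in the
reference or in an outgroup), groups them into chromosome fragments, traces
coding-sequence length evolution into six classes using an outgroup to
polarize changes, and attributes reference genes missing from A to loss in
the A lineage versus acquisition in the reference lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .operon import OperonMap, TranscriptionUnit
from .pairs import AdjacentPair

__all__ = [
    "OrthologyMap",
    "TUTypeCall",
    "AdjacencySource",
    "bbh_orthologs",
    "classify_tu_type",
    "classify_map_types",
    "tu_type_summary",
    "ancestral_pairs",
    "ancestral_fragments",
    "length_evolution_class",
    "loss_attribution",
    "pair_status_agreement",
    "chi2_2x2",
]


@dataclass(frozen=True)
class OrthologyMap:
    """One-to-one gene correspondences from genome A to genome B.

    ``ties`` records genes whose best hit was ambiguous (score ties broken
    lexicographically); ``ambiguous`` marks genes (typically structural
    RNAs) whose orthology cannot be established unambiguously — they are
    reported in evidence but never decide a TU-type call.
    """

    a_to_b: Mapping[str, str]
    ties: tuple[str, ...] = ()
    ambiguous: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        values = list(self.a_to_b.values())
        if len(set(values)) != len(values):
            raise ValueError("orthology map is not one-to-one")

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.a_to_b.items()}

    def get(self, gene_a: str) -> str | None:
        return self.a_to_b.get(gene_a)


def bbh_orthologs(
    similarity: Iterable[tuple[str, str, float]] | pd.DataFrame,
) -> OrthologyMap:
    """Bidirectional best hits from a (gene_a, gene_b, score) table.

    (a, b) is an ortholog pair iff b is a's highest-scoring hit and a is
    b's; score ties are broken toward the lexicographically smallest partner
    and the affected genes are reported in ``ties``.
    """
    if isinstance(similarity, pd.DataFrame):
        rows = list(similarity.itertuples(index=False, name=None))
    else:
        rows = list(similarity)
    best_a: dict[str, tuple[float, str]] = {}
    best_b: dict[str, tuple[float, str]] = {}
    tied: set[str] = set()
    for a, b, score in rows:
        score = float(score)
        for table, key, partner in ((best_a, a, b), (best_b, b, a)):
            cur = table.get(key)
            if cur is None or score > cur[0]:
                table[key] = (score, partner)
                tied.discard(key)
            elif score == cur[0] and partner != cur[1]:
                tied.add(key)
                if partner < cur[1]:
                    table[key] = (score, partner)
    pairs = {}
    for a, (_, b) in best_a.items():
        if best_b.get(b, (None, None))[1] == a:
            pairs[a] = b
    return OrthologyMap(a_to_b=pairs, ties=tuple(sorted(tied)))


# ---------------------------------------------------------------------------
# Five-class TU typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TUTypeCall:
    tu_id: str
    tu_type: str  # identical/similar/split/merged/reorganized/unclassifiable
    reference_tus: tuple[str, ...] = ()
    lost_ref_genes: tuple[str, ...] = ()
    relocated_ref_genes: tuple[str, ...] = ()
    ambiguous_ref_genes: tuple[str, ...] = ()


def _maximal_tus(ref_map: OperonMap) -> list[TranscriptionUnit]:
    """Reference TUs not strictly contained in another (nested alternatives
    collapse to their maximal form, so each A TU receives one call)."""
    tus = list(ref_map.tus)
    sets = [set(t.gene_ids) for t in tus]
    keep = []
    for i, si in enumerate(sets):
        if any(i != j and si < sj for j, sj in enumerate(sets)):
            continue
        keep.append(tus[i])
    return keep


def classify_tu_type(
    tu: TranscriptionUnit,
    map_a: OperonMap,
    ref_map: OperonMap,
    orth: OrthologyMap,
) -> TUTypeCall:
    """Assign one evolutionary type to an A transcription unit."""
    ref_tus = _maximal_tus(ref_map)
    ref_membership: dict[str, str] = {}
    ref_by_id = {}
    for rtu in ref_tus:
        ref_by_id[rtu.tu_id] = rtu
        for g in rtu.gene_ids:
            ref_membership[g] = rtu.tu_id

    orthologs = {}
    for g in tu.gene_ids:
        b = orth.get(g)
        if b is not None:
            if b not in ref_membership:
                raise ValueError(
                    f"TU {tu.tu_id}: orthologue {b} of {g} is absent from the "
                    "reference map"
                )
            orthologs[g] = b
    if not orthologs:
        return TUTypeCall(tu_id=tu.tu_id, tu_type="unclassifiable")

    touched = sorted({ref_membership[b] for b in orthologs.values()})
    matched_ref_genes = set(orthologs.values())
    leftovers = [
        g
        for tid in touched
        for g in ref_by_id[tid].gene_ids
        if g not in matched_ref_genes
    ]
    b_to_a = orth.b_to_a
    ambiguous = tuple(sorted(g for g in leftovers if g in orth.ambiguous))
    deciding = [g for g in leftovers if g not in orth.ambiguous]
    relocated = tuple(sorted(g for g in deciding if g in b_to_a))
    lost = tuple(sorted(g for g in deciding if g not in b_to_a))

    if len(touched) == 1:
        if not deciding and not ambiguous:
            tu_type = "identical"
        elif relocated:
            tu_type = "split"
        elif deciding:
            tu_type = "similar"
        else:
            # only ambiguous-orthology extras: they never decide, so the TU
            # counts as identical and the extras are reported in evidence
            tu_type = "identical"
    else:
        tu_type = "reorganized" if relocated else "merged"
    return TUTypeCall(
        tu_id=tu.tu_id,
        tu_type=tu_type,
        reference_tus=tuple(touched),
        lost_ref_genes=lost,
        relocated_ref_genes=relocated,
        ambiguous_ref_genes=ambiguous,
    )


def classify_map_types(
    map_a: OperonMap, ref_map: OperonMap, orth: OrthologyMap
) -> list[TUTypeCall]:
    return [classify_tu_type(tu, map_a, ref_map, orth) for tu in map_a.tus]


def tu_type_summary(map_a: OperonMap, calls: Sequence[TUTypeCall]) -> pd.DataFrame:
    """Per-type TU/gene/mono/poly counts (one row per evolutionary type)."""
    by_id = {tu.tu_id: tu for tu in map_a.tus}
    rows = []
    order = ["identical", "similar", "split", "merged", "reorganized", "unclassifiable"]
    for t in order:
        members = [by_id[c.tu_id] for c in calls if c.tu_type == t]
        if not members and t == "unclassifiable":
            continue
        rows.append(
            {
                "tu_type": t,
                "n_tus": len(members),
                "n_genes": sum(m.length for m in members),
                "n_monocistronic": sum(1 for m in members if not m.polycistronic),
                "n_polycistronic": sum(1 for m in members if m.polycistronic),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ancestral pairs and fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjacencySource:
    """Adjacency evidence in one other genome.

    ``adjacent`` holds unordered id pairs of that genome's adjacent genes;
    ``oriented_adjacent`` (optional, for strict synteny) holds pairs whose
    order and relative strand orientation are conserved.
    """

    name: str
    a_to_other: Mapping[str, str]
    adjacent: frozenset[frozenset[str]]
    oriented_adjacent: frozenset[tuple[str, str]] | None = None


def ancestral_pairs(
    pairs: Sequence[AdjacentPair],
    sources: Sequence[AdjacencySource],
    strict: bool = False,
) -> list[tuple[AdjacentPair, bool, str | None]]:
    """Flag pairs whose orthologues are adjacent in the reference or an outgroup.

    Sources are tried in order (reference first, then outgroups) and the
    first supporting genome is reported.  Ancestral adjacency ignores
    relative strand; ``strict`` additionally requires conserved order and
    orientation (the syntenic-fragment definition) via each source's
    ``oriented_adjacent`` set.
    """
    out = []
    for pair in pairs:
        support = None
        for src in sources:
            oa = src.a_to_other.get(pair.upstream)
            ob = src.a_to_other.get(pair.downstream)
            if oa is None or ob is None:
                continue
            if strict:
                if src.oriented_adjacent is None:
                    raise ValueError(
                        f"source {src.name}: strict mode needs oriented adjacency"
                    )
                hit = (oa, ob) in src.oriented_adjacent
            else:
                hit = frozenset((oa, ob)) in src.adjacent
            if hit:
                support = src.name
                break
        out.append((pair, support is not None, support))
    return out


def ancestral_fragments(
    flagged: Sequence[tuple[AdjacentPair, bool, str | None]],
    circular: bool = True,
) -> dict:
    """Group consecutive ancestral pairs into chromosome fragments.

    ``flagged`` must be in chromosome order (the wrap-around pair last).  A
    fragment of k pairs spans k+1 genes, except the degenerate fragment
    closing the full circle, which spans exactly the gene count.
    """
    flags = [f for _, f, _ in flagged]
    n = len(flags)
    if not any(flags):
        return {"fragments": [], "n_fragments": 0, "mean_genes": None}
    if circular and all(flags):
        frag = {"pairs": [(p.upstream, p.downstream) for p, _, _ in flagged],
                "n_pairs": n, "n_genes": n, "closes_circle": True}
        return {"fragments": [frag], "n_fragments": 1, "mean_genes": float(n)}
    # rotate so that position 0 starts a non-ancestral stretch, making runs
    # on the circle contiguous in the rotated list
    start = 0
    if circular:
        start = next(i for i in range(n) if not flags[i])
    order = [(start + i) % n for i in range(n)] if circular else list(range(n))
    fragments = []
    run: list[int] = []
    for i in order:
        if flags[i]:
            run.append(i)
        elif run:
            fragments.append(run)
            run = []
    if run:
        fragments.append(run)
    frags = []
    for run in fragments:
        frags.append(
            {
                "pairs": [
                    (flagged[i][0].upstream, flagged[i][0].downstream) for i in run
                ],
                "n_pairs": len(run),
                "n_genes": len(run) + 1,
                "closes_circle": False,
            }
        )
    total_genes = sum(f["n_genes"] for f in frags)
    return {
        "fragments": frags,
        "n_fragments": len(frags),
        "mean_genes": total_genes / len(frags),
    }


# ---------------------------------------------------------------------------
# Coding-sequence length evolution
# ---------------------------------------------------------------------------

def length_evolution_class(
    l_a: float, l_ref: float, l_out: float | None
) -> int | None:
    """Six-way polarized classification of coding-length change.

    With d = L_ref - L_a, d1 = |L_out - L_a| and d2 = |L_ref - L_out|:
    1 — same length in both lineages (d = 0);
    2 — length increased in the reference lineage (d1 < d2, d > 0);
    3 — length decreased in the reference lineage (d1 < d2, d < 0);
    4 — length increased in the A lineage (d1 > d2, d > 0);
    5 — length decreased in the A lineage (d1 > d2, d < 0);
    6 — the changing lineage cannot be identified (d1 = d2, d != 0).
    Returns None (unclassified) when the outgroup length is missing and the
    lengths differ; never a silent class.
    """
    if l_a <= 0 or l_ref <= 0 or (l_out is not None and l_out <= 0):
        raise ValueError("sequence lengths must be positive")
    d = l_ref - l_a
    if d == 0:
        return 1
    if l_out is None:
        return None
    d1 = abs(l_out - l_a)
    d2 = abs(l_ref - l_out)
    if d1 < d2:
        return 2 if d > 0 else 3
    if d1 > d2:
        return 4 if d > 0 else 5
    return 6


def loss_attribution(evidence: Mapping[str, bool | None]) -> str:
    """Fate of a reference gene absent from genome A.

    Presence in any ancestral reconstruction or outgroup implies the gene
    existed in the common ancestor and was lost in the A lineage; absence
    everywhere outside the reference implies acquisition in the reference
    lineage; no usable evidence leaves the call ambiguous.
    """
    usable = {k: v for k, v in evidence.items() if v is not None}
    if not usable:
        return "ambiguous"
    if any(usable.values()):
        return "lost_in_A"
    return "acquired_in_reference"


def pair_status_agreement(
    status_a: Mapping[frozenset, str], status_b: Mapping[frozenset, str]
) -> dict:
    """Compare STU/DTU status of conserved gene pairs across two genomes.

    ``status_a``/``status_b`` map a conserved pair (any hashable key shared
    between the two genomes, e.g. a frozenset of ortholog-resolved ids) to
    its co-transcription status in that genome.  Only keys present in both
    are compared.  Returns counts and fractions of pairs co-transcribed in
    both, separate in both, and of opposite status.
    """
    shared = sorted(set(status_a) & set(status_b), key=repr)
    n = len(shared)
    both_stu = sum(1 for k in shared if status_a[k] == status_b[k] == "STU")
    both_dtu = sum(1 for k in shared if status_a[k] == status_b[k] == "DTU")
    opposite = n - both_stu - both_dtu
    return {
        "n": n,
        "both_stu": both_stu,
        "both_dtu": both_dtu,
        "opposite": opposite,
        "frac_both_stu": both_stu / n if n else None,
        "frac_both_dtu": both_dtu / n if n else None,
        "frac_opposite": opposite / n if n else None,
    }


def chi2_2x2(table: Sequence[Sequence[int]], correction: bool = True) -> dict:
    """Chi-square test on a 2x2 contingency table (e.g. gene conservation
    versus specific regulation of the orthologous TU)."""
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=correction)
    return {"chi2": float(chi2), "p_value": float(p), "dof": int(dof)}
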