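"""Readers and writers for the external formats the toolkit consumes and produces.

Everything downstream operates on the in-memory types defined here:

* :class:`GenomeAnnotation` — ordered, stranded gene coordinates on a (usually
  circular) bacterial replicon, read from GenBank or GFF3;
* :class:`TerminatorCall` — a predicted Rho-independent terminator (GC-rich
  hairpin + U-rich tail), read from TransTermHP plain-text output or a TSV;
* :class:`KnownTUTable` — curated transcription units (RegulonDB-style) used
  for training, with their evidence class and leader-peptide flag.

Coordinates are 1-based and inclusive everywhere internally (the GenBank
convention); GFF3 is also 1-based inclusive so no conversion is needed at
that boundary.  TSV dialect: tab-separated, header row, UTF-8, ``.`` for
missing values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "TerminatorCall",
    "KnownTU",
    "KnownTUTable",
    "AnnotationError",
    "ParseError",
    "read_annotation",
    "write_annotation",
    "read_terminators",
    "write_terminators",
    "read_known_tus",
    "write_known_tus",
    "write_operon_map",
    "read_operon_map",
]

MISSING = "."


class ParseError(ValueError):
    """An input file does not conform to its declared dialect."""


class AnnotationError(ValueError):
    """An annotation or a cross-reference into one violates an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """A single gene on the replicon.

    ``start``/``end`` are 1-based inclusive with ``end >= start`` regardless
    of strand; ``kind`` distinguishes protein-coding genes from structural
    RNAs (tRNA/rRNA/ncRNA), both of which participate in the pair universe.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise AnnotationError(
                f"{self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.kind not in ("CDS", "RNA"):
            raise AnnotationError(f"{self.gene_id}: bad kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeAnnotation:
    """An ordered gene list on one replicon.

    Genes are kept sorted strictly by start coordinate; gene ids are unique.
    ``circular`` defaults to True, matching bacterial chromosomes.
    """

    replicon_id: str
    length: int
    genes: tuple[GeneRecord, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        genes = tuple(sorted(self.genes, key=lambda g: (g.start, g.end)))
        object.__setattr__(self, "genes", genes)
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.end > self.length:
                raise AnnotationError(
                    f"{g.gene_id}: end {g.end} beyond replicon length {self.length}"
                )
        starts = [g.start for g in genes]
        if len(set(starts)) != len(starts):
            raise AnnotationError("two genes share a start coordinate")

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {g.gene_id: g for g in self.genes}
            )
            return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        try:
            self.gene(gene_id)
            return True
        except KeyError:
            return False

    def restrict(self, kinds: Iterable[str]) -> "GenomeAnnotation":
        """Annotation restricted to the given gene kinds (e.g. CDS only)."""
        kinds = set(kinds)
        return replace(
            self, genes=tuple(g for g in self.genes if g.kind in kinds)
        )


@dataclass(frozen=True)
class TerminatorCall:
    """A predicted Rho-independent terminator.

    ``confidence`` is the predictor's 0-100 score; ``hairpin_energy`` the
    hairpin free energy in kcal/mol (non-positive for a stable stem).
    Coordinates are normalized so that ``start <= end``.
    """

    start: int
    end: int
    strand: str
    confidence: float
    hairpin_energy: float = 0.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            object.__setattr__(self, "start", self.end)
            object.__setattr__(self, "end", max(self.start, self.end))
        if not 0.0 <= self.confidence <= 100.0:
            raise ParseError(
                f"terminator confidence {self.confidence} outside [0, 100]"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"bad terminator strand {self.strand!r}")


@dataclass(frozen=True)
class KnownTU:
    tu_id: str
    gene_ids: tuple[str, ...]
    evidence: str  # {experimental, computational}
    leader_peptide: bool = False

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise AnnotationError(f"TU {self.tu_id}: empty gene list")
        if self.evidence not in ("experimental", "computational"):
            raise AnnotationError(
                f"TU {self.tu_id}: bad evidence {self.evidence!r}"
            )

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class KnownTUTable:
    tus: tuple[KnownTU, ...]

    def __iter__(self):
        return iter(self.tus)

    def __len__(self) -> int:
        return len(self.tus)

    def validate_against(self, annotation: GenomeAnnotation) -> None:
        """Raise if any TU references a gene missing from the annotation."""
        missing = sorted(
            {
                gid
                for tu in self.tus
                for gid in tu.gene_ids
                if gid not in annotation
            }
        )
        if missing:
            raise AnnotationError(
                "TU table references genes absent from the annotation: "
                + ", ".join(missing)
            )

    def experimental(self) -> "KnownTUTable":
        return KnownTUTable(
            tuple(t for t in self.tus if t.evidence == "experimental")
        )


# ---------------------------------------------------------------------------
# Annotation readers
# ---------------------------------------------------------------------------

_RNA_FEATURES = {"tRNA", "rRNA", "ncRNA", "tmRNA", "misc_RNA"}


def read_annotation(path: str | Path, format: str = "genbank") -> GenomeAnnotation:
    """Read a genome annotation from GenBank or GFF3.

    Genes are returned sorted by start; the circular flag is taken from the
    record metadata where present and defaults to True otherwise.
    """
    path = Path(path)
    if format == "genbank":
        ann = _read_genbank(path)
    elif format == "gff3":
        ann = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if len(ann) == 0:
        raise ParseError(f"{path}: annotation contains no genes")
    return ann


def _read_genbank(path: Path) -> GenomeAnnotation:
    from Bio import SeqIO

    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise ParseError(f"{path}: no GenBank records found") from None
    topology = record.annotations.get("topology", "circular")
    genes: list[GeneRecord] = []
    for feat in record.features:
        if feat.type == "CDS":
            kind = "CDS"
        elif feat.type in _RNA_FEATURES:
            kind = "RNA"
        else:
            continue
        quals = feat.qualifiers
        gene_id = (
            quals.get("locus_tag", quals.get("gene", quals.get("protein_id", [None])))
        )[0]
        if gene_id is None:
            raise ParseError(f"{path}: {feat.type} feature without an id")
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=int(feat.location.start) + 1,  # Biopython is 0-based
                end=int(feat.location.end),
                strand="+" if feat.location.strand >= 0 else "-",
                kind=kind,
                name=quals.get("gene", [None])[0],
            )
        )
    return GenomeAnnotation(
        replicon_id=record.id,
        length=len(record.seq) if record.seq is not None else max(g.end for g in genes),
        genes=tuple(genes),
        circular=(topology != "linear"),
    )


_GFF_ATTR_ID_KEYS = ("ID", "locus_tag", "gene_id", "Name")


def _gff_attrs(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path) -> GenomeAnnotation:
    genes: list[GeneRecord] = []
    replicon = None
    length = 0
    circular = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    replicon = parts[1]
                    length = int(parts[3])
                continue
            if not line or line.startswith("#"):
                if "Is_circular=false" in line:
                    circular = False
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype == "CDS":
                kind = "CDS"
            elif ftype in _RNA_FEATURES:
                kind = "RNA"
            elif ftype == "region":
                attr = _gff_attrs(attrs)
                if attr.get("Is_circular", "true").lower() == "false":
                    circular = False
                length = max(length, int(end))
                continue
            else:
                continue
            attr = _gff_attrs(attrs)
            gene_id = next(
                (attr[k] for k in _GFF_ATTR_ID_KEYS if k in attr), None
            )
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: feature without an ID attribute")
            replicon = replicon or seqid
            try:
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        kind=kind,
                        name=attr.get("gene"),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not genes:
        raise ParseError(f"{path}: annotation contains no genes")
    length = max(length, max(g.end for g in genes))
    return GenomeAnnotation(
        replicon_id=replicon or "unknown",
        length=length,
        genes=tuple(genes),
        circular=circular,
    )


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (round-trips through :func:`read_annotation`)."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {annotation.replicon_id} 1 {annotation.length}\n"
        )
        fh.write(
            "\t".join(
                [
                    annotation.replicon_id,
                    "dister",
                    "region",
                    "1",
                    str(annotation.length),
                    MISSING,
                    "+",
                    MISSING,
                    f"ID=region0;Is_circular={str(annotation.circular).lower()}",
                ]
            )
            + "\n"
        )
        for g in annotation.genes:
            ftype = "CDS" if g.kind == "CDS" else "ncRNA"
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";gene={g.name}"
            fh.write(
                "\t".join(
                    [
                        annotation.replicon_id,
                        "dister",
                        ftype,
                        str(g.start),
                        str(g.end),
                        MISSING,
                        g.strand,
                        MISSING,
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Terminator readers
# ---------------------------------------------------------------------------

# TransTermHP "TERM" line, e.g.
#   TERM 19  15310 - 15327  + F    96  -11.2 -4.0 | opp_overlap 15310
_TERM_RE = re.compile(
    r"^\s*TERM\s+\S+\s+(\d+)\s*-\s*(\d+)\s+([+-])\s+\S+\s+"
    r"([0-9]+(?:\.[0-9]+)?)\s+(-?[0-9]+(?:\.[0-9]+)?)"
)


def read_terminators(path: str | Path, format: str = "transtermhp") -> list[TerminatorCall]:
    """Read predicted terminators from TransTermHP output or a 5-column TSV.

    TransTermHP mode scans for ``TERM`` lines; everything else in the report
    is ignored.  Coordinates are normalized so start <= end (TransTermHP
    prints minus-strand terminators with descending coordinates).
    """
    path = Path(path)
    calls: list[TerminatorCall] = []
    if format == "transtermhp":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.lstrip().startswith("TERM"):
                    continue
                m = _TERM_RE.match(line)
                if m is None:
                    raise ParseError(
                        f"{path}:{lineno}: unparseable TERM line: {line.strip()!r}"
                    )
                s, e = int(m.group(1)), int(m.group(2))
                calls.append(
                    TerminatorCall(
                        start=min(s, e),
                        end=max(s, e),
                        strand=m.group(3),
                        confidence=float(m.group(4)),
                        hairpin_energy=float(m.group(5)),
                    )
                )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"start", "end", "strand", "confidence", "hairpin_energy"}
        if not required.issubset(df.columns):
            raise ParseError(
                f"{path}: terminator TSV needs columns {sorted(required)}"
            )
        for row in df.itertuples(index=False):
            s, e = int(row.start), int(row.end)
            calls.append(
                TerminatorCall(
                    start=min(s, e),
                    end=max(s, e),
                    strand=str(row.strand),
                    confidence=float(row.confidence),
                    hairpin_energy=float(row.hairpin_energy),
                )
            )
    else:
        raise ValueError(f"unknown terminator format {format!r}")
    return calls


def write_terminators(calls: Sequence[TerminatorCall], path: str | Path) -> None:
    """Write terminator calls as the 5-column TSV dialect."""
    df = pd.DataFrame(
        {
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "strand": [c.strand for c in calls],
            "confidence": [c.confidence for c in calls],
            "hairpin_energy": [c.hairpin_energy for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Known-TU table I/O
# ---------------------------------------------------------------------------

def read_known_tus(path: str | Path) -> KnownTUTable:
    """Read a curated TU table (tu_id, comma-joined genes, evidence, leader flag)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tu_id", "gene_ids", "evidence", "leader_peptide"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: TU TSV needs columns {sorted(required)}")
    tus = []
    for row in df.itertuples(index=False):
        tus.append(
            KnownTU(
                tu_id=row.tu_id,
                gene_ids=tuple(row.gene_ids.split(",")),
                evidence=row.evidence,
                leader_peptide=str(row.leader_peptide).lower()
                in ("true", "1", "yes"),
            )
        )
    return KnownTUTable(tuple(tus))


def write_known_tus(table: KnownTUTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "tu_id": [t.tu_id for t in table],
            "gene_ids": [",".join(t.gene_ids) for t in table],
            "evidence": [t.evidence for t in table],
            "leader_peptide": [str(t.leader_peptide) for t in table],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operon-map export (the OperonMap type lives in dister.operon)
# ---------------------------------------------------------------------------

def write_operon_map(operon_map, path: str | Path, format: str = "tsv") -> None:
    """Write an assembled operon map as TSV or as GFF3 (one feature per TU)."""
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            {
                "tu_id": [tu.tu_id for tu in operon_map.tus],
                "gene_ids": [",".join(tu.gene_ids) for tu in operon_map.tus],
                "strand": [tu.strand for tu in operon_map.tus],
                "length": [tu.length for tu in operon_map.tus],
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        if operon_map.annotation is None:
            raise AnnotationError("GFF3 export needs the map's annotation attached")
        ann = operon_map.annotation
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("##gff-version 3\n")
            fh.write(
                f"##sequence-region {ann.replicon_id} 1 {ann.length}\n"
            )
            for tu in operon_map.tus:
                coords = [ann.gene(g) for g in tu.gene_ids]
                start = min(c.start for c in coords)
                end = max(c.end for c in coords)
                fh.write(
                    "\t".join(
                        [
                            ann.replicon_id,
                            "dister",
                            "transcription_unit",
                            str(start),
                            str(end),
                            MISSING,
                            tu.strand,
                            MISSING,
                            f"ID={tu.tu_id};genes={','.join(tu.gene_ids)}",
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown operon map format {format!r}")


def read_operon_map(path: str | Path, annotation: GenomeAnnotation | None = None):
    """Read a TSV operon map back into an :class:`dister.operon.OperonMap`."""
    from .operon import OperonMap, TranscriptionUnit

    df = pd.read_csv(path, sep="\t", dtype=str)
    tus = tuple(
        TranscriptionUnit(
            tu_id=row.tu_id,
            gene_ids=tuple(row.gene_ids.split(",")),
            strand=row.strand,
        )
        for row in df.itertuples(index=False)
    )
    if annotation is not None:
        missing = sorted(
            {g for tu in tus for g in tu.gene_ids if g not in annotation}
        )
        if missing:
            raise AnnotationError(
                "operon map references genes absent from the annotation: "
                + ", ".join(missing)
            )
    replicon = annotation.replicon_id if annotation is not None else "unknown"
    return OperonMap(
        replicon_id=replicon,
        tus=tus,
        annotation=annotation,
        provenance={"source": str(path)},
        validate_partition=False,
    )
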