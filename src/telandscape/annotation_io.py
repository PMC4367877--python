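"""Genome annotation input: GenBank, EMBL, and the native tab-separated dialect.

Produces a :class:`GenomeAnnotation` — an ordered list of chromosomes, each
carrying typed gene features (gene, exon, pseudogene, miscRNA, UTRs) with
1-based inclusive coordinates.  GenBank and EMBL parsing is delegated to
Biopython; the native dialect is a small TSV defined here (see
:data:`NATIVE_ANNOTATION_COLUMNS`).

Conventions applied at the boundary:

* a ``gene`` feature's span is its outermost annotated coordinates — introns
  and UTRs inside count as gene body for proximity purposes;
* compound ``join(...)`` locations are flattened to the enclosing span, and
  each segment of a gene/mRNA join is additionally emitted as an ``exon``;
* ``complement(a..b)`` yields strand ``-`` with unchanged coordinates;
* the NCBI numeric GeneID is taken from a ``/db_xref="GeneID:n"`` qualifier
  when present and is what links a gene to its gene2go annotations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .core_model import FORWARD, REVERSE, UNSTRANDED, SeqRegion

#: the closed set of feature kinds the analyses know about
FEATURE_KINDS = frozenset(
    {"gene", "exon", "pseudogene", "miscRNA", "five_prime_UTR", "three_prime_UTR"}
)

#: column order of the native annotation dialect (tab-separated, '#' comments)
NATIVE_ANNOTATION_COLUMNS = (
    "chrom",
    "start",
    "end",
    "strand",
    "kind",
    "gene_name",
    "gene_numeric_id",
)

_GENBANK_KIND_MAP = {
    "gene": "gene",
    "exon": "exon",
    "misc_RNA": "miscRNA",
    "5'UTR": "five_prime_UTR",
    "3'UTR": "three_prime_UTR",
}


class AnnotationFormatError(ValueError):
    """Malformed annotation input (bad header, bad coordinates, bad kind)."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated object: a gene, exon, pseudogene, miscRNA or UTR."""

    feature_id: str
    gene_name: str
    kind: str
    region: SeqRegion
    gene_numeric_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise AnnotationFormatError(
                f"unknown feature kind {self.kind!r}; valid kinds: {sorted(FEATURE_KINDS)}"
            )


@dataclass
class ChromosomeRecord:
    chrom_id: str
    length: int
    organism: str
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            self._check(f)

    def _check(self, f: GeneFeature) -> None:
        if f.region.chrom != self.chrom_id:
            raise AnnotationFormatError(
                f"feature {f.feature_id} is on {f.region.chrom}, not {self.chrom_id}"
            )
        if f.region.end > self.length:
            raise AnnotationFormatError(
                f"feature {f.feature_id} ends at {f.region.end}, past the "
                f"{self.length} bp of {self.chrom_id}"
            )


@dataclass
class GenomeAnnotation:
    organism: str
    chromosomes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chrom_id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise AnnotationFormatError(f"duplicate chromosome ids in genome: {ids}")

    def chromosome(self, chrom_id: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c
        raise KeyError(f"unknown chromosome {chrom_id!r}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def sniff_annotation_dialect(path) -> str:
    """Guess the dialect from the first non-blank line's leading token."""
    with open(path) as fh:
        for line in fh:
            token = line.split()[0] if line.split() else ""
            if not token:
                continue
            if token == "LOCUS":
                return "genbank"
            if token == "ID":
                return "embl"
            return "native"
    raise AnnotationFormatError(f"{path}: file is empty")


def read_annotation(path, dialect: str = "auto") -> GenomeAnnotation:
    """Parse an annotation file into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    path : path-like
        Annotation file; multi-record files yield one chromosome per record.
    dialect : {"genbank", "embl", "native", "auto"}
        ``auto`` sniffs by the first header token (``LOCUS`` -> GenBank,
        ``ID`` -> EMBL, anything else -> native TSV).
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise AnnotationFormatError(f"{path}: missing or empty annotation file")
    if dialect == "auto":
        dialect = sniff_annotation_dialect(path)
    if dialect == "native":
        return _read_native(path)
    if dialect not in ("genbank", "embl"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    try:
        records = list(SeqIO.parse(str(path), dialect))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise AnnotationFormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    if not records:
        raise AnnotationFormatError(f"{path}: no {dialect} records found")
    chroms = [_record_to_chromosome(rec) for rec in records]
    organism = chroms[0].organism
    return GenomeAnnotation(organism=organism, chromosomes=chroms)


def _strand_of(location) -> str:
    if location.strand == 1:
        return FORWARD
    if location.strand == -1:
        return REVERSE
    return UNSTRANDED


def _record_to_chromosome(rec: SeqRecord) -> ChromosomeRecord:
    organism = rec.annotations.get("organism", "") or "unknown"
    length = len(rec.seq) if rec.seq is not None else 0
    chrom_id = rec.id or rec.name
    features: list[GeneFeature] = []
    counter = 0
    for feat in rec.features:
        if feat.type == "source":
            org = feat.qualifiers.get("organism", [None])[0]
            if org:
                organism = org
            continue
        kind = _classify_genbank_feature(feat)
        parts = feat.location.parts if feat.location is not None else []
        if not parts:
            continue
        span_start = min(int(p.start) for p in parts) + 1  # 0-based -> 1-based
        span_end = max(int(p.end) for p in parts)
        if span_end < span_start:
            raise AnnotationFormatError(
                f"{chrom_id}: feature {feat.type} has end < start "
                f"({span_end} < {span_start})"
            )
        strand = _strand_of(feat.location)
        name = _gene_name(feat)
        numeric = _gene_numeric_id(feat)
        if kind is not None:
            counter += 1
            features.append(
                GeneFeature(
                    feature_id=f"{chrom_id}.{kind}.{counter}",
                    gene_name=name,
                    kind=kind,
                    region=SeqRegion(chrom_id, span_start, span_end, strand),
                    gene_numeric_id=numeric,
                )
            )
        # join() segments of genes and mRNAs double as exons
        if feat.type in ("gene", "mRNA") and len(parts) > 1:
            for p in parts:
                counter += 1
                features.append(
                    GeneFeature(
                        feature_id=f"{chrom_id}.exon.{counter}",
                        gene_name=name,
                        kind="exon",
                        region=SeqRegion(chrom_id, int(p.start) + 1, int(p.end), strand),
                        gene_numeric_id=numeric,
                    )
                )
    return ChromosomeRecord(chrom_id=chrom_id, length=length, organism=organism, features=features)


def _classify_genbank_feature(feat: SeqFeature) -> Optional[str]:
    if feat.type == "gene" and ("pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers):
        return "pseudogene"
    return _GENBANK_KIND_MAP.get(feat.type)


def _gene_name(feat: SeqFeature) -> str:
    for key in ("locus_tag", "gene", "standard_name", "note"):
        val = feat.qualifiers.get(key)
        if val:
            return str(val[0])
    return ""


def _gene_numeric_id(feat: SeqFeature) -> Optional[int]:
    for xref in feat.qualifiers.get("db_xref", []):
        if xref.startswith("GeneID:"):
            try:
                return int(xref.split(":", 1)[1])
            except ValueError:
                return None
    return None


def _read_native(path: Path) -> GenomeAnnotation:
    """Native annotation dialect: tab-separated features plus '#' pragmas.

    Two pragma comments carry what the flat-file formats put in headers::

        #organism\tArabidopsis thaliana
        #chromosome\tChr1\t30427671

    followed by one feature per line in :data:`NATIVE_ANNOTATION_COLUMNS`
    order (``gene_numeric_id`` may be empty).
    """
    organism = "unknown"
    chrom_meta: dict[str, int] = {}
    feats_by_chrom: dict[str, list[GeneFeature]] = {}
    counters: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if fields[0] == "organism" and len(fields) >= 2:
                    organism = fields[1]
                elif fields[0] == "chromosome" and len(fields) >= 3:
                    chrom_meta[fields[1]] = int(fields[2])
                    feats_by_chrom.setdefault(fields[1], [])
                continue
            fields = line.split("\t")
            if len(fields) != len(NATIVE_ANNOTATION_COLUMNS):
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected {len(NATIVE_ANNOTATION_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, strand, kind, gene_name, numeric_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationFormatError(f"{path}:{lineno}: bad coordinates") from exc
            if end < start:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: feature {gene_name!r} has end < start"
                )
            if kind not in FEATURE_KINDS:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: unknown kind {kind!r}; valid: {sorted(FEATURE_KINDS)}"
                )
            counters[chrom] = counters.get(chrom, 0) + 1
            feats_by_chrom.setdefault(chrom, []).append(
                GeneFeature(
                    feature_id=f"{chrom}.{kind}.{counters[chrom]}",
                    gene_name=gene_name,
                    kind=kind,
                    region=SeqRegion(chrom, start, end, strand),
                    gene_numeric_id=int(numeric_s) if numeric_s else None,
                )
            )
    chromosomes = []
    for chrom, feats in feats_by_chrom.items():
        length = chrom_meta.get(chrom, max((f.region.end for f in feats), default=0))
        chromosomes.append(
            ChromosomeRecord(chrom_id=chrom, length=length, organism=organism, features=feats)
        )
    if not chromosomes:
        raise AnnotationFormatError(f"{path}: no chromosomes declared")
    return GenomeAnnotation(organism=organism, chromosomes=chromosomes)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def extract_features(rec: ChromosomeRecord, kinds: Iterable[str]) -> list:
    """Features of the requested kinds, sorted by (start, end)."""
    kinds = set(kinds)
    if not kinds:
        raise ValueError("kinds must be non-empty")
    unknown = kinds - FEATURE_KINDS
    if unknown:
        raise ValueError(
            f"unknown feature kinds {sorted(unknown)}; valid kinds: {sorted(FEATURE_KINDS)}"
        )
    picked = [f for f in rec.features if f.kind in kinds]
    return sorted(picked, key=lambda f: (f.region.start, f.region.end))


# ---------------------------------------------------------------------------
# writing (round-trip support for the synthetic generator)
# ---------------------------------------------------------------------------

def to_seqrecords(genome: GenomeAnnotation) -> list:
    """Render a GenomeAnnotation as Biopython SeqRecords (undefined sequence).

    Only coordinates matter downstream, so the sequence is a run of ``n``.
    """
    records = []
    for chrom in genome.chromosomes:
        rec = SeqRecord(
            Seq("n" * chrom.length),
            id=chrom.chrom_id,
            name=chrom.chrom_id,
            description=f"{genome.organism} {chrom.chrom_id}",
            annotations={
                "organism": genome.organism,
                "molecule_type": "DNA",
                "topology": "linear",
            },
        )
        rec.features.append(
            SeqFeature(
                SimpleLocation(0, chrom.length),
                type="source",
                qualifiers={"organism": [genome.organism]},
            )
        )
        for f in chrom.features:
            strand = {FORWARD: 1, REVERSE: -1, UNSTRANDED: None}[f.region.strand]
            quals: dict = {"locus_tag": [f.gene_name]}
            if f.gene_numeric_id is not None:
                quals["db_xref"] = [f"GeneID:{f.gene_numeric_id}"]
            gb_type = {
                "gene": "gene",
                "pseudogene": "gene",
                "exon": "exon",
                "miscRNA": "misc_RNA",
                "five_prime_UTR": "5'UTR",
                "three_prime_UTR": "3'UTR",
            }[f.kind]
            if f.kind == "pseudogene":
                quals["pseudo"] = [""]
            rec.features.append(
                SeqFeature(
                    SimpleLocation(f.region.start - 1, f.region.end, strand=strand),
                    type=gb_type,
                    qualifiers=quals,
                )
            )
        records.append(rec)
    return records


def write_annotation(genome: GenomeAnnotation, path, dialect: str) -> None:
    """Write a GenomeAnnotation as GenBank, EMBL, or the native TSV."""
    path = Path(path)
    if dialect in ("genbank", "embl"):
        SeqIO.write(to_seqrecords(genome), str(path), dialect)
        return
    if dialect != "native":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"#organism\t{genome.organism}\n")
        for chrom in genome.chromosomes:
            fh.write(f"#chromosome\t{chrom.chrom_id}\t{chrom.length}\n")
        fh.write("#" + "\t".join(NATIVE_ANNOTATION_COLUMNS) + "\n")
        for chrom in genome.chromosomes:
            for f in chrom.features:
                numeric = "" if f.gene_numeric_id is None else str(f.gene_numeric_id)
                fh.write(
                    "\t".join(
                        [
                            f.region.chrom,
                            str(f.region.start),
                            str(f.region.end),
                            f.region.strand,
                            f.kind,
                            f.gene_name,
                            numeric,
                        ]
                    )
                    + "\n"
                )
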