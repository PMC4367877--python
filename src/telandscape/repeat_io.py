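"""Repeat-hit input: RepeatMasker, Censor, BLAST tabular, Repet, and native TSV.

Every dialect is reduced to the same canonical record, :class:`TECopy` — one
genomic occurrence of a named TE family with its percent similarity to the
family consensus.  Dialect-specific conventions (RepeatMasker reports
*divergence*, Censor may report a fractional similarity, BLAST reports percent
identity) are converted at the boundary:

==============  =====================================================
dialect         similarity =
==============  =====================================================
repeatmasker    100 - "% div" column
censor          similarity column, x100 when given as a fraction <= 1
abblast         percent-identity column
ncbiblast       pident column (outfmt 6)
repet           percent-identity column
native          explicit similarity column
==============  =====================================================

Hits are kept exactly as reported — overlapping or nested copies are never
merged, so fragmented copies stay individually visible downstream.

Column maps for the tabular dialects accepted here:

* **ncbiblast** — the 12 standard ``outfmt 6`` columns; the genome is the
  query (qseqid = chromosome) and the consensus the subject (sseqid =
  family); ``qstart > qend`` means a reverse-strand hit.
* **abblast** — 10 whitespace-separated columns: query, subject,
  percent-identity, alignment-length, qstart, qend, sstart, send, E-value,
  score.  Other column counts are rejected loudly.
* **repet** — 7 tab-separated columns: chrom, start, end, strand, family,
  percent-identity, score.
* **censor** — 10 whitespace-separated columns: chrom, start, end, family,
  rstart, rend, orientation (``d``/``c``), similarity, positives, score.
* **native** — 7 tab-separated columns: chrom, start, end, strand, family,
  superfamily, similarity ('#' comments allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .core_model import FORWARD, REVERSE, SeqRegion

REPEAT_DIALECTS = ("repeatmasker", "censor", "abblast", "ncbiblast", "repet", "native")


class RepeatFormatError(ValueError):
    """A hit line that cannot be interpreted in the declared dialect."""


@dataclass(frozen=True)
class TECopy:
    """One repeat hit: a TE family occurrence at a genomic location."""

    family: str
    region: SeqRegion
    similarity: float
    source: str
    superfamily: Optional[str] = None
    score: Optional[float] = None
    class_label: Optional[str] = None  # RepeatMasker class/family column, kept for fallback

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 100.0:
            raise RepeatFormatError(
                f"similarity {self.similarity} outside [0, 100] for {self.family}"
            )


@dataclass(frozen=True)
class SuperfamilyTable:
    """Case-insensitive family -> superfamily mapping; misses resolve to Unknown."""

    mapping: dict  # lowercased family -> superfamily
    provenance: str = ""

    def lookup(self, family: str) -> str:
        return self.mapping.get(family.lower(), "Unknown")

    def __contains__(self, family: str) -> bool:
        return family.lower() in self.mapping


def similarity_from_divergence(div: float) -> float:
    """Percent similarity from a RepeatMasker percent divergence."""
    if not 0.0 <= div <= 100.0:
        raise ValueError(f"divergence {div} outside [0, 100]")
    return 100.0 - div


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def sniff_repeat_dialect(path) -> str:
    """Guess the hit-file dialect.

    RepeatMasker is recognised by its banner header; otherwise the first data
    line's column count decides (12 -> BLAST tabular, 10 with a ``d``/``c``
    orientation column -> Censor, anything else -> native TSV).  ``abblast``
    and ``repet`` are never sniffed — name them explicitly.
    """
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            tokens = stripped.split()
            if tokens[0] in ("SW", "score") or stripped.startswith("   SW"):
                return "repeatmasker"
            if stripped.startswith("#"):
                continue
            if len(tokens) == 12:
                return "ncbiblast"
            if len(tokens) == 10 and tokens[6] in ("d", "c"):
                return "censor"
            return "native"
    raise RepeatFormatError(f"{path}: file is empty")


def read_repeats(path, dialect: str = "auto") -> list:
    """Parse a repeat-hit file into a list of :class:`TECopy`.

    Comment and header lines are skipped; one record is produced per hit
    line.  Errors carry the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = sniff_repeat_dialect(path)
    if dialect not in REPEAT_DIALECTS:
        raise ValueError(f"unknown repeat dialect {dialect!r}; know {REPEAT_DIALECTS}")
    parser = {
        "repeatmasker": _parse_repeatmasker_line,
        "censor": _parse_censor_line,
        "abblast": _parse_abblast_line,
        "ncbiblast": _parse_ncbiblast_line,
        "repet": _parse_repet_line,
        "native": _parse_native_line,
    }[dialect]
    copies: list[TECopy] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "repeatmasker" and _is_repeatmasker_header(line):
                continue
            try:
                copies.append(parser(line))
            except RepeatFormatError:
                raise
            except Exception as exc:
                raise RepeatFormatError(f"{path}:{lineno}: {exc}") from exc
    return copies


def _is_repeatmasker_header(line: str) -> bool:
    first = line.split()[0]
    return first in ("SW", "score", "bit")


def _parse_repeatmasker_line(line: str) -> TECopy:
    # score div del ins query qbegin qend (left) strand name class/family ...
    t = line.split()
    if len(t) < 11:
        raise ValueError(f"RepeatMasker line has {len(t)} columns, need >= 11")
    score = float(t[0])
    div = float(t[1])
    chrom, qbegin, qend = t[4], int(t[5]), int(t[6])
    strand = REVERSE if t[8] in ("C", "c") else FORWARD
    family, class_label = t[9], t[10]
    return TECopy(
        family=family,
        region=SeqRegion(chrom, qbegin, qend, strand),
        similarity=similarity_from_divergence(div),
        source="repeatmasker",
        score=score,
        class_label=class_label,
    )


def _parse_censor_line(line: str) -> TECopy:
    t = line.split()
    if len(t) != 10:
        raise ValueError(f"Censor map line has {len(t)} columns, need 10")
    chrom, start, end, family = t[0], int(t[1]), int(t[2]), t[3]
    strand = REVERSE if t[6] in ("c", "C", "-") else FORWARD
    sim = float(t[7])
    if sim <= 1.0:  # fractional similarity
        sim *= 100.0
    return TECopy(
        family=family,
        region=SeqRegion(chrom, start, end, strand),
        similarity=sim,
        source="censor",
        score=float(t[9]),
    )


def _oriented(chrom: str, a: int, b: int) -> SeqRegion:
    if a > b:
        return SeqRegion(chrom, b, a, REVERSE)
    return SeqRegion(chrom, a, b, FORWARD)


def _parse_ncbiblast_line(line: str) -> TECopy:
    t = line.split()
    if len(t) != 12:
        raise ValueError(f"BLAST outfmt-6 line has {len(t)} columns, need 12")
    chrom, family, pident = t[0], t[1], float(t[2])
    region = _oriented(chrom, int(t[6]), int(t[7]))
    if int(t[8]) > int(t[9]):  # reverse orientation may be carried by the subject
        region = replace(region, strand=REVERSE)
    return TECopy(
        family=family,
        region=region,
        similarity=pident,
        source="ncbiblast",
        score=float(t[11]),
    )


def _parse_abblast_line(line: str) -> TECopy:
    t = line.split()
    if len(t) != 10:
        raise ValueError(f"AB-BLAST tabular line has {len(t)} columns, need 10")
    chrom, family, pident = t[0], t[1], float(t[2])
    region = _oriented(chrom, int(t[4]), int(t[5]))
    if int(t[6]) > int(t[7]):
        region = replace(region, strand=REVERSE)
    return TECopy(
        family=family,
        region=region,
        similarity=pident,
        source="abblast",
        score=float(t[9]),
    )


def _parse_repet_line(line: str) -> TECopy:
    t = line.split("\t")
    if len(t) != 7:
        raise ValueError(f"Repet line has {len(t)} columns, need 7")
    chrom, start, end, strand, family, pident, score = t
    return TECopy(
        family=family,
        region=SeqRegion(chrom, int(start), int(end), strand),
        similarity=float(pident),
        source="repet",
        score=float(score),
    )


def _parse_native_line(line: str) -> TECopy:
    t = line.split("\t")
    if len(t) != 7:
        raise ValueError(f"native repeat line has {len(t)} columns, need 7")
    chrom, start, end, strand, family, superfamily, sim = t
    return TECopy(
        family=family,
        region=SeqRegion(chrom, int(start), int(end), strand),
        similarity=float(sim),
        source="native",
        superfamily=superfamily or None,
    )


# ---------------------------------------------------------------------------
# superfamily assignment
# ---------------------------------------------------------------------------

def load_superfamily_table(path) -> SuperfamilyTable:
    """Two-column TSV (family, superfamily); '#' comments allowed.

    Duplicate family keys are tolerated only when they agree.
    """
    mapping: dict[str, str] = {}
    provenance = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if not provenance:
                    provenance = line.lstrip("# ").strip()
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise RepeatFormatError(
                    f"{path}:{lineno}: expected 'family<TAB>superfamily'"
                )
            key = fields[0].lower()
            if key in mapping and mapping[key] != fields[1]:
                raise RepeatFormatError(
                    f"{path}:{lineno}: family {fields[0]!r} mapped to both "
                    f"{mapping[key]!r} and {fields[1]!r}"
                )
            mapping[key] = fields[1]
    return SuperfamilyTable(mapping=mapping, provenance=provenance)


def _superfamily_from_class(class_label: str) -> Optional[str]:
    # RepeatMasker class/family looks like "DNA/Helitron" or "LTR/Copia";
    # the part after the slash is the superfamily, a bare class stands alone.
    if not class_label or class_label in (".", "Unknown"):
        return None
    return class_label.split("/")[-1]


def assign_superfamilies(tes: Sequence[TECopy], table: SuperfamilyTable) -> list:
    """Return copies with superfamily set from the table.

    Lookup misses fall back to the RepeatMasker class/family column when the
    hit carried one, then to ``"Unknown"``.
    """
    out = []
    for te in tes:
        if te.family in table:
            sf = table.lookup(te.family)
        else:
            sf = _superfamily_from_class(te.class_label or "") or "Unknown"
        out.append(replace(te, superfamily=sf))
    return out


# ---------------------------------------------------------------------------
# writing (round-trip support for the synthetic generator)
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query     matching"
    "  repeat         position in repeat\n"
    "score  div. del. ins.  sequence  begin end     (left)  repeat"
    "         class/family  begin end  (left)  ID\n"
    "\n"
)


def write_repeats(tes: Sequence[TECopy], path, dialect: str) -> None:
    """Serialize copies as a RepeatMasker .out or native TSV file."""
    path = Path(path)
    if dialect == "repeatmasker":
        with open(path, "w") as fh:
            fh.write(_RM_HEADER)
            for i, te in enumerate(tes, 1):
                div = round(100.0 - te.similarity, 1)
                strand = "C" if te.region.strand == REVERSE else "+"
                class_label = te.class_label or (
                    f"DNA/{te.superfamily}" if te.superfamily else "Unknown"
                )
                score = int(te.score) if te.score is not None else 1000
                fh.write(
                    f"{score} {div:.1f} 0.0 0.0 {te.region.chrom} "
                    f"{te.region.start} {te.region.end} (0) {strand} "
                    f"{te.family} {class_label} 1 {te.region.length} (0) {i}\n"
                )
        return
    if dialect != "native":
        raise ValueError(f"can only write 'repeatmasker' or 'native', not {dialect!r}")
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tfamily\tsuperfamily\tsimilarity\n")
        for te in tes:
            fh.write(
                "\t".join(
                    [
                        te.region.chrom,
                        str(te.region.start),
                        str(te.region.end),
                        te.region.strand,
                        te.family,
                        te.superfamily or "",
                        f"{te.similarity:.1f}",
                    ]
                )
                + "\n"
            )
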