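"""Distribution panels: occurrence curves, genome frequency, size summaries.

Three whole-genome views of a set of TE copies:

* **chromosome distribution** — copy occurrence counts along each chromosome
  in equal-width windows (midpoint binning, so a copy straddling a window
  edge is counted once);
* **genome frequency** — per chromosome, its share of the genome length next
  to each family's share of its own genome-wide copy total, exposing
  insertion biases toward particular chromosomes;
* **size distribution and coverage** — a histogram of copy lengths per
  family, and the fraction of the genome covered by each item class (TE
  copies, genes, pseudogenes, ...), computed on the base-pair union so
  overlapping copies are not double-counted.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import ChromosomeRecord, GenomeAnnotation
from .core_model import BinnedCurve, SeqRegion, union_length
from .repeat_io import TECopy


def chromosome_distribution(
    tes: Sequence[TECopy], chrom: ChromosomeRecord, n_bins: int
) -> BinnedCurve:
    """Occurrence counts of copies along one chromosome.

    The chromosome ``[1, length]`` is split into ``n_bins`` equal-width
    windows (the last absorbs any remainder); a copy is counted once, in the
    window containing its midpoint.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    for te in tes:
        if te.region.chrom != chrom.chrom_id:
            raise ValueError(
                f"copy of {te.family} is on {te.region.chrom}, not {chrom.chrom_id}"
            )
    width = max(chrom.length // n_bins, 1)
    edges = [1 + i * width for i in range(n_bins)] + [chrom.length]
    counts = [0] * n_bins
    for te in tes:
        idx = min((te.region.midpoint - 1) // width, n_bins - 1)
        counts[idx] += 1
    return BinnedCurve(edges=tuple(edges), counts=tuple(counts))


def genome_frequency(
    tes_by_family: Dict[str, Sequence[TECopy]], genome: GenomeAnnotation
) -> pd.DataFrame:
    """Per-chromosome copy counts and percentages for each family.

    A family's percentage on a chromosome is its copy count there divided by
    the family's genome-wide total (so each family's column sums to 100 when
    it has at least one copy).  Chromosome length percentages are shares of
    the total genome length.  A final TOTAL row carries the genome-wide
    counts.
    """
    known = {c.chrom_id for c in genome.chromosomes}
    for fam, copies in tes_by_family.items():
        for te in copies:
            if te.region.chrom not in known:
                raise ValueError(
                    f"{fam} copy on unknown chromosome {te.region.chrom!r}"
                )
    genome_len = genome.total_length
    families = list(tes_by_family)
    totals = {f: len(tes_by_family[f]) for f in families}
    rows = []
    for chrom in genome.chromosomes:
        row: dict = {
            "chrom_id": chrom.chrom_id,
            "chrom_length": chrom.length,
            "chrom_length_pct": 100.0 * chrom.length / genome_len if genome_len else 0.0,
        }
        for f in families:
            n = sum(1 for te in tes_by_family[f] if te.region.chrom == chrom.chrom_id)
            row[f"{f}_copies"] = n
            row[f"{f}_pct"] = 100.0 * n / totals[f] if totals[f] else 0.0
        rows.append(row)
    total_row: dict = {
        "chrom_id": "TOTAL",
        "chrom_length": genome_len,
        "chrom_length_pct": 100.0 if genome_len else 0.0,
    }
    for f in families:
        total_row[f"{f}_copies"] = totals[f]
        total_row[f"{f}_pct"] = 100.0 if totals[f] else 0.0
    rows.append(total_row)
    return pd.DataFrame(rows)


def size_histogram(
    tes: Sequence[TECopy],
    n_intervals: int,
    size_min: Optional[int] = None,
    size_max: Optional[int] = None,
) -> BinnedCurve:
    """Histogram of copy lengths over [size_min, size_max].

    Bounds default to the observed minimum/maximum; bins are equal-width with
    the last bin right-closed; copies outside the range are excluded.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    sizes = np.array([te.region.length for te in tes], dtype=float)
    lo = float(size_min) if size_min is not None else (sizes.min() if sizes.size else 0.0)
    hi = float(size_max) if size_max is not None else (sizes.max() if sizes.size else 1.0)
    if lo > hi:
        raise ValueError(f"size_min ({lo}) > size_max ({hi})")
    if lo == hi:  # a single observed size still deserves one bin around it
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(sizes, bins=n_intervals, range=(lo, hi))
    return BinnedCurve(edges=tuple(edges.tolist()), counts=tuple(int(c) for c in counts))


def size_proportions(
    genome: GenomeAnnotation,
    classes: Dict[str, Sequence[SeqRegion]],
) -> pd.DataFrame:
    """Genome coverage of each item class, as union bp and percent.

    ``classes`` maps a class name (a TE family, "All TEs", "gene", ...) to
    the regions belonging to it.  Coverage is the union of the regions, so a
    class never exceeds 100%; classes overlap each other freely and are not
    expected to sum to anything.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    genome_len = genome.total_length
    rows = []
    for name, regions in classes.items():
        by_chrom: Dict[str, list] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        covered = sum(union_length(rs) for rs in by_chrom.values())
        rows.append(
            {
                "item_class": name,
                "covered_bp": covered,
                "percent": 100.0 * covered / genome_len if genome_len else 0.0,
            }
        )
    return pd.DataFrame(rows)


def class_regions(
    genome: GenomeAnnotation,
    tes: Sequence[TECopy],
    selected_families: Sequence[str],
    feature_kinds: Iterable[str] = ("gene", "pseudogene", "miscRNA", "exon"),
) -> Dict[str, list]:
    """Assemble the region sets behind a coverage report.

    One class per selected family, one "All TEs" class with every copy, and
    one class per requested annotation kind (UTR kinds are pooled as "UTRs").
    """
    classes: Dict[str, list] = {}
    for fam in selected_families:
        classes[fam] = [te.region for te in tes if te.family == fam]
    classes["All TEs"] = [te.region for te in tes]
    kinds = set(feature_kinds)
    utr_kinds = {"five_prime_UTR", "three_prime_UTR"} & kinds
    plain = kinds - utr_kinds
    for kind in sorted(plain):
        classes[kind] = [
            f.region
            for chrom in genome.chromosomes
            for f in chrom.features
            if f.kind == kind
        ]
    if utr_kinds:
        classes["UTRs"] = [
            f.region
            for chrom in genome.chromosomes
            for f in chrom.features
            if f.kind in utr_kinds
        ]
    return classes
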