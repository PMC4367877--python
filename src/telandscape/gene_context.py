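"""TE-gene context: nearest genes, insertion-site classes, GO summaries, table.

The central question is where each TE copy sits relative to the annotated
genes of its chromosome.  Each copy is assigned exactly one of four
categories:

* **ExonIntronUTR** — the copy overlaps a gene body by at least one base;
* **ProximalPromoter** — the nearest flanking gene lies within the proximal
  distance cutoff (default 3,000 bp, inclusive) and the copy is on that
  gene's 5' side, taking gene strand into account;
* **Proximal3End** — same, on the gene's 3' side;
* **Intergenic** — no gene within the cutoff.

"Upstream/downstream" in neighbor reports is purely chromosomal (left/right
of the copy); strand semantics enter only when a flank is promoted to a
promoter or 3'-end call.  When both flanking genes sit at exactly the same
gap, the promoter interpretation wins.

Neighbor genes (flanking and containing) then feed two summaries: a
distance histogram within a category, and the distribution of the neighbor
genes' GO slim terms — the functional fingerprint of the genomic
neighborhoods a TE family inserts into.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .annotation_io import GeneFeature, GenomeAnnotation, extract_features
from .core_model import (
    FORWARD,
    REVERSE,
    BinnedCurve,
    ProximityConfig,
    RegionCategory,
    region_gap,
)
from .ontology_io import GODag, GeneGOMap, SlimSet, map_to_slim
from .repeat_io import TECopy

#: feature kinds considered "annotated genes" for neighbor search
DEFAULT_NEIGHBOR_KINDS = ("gene", "pseudogene")

#: fixed column order of the master feature table
FEATURE_TABLE_COLUMNS = (
    "organism",
    "chrom",
    "te_family",
    "te_start",
    "te_end",
    "te_strand",
    "superfamily",
    "similarity",
    "gene_name",
    "gene_start",
    "gene_end",
    "gene_strand",
    "relation",
    "distance",
    "region_category",
    "go_terms",
    "ortholog_X",
)

UNANNOTATED = "unannotated"
OTHER = "other"


@dataclass(frozen=True)
class NeighborReport:
    """A copy's closest left/right genes (with gaps) and overlapping genes."""

    te: TECopy
    left_gene: Optional[Tuple[GeneFeature, int]] = None
    right_gene: Optional[Tuple[GeneFeature, int]] = None
    containing_genes: Tuple[GeneFeature, ...] = ()


@dataclass(frozen=True)
class GODistribution:
    """Slim term -> fraction of neighbor-gene slim assignments."""

    proportions: Dict[str, float]
    display_threshold: float = 0.01
    n_assignments: int = 0

    def displayed(self) -> Dict[str, float]:
        """Slices at or above the threshold, the rest pooled as "other"."""
        shown = {
            t: p for t, p in self.proportions.items() if p >= self.display_threshold
        }
        rest = 1.0 - sum(shown.values())
        if rest > 1e-12:
            shown[OTHER] = rest
        return shown


@dataclass(frozen=True)
class CoupleCount:
    """A (TE family, gene, relation side) pairing and the organisms carrying it."""

    family: str
    gene_name: str  # lower-cased
    relation: str
    organisms: frozenset

    @property
    def x(self) -> int:
        return len(self.organisms)


# ---------------------------------------------------------------------------
# nearest-gene search
# ---------------------------------------------------------------------------

def nearest_genes(te: TECopy, genes: Sequence[GeneFeature]) -> NeighborReport:
    """Closest non-overlapping genes left and right of a copy, plus overlaps.

    ``genes`` must be sorted by start coordinate and lie on the copy's
    chromosome.  Gap ties are broken toward the smaller start coordinate.
    """
    starts = []
    for i, g in enumerate(genes):
        if g.region.chrom != te.region.chrom:
            raise ValueError(
                f"gene {g.feature_id} is on {g.region.chrom}, not {te.region.chrom}"
            )
        if i and genes[i - 1].region.start > g.region.start:
            raise ValueError("genes must be sorted by start coordinate")
        starts.append(g.region.start)

    # right neighbor: smallest start strictly past the copy's end
    right: Optional[Tuple[GeneFeature, int]] = None
    i = bisect_right(starts, te.region.end)
    if i < len(genes):
        g = genes[i]
        right = (g, region_gap(te.region, g.region))

    # left neighbor and containing genes need a scan: a gene starting far left
    # may still reach past the copy
    left: Optional[Tuple[GeneFeature, int]] = None
    containing: List[GeneFeature] = []
    for g in genes[:i]:
        if g.region.end < te.region.start:
            gap = region_gap(te.region, g.region)
            if left is None or gap < left[1] or (gap == left[1] and g.region.start < left[0].region.start):
                left = (g, gap)
        elif g.region.overlaps(te.region):
            containing.append(g)
    return NeighborReport(
        te=te, left_gene=left, right_gene=right, containing_genes=tuple(containing)
    )


def _flank_category(te: TECopy, gene: GeneFeature, side: str) -> RegionCategory:
    """Promoter vs 3'-end call for a flanking gene, strand-aware.

    ``side`` is the gene's position relative to the copy ("left"/"right");
    unstranded genes are treated as forward.
    """
    gene_forward = gene.region.strand != REVERSE
    te_is_5prime = (side == "right") == gene_forward
    return (
        RegionCategory.PROXIMAL_PROMOTER if te_is_5prime else RegionCategory.PROXIMAL_3_END
    )


def classification_detail(
    report: NeighborReport, config: ProximityConfig
) -> Tuple[RegionCategory, Optional[GeneFeature], Optional[int]]:
    """Category plus the gene and gap that decided it (None for Intergenic)."""
    if report.containing_genes:
        return RegionCategory.EXON_INTRON_UTR, report.containing_genes[0], 0
    candidates: List[Tuple[int, RegionCategory, GeneFeature]] = []
    for pair, side in ((report.left_gene, "left"), (report.right_gene, "right")):
        if pair is None:
            continue
        gene, gap = pair
        if gap <= config.proximal_distance:
            candidates.append((gap, _flank_category(report.te, gene, side), gene))
    if not candidates:
        return RegionCategory.INTERGENIC, None, None
    best_gap = min(gap for gap, _, _ in candidates)
    tied = [(cat, gene) for gap, cat, gene in candidates if gap == best_gap]
    for cat, gene in tied:  # promoter wins an exact tie
        if cat is RegionCategory.PROXIMAL_PROMOTER:
            return cat, gene, best_gap
    cat, gene = tied[0]
    return cat, gene, best_gap


def classify_te(report: NeighborReport, config: ProximityConfig) -> RegionCategory:
    """The copy's single region category (see module docstring for the rules)."""
    return classification_detail(report, config)[0]


# ---------------------------------------------------------------------------
# genome-wide classification
# ---------------------------------------------------------------------------

def neighbor_reports(
    tes: Sequence[TECopy],
    genome: GenomeAnnotation,
    neighbor_kinds: Iterable[str] = DEFAULT_NEIGHBOR_KINDS,
) -> List[NeighborReport]:
    """One NeighborReport per copy, against the genome's gene features."""
    genes_by_chrom = {
        c.chrom_id: extract_features(c, set(neighbor_kinds)) for c in genome.chromosomes
    }
    reports = []
    for te in tes:
        if te.region.chrom not in genes_by_chrom:
            raise ValueError(f"copy on unknown chromosome {te.region.chrom!r}")
        reports.append(nearest_genes(te, genes_by_chrom[te.region.chrom]))
    return reports


def category_distribution(
    tes: Sequence[TECopy],
    genome: GenomeAnnotation,
    config: ProximityConfig,
    neighbor_kinds: Iterable[str] = DEFAULT_NEIGHBOR_KINDS,
) -> Dict[RegionCategory, float]:
    """Proportion of copies in each region category (sums to 1; {} if empty)."""
    if not tes:
        return {}
    reports = neighbor_reports(tes, genome, neighbor_kinds)
    counts: Dict[RegionCategory, int] = {}
    for rep in reports:
        cat = classify_te(rep, config)
        counts[cat] = counts.get(cat, 0) + 1
    n = len(tes)
    return {cat: c / n for cat, c in counts.items()}


def region_position_histogram(
    tes: Sequence[TECopy],
    genome: GenomeAnnotation,
    config: ProximityConfig,
    category: RegionCategory,
    neighbor_kinds: Iterable[str] = DEFAULT_NEIGHBOR_KINDS,
) -> BinnedCurve:
    """Histogram of gene-boundary gaps for copies in one proximal category.

    The gap axis runs over [0, proximal_distance] in ``region_bins``
    left-closed equal bins (last bin right-closed); bin 0 is flush against
    the gene boundary — the gene start for promoters, the gene end for
    3' ends.
    """
    if category not in (RegionCategory.PROXIMAL_PROMOTER, RegionCategory.PROXIMAL_3_END):
        raise ValueError(f"{category} has no distance axis")
    n_bins = config.region_bins
    width = config.proximal_distance / n_bins if config.proximal_distance else 1.0
    counts = [0] * n_bins
    for rep in neighbor_reports(tes, genome, neighbor_kinds):
        cat, _gene, gap = classification_detail(rep, config)
        if cat is not category:
            continue
        idx = min(int(gap // width), n_bins - 1)
        counts[idx] += 1
    edges = tuple(i * width for i in range(n_bins + 1))
    return BinnedCurve(edges=edges, counts=tuple(counts))


# ---------------------------------------------------------------------------
# GO distributions of neighbor genes
# ---------------------------------------------------------------------------

def go_distribution_for_genes(
    genes: Sequence[GeneFeature],
    go_map: GeneGOMap,
    dag: GODag,
    slim: SlimSet,
    config: ProximityConfig = ProximityConfig(),
) -> GODistribution:
    """Slim-term distribution over a set of gene incidences.

    Each gene contributes one assignment per distinct slim term its GO
    annotations map to (set semantics per gene, so annotation redundancy does
    not inflate a slice); genes without a numeric id, without GO terms, or
    whose terms miss the slim entirely contribute one "unannotated"
    assignment.
    """
    counts: Dict[str, int] = {}
    total = 0
    for gene in genes:
        slim_terms = map_to_slim(dag, go_map.terms_for(gene.gene_numeric_id), slim)
        if not slim_terms:
            counts[UNANNOTATED] = counts.get(UNANNOTATED, 0) + 1
            total += 1
            continue
        for t in sorted(slim_terms):
            counts[t] = counts.get(t, 0) + 1
            total += 1
    proportions = {t: c / total for t, c in counts.items()} if total else {}
    return GODistribution(
        proportions=proportions,
        display_threshold=config.display_threshold,
        n_assignments=total,
    )


def collect_neighbor_genes(
    tes: Sequence[TECopy],
    genome: GenomeAnnotation,
    neighbor_kinds: Iterable[str] = DEFAULT_NEIGHBOR_KINDS,
) -> List[GeneFeature]:
    """Each copy's distinct neighbor genes (left, right, containing), pooled.

    A gene neighboring several copies appears once per copy: the tally
    weights neighborhoods by how often TEs land in them.
    """
    pooled: List[GeneFeature] = []
    for rep in neighbor_reports(tes, genome, neighbor_kinds):
        seen = set()
        for gene in (
            [p[0] for p in (rep.left_gene, rep.right_gene) if p is not None]
            + list(rep.containing_genes)
        ):
            if gene.feature_id not in seen:
                seen.add(gene.feature_id)
                pooled.append(gene)
    return pooled


def neighbor_go_distribution(
    tes: Sequence[TECopy],
    genome: GenomeAnnotation,
    go_map: GeneGOMap,
    dag: GODag,
    slim: SlimSet,
    config: ProximityConfig = ProximityConfig(),
    neighbor_kinds: Iterable[str] = DEFAULT_NEIGHBOR_KINDS,
) -> GODistribution:
    """GO slim distribution of the genes neighboring a set of TE copies."""
    genes = collect_neighbor_genes(tes, genome, neighbor_kinds)
    return go_distribution_for_genes(genes, go_map, dag, slim, config)


# ---------------------------------------------------------------------------
# master feature table and cross-organism couples
# ---------------------------------------------------------------------------

def build_feature_table(
    tes: Sequence[TECopy],
    genome: GenomeAnnotation,
    config: ProximityConfig = ProximityConfig(),
    go_map: Optional[GeneGOMap] = None,
    dag: Optional[GODag] = None,
    slim: Optional[SlimSet] = None,
    couple_counts: Optional[Dict[Tuple[str, str, str], int]] = None,
    neighbor_kinds: Iterable[str] = DEFAULT_NEIGHBOR_KINDS,
) -> pd.DataFrame:
    """One row per (copy, neighbor gene): the downloadable master table.

    Every copy yields a row for each existing flank neighbor (at most two)
    plus one row per containing gene; a copy with no gene on its chromosome
    yields a single placeholder row with ``relation = none``.  Column order
    is :data:`FEATURE_TABLE_COLUMNS`.
    """

    def _go_terms(gene: GeneFeature) -> str:
        if go_map is None or dag is None or slim is None:
            return ""
        terms = map_to_slim(dag, go_map.terms_for(gene.gene_numeric_id), slim)
        return ";".join(sorted(terms))

    rows = []
    for rep in neighbor_reports(tes, genome, neighbor_kinds):
        te = rep.te
        category = classify_te(rep, config)
        base = {
            "organism": genome.organism,
            "chrom": te.region.chrom,
            "te_family": te.family,
            "te_start": te.region.start,
            "te_end": te.region.end,
            "te_strand": te.region.strand,
            "superfamily": te.superfamily or "Unknown",
            "similarity": te.similarity,
            "region_category": str(category),
        }
        emitted = []
        for pair, relation in ((rep.left_gene, "left"), (rep.right_gene, "right")):
            if pair is None:
                continue
            gene, gap = pair
            emitted.append((gene, relation, gap))
        for gene in rep.containing_genes:
            emitted.append((gene, "within", 0))
        if not emitted:
            rows.append(
                {
                    **base,
                    "gene_name": "",
                    "gene_start": "",
                    "gene_end": "",
                    "gene_strand": "",
                    "relation": "none",
                    "distance": "",
                    "go_terms": "",
                    "ortholog_X": "",
                }
            )
            continue
        for gene, relation, gap in emitted:
            key = (te.family, gene.gene_name.lower(), relation)
            x = couple_counts.get(key, 1) if couple_counts is not None else 1
            rows.append(
                {
                    **base,
                    "gene_name": gene.gene_name,
                    "gene_start": gene.region.start,
                    "gene_end": gene.region.end,
                    "gene_strand": gene.region.strand,
                    "relation": relation,
                    "distance": gap,
                    "go_terms": _go_terms(gene),
                    "ortholog_X": x,
                }
            )
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))


def count_couples(
    tables: Dict[str, pd.DataFrame],
    ortholog_map: Optional[Dict[str, str]] = None,
) -> List[CoupleCount]:
    """Cross-organism TE-gene couples from per-organism feature tables.

    A couple is keyed by (family, case-insensitive gene name, relation side);
    its X is the number of distinct organisms with at least one instance.
    ``ortholog_map`` (lower-cased gene name -> ortholog group) overrides name
    matching, so differently named orthologs collapse to one couple.
    """
    if not tables:
        raise ValueError("need at least one organism")
    ortholog_map = ortholog_map or {}
    organisms_by_key: Dict[Tuple[str, str, str], set] = {}
    for organism, df in tables.items():
        for _, row in df.iterrows():
            if row["relation"] in ("none", "") or not row["gene_name"]:
                continue
            gname = str(row["gene_name"]).lower()
            gname = ortholog_map.get(gname, gname)
            key = (row["te_family"], gname, row["relation"])
            organisms_by_key.setdefault(key, set()).add(organism)
    return [
        CoupleCount(family=k[0], gene_name=k[1], relation=k[2], organisms=frozenset(orgs))
        for k, orgs in sorted(organisms_by_key.items())
    ]


def couple_count_map(couples: Sequence[CoupleCount]) -> Dict[Tuple[str, str, str], int]:
    return {(c.family, c.gene_name, c.relation): c.x for c in couples}


def filter_couples(
    couples: Sequence[CoupleCount], config: ProximityConfig
) -> List[CoupleCount]:
    """Couples present in at least ``min_organisms`` organisms."""
    return [c for c in couples if c.x >= config.min_organisms]
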