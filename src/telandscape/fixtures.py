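"""Deterministic synthetic genome/repeat/ontology generator with ground truth.

Emulates the coordinate structure of an annotated genome plus a repeat
screen: genes laid out on a jittered grid along each chromosome, TE copies
of several families placed *constructively* so that each copy realizes a
pre-assigned region category — inside a gene, within the proximal distance
of a gene's 5' or 3' boundary, or farther than that distance from every
gene.  Because placement is constructive rather than sampled-and-tested,
the planted category proportions are exact and downstream tests need no
tolerance.

What is emulated: coordinates, strands, per-copy similarity, a toy GO DAG
with slim-level structure, and gene2go annotations.  What is *not*: actual
nucleotide sequence, TE nesting, fragmentation, or the clustered gene/TE
densities of real chromosomes (real genomes concentrate TEs around
centromeres; the grid layout here is deliberately uniform).

One pseudo-random stream per file kind (genes / TE copies / ontology), each
derived from the single seed, so adding a file kind never shifts existing
outputs; identical spec + seed give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation_io import (
    ChromosomeRecord,
    GeneFeature,
    GenomeAnnotation,
    write_annotation,
)
from .core_model import FORWARD, REVERSE, SeqRegion
from .repeat_io import TECopy, write_repeats

CATEGORIES = ("within", "promoter", "three_prime", "intergenic")


class PlacementError(ValueError):
    """The requested layout cannot be realized on these chromosomes."""


@dataclass(frozen=True)
class FamilySpec:
    name: str
    superfamily: str = "Helitron"
    n_copies: int = 200
    size_bounds: Tuple[int, int] = (100, 800)
    sim_bounds: Tuple[float, float] = (80.0, 100.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic genome run."""

    seed: int = 42
    organism: str = "Synthorg demo"
    chromosome_lengths: Tuple[int, ...] = (2_000_000, 2_000_000)
    genes_per_chromosome: int = 100
    gene_length_bounds: Tuple[int, int] = (1000, 5000)
    families: Tuple[FamilySpec, ...] = (
        FamilySpec("TEfam1"),
        FamilySpec("TEfam2"),
        FamilySpec("TEfam3"),
    )
    #: planted (p_within, p_promoter, p_3end, p_intergenic)
    proportions: Tuple[float, float, float, float] = (0.10, 0.25, 0.25, 0.40)
    proximal_distance: int = 3000
    n_slim_terms: int = 6
    leaves_per_slim: int = 3
    annotation_prob: float = 0.8
    taxon: int = 3702

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("planted proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("planted proportions must be non-negative")
        if self.genes_per_chromosome < 0 or self.proximal_distance < 0:
            raise ValueError("counts and distances must be non-negative")


def _category_counts(n: int, proportions: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment, so counts are exact and sum to n."""
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


@dataclass
class _PlacedCopy:
    te: TECopy
    category: str
    anchor_gene: Optional[str]  # gene realizing the category (within/proximal)
    gap: Optional[int]  # planted boundary gap for proximal copies
    left_gene: Optional[str]
    right_gene: Optional[str]
    containing_gene: Optional[str]


def synthesize(spec: SyntheticSpec):
    """Generate a synthetic genome in memory.

    Returns ``(genome, tes, truth)``: the annotation object, the planted TE
    copies (superfamilies already set), and the ground-truth dict.  Used by
    :func:`make_synthetic_genome` and directly by tests that need many seeds
    without file round-trips.
    """
    rng_genes = np.random.default_rng([spec.seed, 1])
    rng_tes = np.random.default_rng([spec.seed, 2])
    rng_go = np.random.default_rng([spec.seed, 3])
    genome, genes_by_chrom = _place_genes(spec, rng_genes)
    placed = _place_copies(spec, genes_by_chrom, rng_tes)
    dag_parents, slim_ids, leaf_to_slim, gene_go = _make_ontology(spec, genome, rng_go)
    truth = _ground_truth(spec, genome, placed, slim_ids, leaf_to_slim, gene_go)
    truth["dag_parents"] = {t: sorted(ps) for t, ps in dag_parents.items()}
    return genome, [p.te for p in placed], truth


def make_synthetic_genome(spec: SyntheticSpec, out_dir) -> dict:
    """Generate all input files plus a ground-truth JSON; return the truth.

    Writes GenBank, EMBL and native annotation; RepeatMasker and native
    repeat files; toy gene2go, OBO and slim files; a superfamily table; and
    ``ground_truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_genes = np.random.default_rng([spec.seed, 1])
    rng_tes = np.random.default_rng([spec.seed, 2])
    rng_go = np.random.default_rng([spec.seed, 3])

    genome, genes_by_chrom = _place_genes(spec, rng_genes)
    placed = _place_copies(spec, genes_by_chrom, rng_tes)
    dag_parents, slim_ids, leaf_to_slim, gene_go = _make_ontology(spec, genome, rng_go)

    # --- write input files ------------------------------------------------
    write_annotation(genome, out_dir / "annotation.gb", "genbank")
    write_annotation(genome, out_dir / "annotation.embl", "embl")
    write_annotation(genome, out_dir / "annotation.tsv", "native")
    tes = [p.te for p in placed]
    write_repeats(tes, out_dir / "repeats.out", "repeatmasker")
    write_repeats(tes, out_dir / "repeats.tsv", "native")
    _write_obo(dag_parents, out_dir / "go.obo")
    with open(out_dir / "slim.txt", "w") as fh:
        fh.write("# toy slim: the intermediate-level terms of the synthetic DAG\n")
        for t in slim_ids:
            fh.write(t + "\n")
    with open(out_dir / "gene2go.tsv", "w") as fh:
        fh.write("#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory\n")
        for chrom in genome.chromosomes:
            for f in chrom.features:
                for term in gene_go.get(f.gene_name, []):
                    fh.write(
                        f"{spec.taxon}\t{f.gene_numeric_id}\t{term}\tIEA\t-\t-\t-\tProcess\n"
                    )
    with open(out_dir / "superfamily.tsv", "w") as fh:
        fh.write("# synthetic family -> superfamily table\n")
        for fam in spec.families:
            fh.write(f"{fam.name}\t{fam.superfamily}\n")

    truth = _ground_truth(spec, genome, placed, slim_ids, leaf_to_slim, gene_go)
    truth["dag_parents"] = {t: sorted(ps) for t, ps in dag_parents.items()}
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _max_te_size(spec: SyntheticSpec) -> int:
    return max((f.size_bounds[1] for f in spec.families), default=0)


def _place_genes(spec: SyntheticSpec, rng) -> Tuple[GenomeAnnotation, Dict[str, list]]:
    gmin, gmax = spec.gene_length_bounds
    max_te = _max_te_size(spec)
    clearance = spec.proximal_distance + max_te + 2
    chromosomes = []
    genes_by_chrom: Dict[str, list] = {}
    next_gene_id = 100001
    for ci, length in enumerate(spec.chromosome_lengths):
        chrom_id = f"chr{ci + 1}"
        n = spec.genes_per_chromosome
        features: List[GeneFeature] = []
        if n > 0:
            slot = length // (n + 1)
            jitter_max = slot // 20
            needed = gmax + 2 * jitter_max + 2 * clearance + max_te + 4
            if slot < needed:
                raise PlacementError(
                    f"{chrom_id}: {n} genes on {length} bp leave {slot} bp per slot "
                    f"but the layout needs {needed}; use larger chromosomes or fewer genes"
                )
            for gi in range(n):
                glen = int(rng.integers(gmin, gmax + 1))
                jitter = int(rng.integers(-jitter_max, jitter_max + 1))
                center = (gi + 1) * slot + jitter
                start = center - glen // 2
                end = start + glen - 1
                strand = FORWARD if rng.random() < 0.5 else REVERSE
                name = f"{chrom_id}g{gi:04d}"
                features.append(
                    GeneFeature(
                        feature_id=f"{chrom_id}.gene.{gi + 1}",
                        gene_name=name,
                        kind="gene",
                        region=SeqRegion(chrom_id, start, end, strand),
                        gene_numeric_id=next_gene_id,
                    )
                )
                next_gene_id += 1
        chromosomes.append(
            ChromosomeRecord(
                chrom_id=chrom_id, length=length, organism=spec.organism, features=features
            )
        )
        genes_by_chrom[chrom_id] = features
    return GenomeAnnotation(organism=spec.organism, chromosomes=chromosomes), genes_by_chrom


def _place_copies(spec: SyntheticSpec, genes_by_chrom: Dict[str, list], rng) -> List[_PlacedCopy]:
    D = spec.proximal_distance
    chrom_ids = list(genes_by_chrom)
    total_genes = sum(len(g) for g in genes_by_chrom.values())
    placed: List[_PlacedCopy] = []
    for fam in spec.families:
        counts = _category_counts(fam.n_copies, spec.proportions)
        if counts[0] > 0 and total_genes == 0:
            raise PlacementError(
                f"{fam.name}: cannot place within-gene copies in a genome with 0 genes"
            )
        if (counts[1] > 0 or counts[2] > 0) and total_genes == 0:
            raise PlacementError(
                f"{fam.name}: cannot place gene-proximal copies in a genome with 0 genes"
            )
        plan = [cat for cat, c in zip(CATEGORIES, counts) for _ in range(c)]
        for category in plan:
            chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
            genes = genes_by_chrom[chrom]
            if category != "intergenic" and not genes:
                # all genes may have landed on other chromosomes
                with_genes = [c for c in chrom_ids if genes_by_chrom[c]]
                chrom = with_genes[int(rng.integers(0, len(with_genes)))]
                genes = genes_by_chrom[chrom]
            size = int(rng.integers(fam.size_bounds[0], fam.size_bounds[1] + 1))
            sim = round(float(rng.uniform(*fam.sim_bounds)), 1)
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            placed.append(
                _place_one(spec, fam, chrom, genes, category, size, sim, strand, rng)
            )
    return placed


def _place_one(spec, fam, chrom, genes, category, size, sim, strand, rng) -> _PlacedCopy:
    D = spec.proximal_distance
    chrom_len = dict(
        zip([f"chr{i+1}" for i in range(len(spec.chromosome_lengths))], spec.chromosome_lengths)
    )[chrom]
    n = len(genes)

    def neighbors_of_gap(k: int) -> Tuple[Optional[str], Optional[str]]:
        left = genes[k - 1].gene_name if k > 0 else None
        right = genes[k].gene_name if k < n else None
        return left, right

    if category == "within":
        gi = int(rng.integers(0, n))
        gene = genes[gi]
        glen = gene.region.length
        s = min(size, glen - 2) if glen > 2 else 1
        start = int(rng.integers(gene.region.start + 1, gene.region.end - s + 1))
        region = SeqRegion(chrom, start, start + s - 1, strand)
        left = genes[gi - 1].gene_name if gi > 0 else None
        right = genes[gi + 1].gene_name if gi + 1 < n else None
        return _PlacedCopy(
            te=_copy(fam, region, sim),
            category=category,
            anchor_gene=gene.gene_name,
            gap=None,
            left_gene=left,
            right_gene=right,
            containing_gene=gene.gene_name,
        )

    if category in ("promoter", "three_prime"):
        gi = int(rng.integers(0, n))
        gene = genes[gi]
        gap = int(rng.integers(0, D + 1))
        gene_forward = gene.region.strand != REVERSE
        want_5prime = category == "promoter"
        # the copy sits left of the gene iff the wanted side matches strand
        on_left = want_5prime == gene_forward
        if on_left:
            end = gene.region.start - gap - 1
            start = end - size + 1
            k = gi  # gap between gene gi-1 and gene gi
        else:
            start = gene.region.end + gap + 1
            end = start + size - 1
            k = gi + 1
        if start < 1 or end > chrom_len:
            raise PlacementError(
                f"{fam.name}: proximal copy of gene {gene.gene_name} falls off {chrom}; "
                f"use larger chromosomes"
            )
        left, right = neighbors_of_gap(k)
        region = SeqRegion(chrom, start, end, strand)
        return _PlacedCopy(
            te=_copy(fam, region, sim),
            category=category,
            anchor_gene=gene.gene_name,
            gap=gap,
            left_gene=left,
            right_gene=right,
            containing_gene=None,
        )

    # intergenic: anywhere farther than D from every gene
    k = int(rng.integers(0, n + 1)) if n else 0
    prev_end = genes[k - 1].region.end if k > 0 else 0
    next_start = genes[k].region.start if k < n else chrom_len + 1
    lo = max(prev_end + D + 2, 1)
    hi = next_start - D - 2 - size
    if hi < lo:
        raise PlacementError(
            f"{fam.name}: no room for an intergenic copy between genes on {chrom}; "
            f"use larger chromosomes"
        )
    start = int(rng.integers(lo, hi + 1))
    region = SeqRegion(chrom, start, start + size - 1, strand)
    left, right = neighbors_of_gap(k)
    return _PlacedCopy(
        te=_copy(fam, region, sim),
        category="intergenic",
        anchor_gene=None,
        gap=None,
        left_gene=left,
        right_gene=right,
        containing_gene=None,
    )


def _copy(fam: FamilySpec, region: SeqRegion, sim: float) -> TECopy:
    return TECopy(
        family=fam.name,
        region=region,
        similarity=sim,
        source="synthetic",
        superfamily=fam.superfamily,
    )


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def _make_ontology(spec: SyntheticSpec, genome: GenomeAnnotation, rng):
    root = "GO:0000001"
    slim_ids = [f"GO:{2 + i:07d}" for i in range(spec.n_slim_terms)]
    parents: Dict[str, List[str]] = {root: []}
    leaf_to_slim: Dict[str, str] = {}
    for i, s in enumerate(slim_ids):
        parents[s] = [root]
        for j in range(spec.leaves_per_slim):
            leaf = f"GO:{101 + i * spec.leaves_per_slim + j:07d}"
            parents[leaf] = [s]
            leaf_to_slim[leaf] = s
    leaves = sorted(leaf_to_slim)
    gene_go: Dict[str, List[str]] = {}
    for chrom in genome.chromosomes:
        for f in chrom.features:
            if rng.random() < spec.annotation_prob and leaves:
                k = int(rng.integers(1, 3))
                picks = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
                gene_go[f.gene_name] = sorted(leaves[int(p)] for p in picks)
    return parents, slim_ids, leaf_to_slim, gene_go


def _write_obo(parents: Dict[str, List[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(parents):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term[3:]}\n")
            fh.write("namespace: biological_process\n")
            for p in parents[term]:
                fh.write(f"is_a: {p} ! parent\n")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _ground_truth(spec, genome, placed, slim_ids, leaf_to_slim, gene_go) -> dict:
    gene_slim = {
        name: sorted({leaf_to_slim[t] for t in terms})
        for name, terms in gene_go.items()
    }
    copies = []
    for p in placed:
        copies.append(
            {
                "family": p.te.family,
                "superfamily": p.te.superfamily,
                "chrom": p.te.region.chrom,
                "start": p.te.region.start,
                "end": p.te.region.end,
                "strand": p.te.region.strand,
                "similarity": p.te.similarity,
                "category": p.category,
                "anchor_gene": p.anchor_gene,
                "gap": p.gap,
                "left_gene": p.left_gene,
                "right_gene": p.right_gene,
                "containing_gene": p.containing_gene,
            }
        )
    category_counts: Dict[str, Dict[str, int]] = {}
    chrom_counts: Dict[str, Dict[str, int]] = {}
    for p in placed:
        category_counts.setdefault(p.te.family, {c: 0 for c in CATEGORIES})
        category_counts[p.te.family][p.category] += 1
        chrom_counts.setdefault(p.te.family, {})
        chrom_counts[p.te.family][p.te.region.chrom] = (
            chrom_counts[p.te.family].get(p.te.region.chrom, 0) + 1
        )
    overall = {c: 0 for c in CATEGORIES}
    for fam_counts in category_counts.values():
        for c, v in fam_counts.items():
            overall[c] += v
    n_total = sum(overall.values())

    # expected neighbor-GO distribution, from planted neighbors alone
    go_counts: Dict[str, int] = {}
    total_assign = 0
    expected_rows = 0
    for p in placed:
        neighbor_names = [
            g for g in (p.left_gene, p.right_gene, p.containing_gene) if g is not None
        ]
        expected_rows += len(neighbor_names) if neighbor_names else 1
        for gname in neighbor_names:
            slims = gene_slim.get(gname, [])
            if not slims:
                go_counts["unannotated"] = go_counts.get("unannotated", 0) + 1
                total_assign += 1
            else:
                for s in slims:
                    go_counts[s] = go_counts.get(s, 0) + 1
                    total_assign += 1
    neighbor_go = (
        {t: c / total_assign for t, c in go_counts.items()} if total_assign else {}
    )

    # all-genes baseline
    base_counts: Dict[str, int] = {}
    base_total = 0
    for chrom in genome.chromosomes:
        for f in chrom.features:
            slims = gene_slim.get(f.gene_name, [])
            if not slims:
                base_counts["unannotated"] = base_counts.get("unannotated", 0) + 1
                base_total += 1
            else:
                for s in slims:
                    base_counts[s] = base_counts.get(s, 0) + 1
                    base_total += 1
    baseline_go = (
        {t: c / base_total for t, c in base_counts.items()} if base_total else {}
    )

    return {
        "spec": {
            "seed": spec.seed,
            "organism": spec.organism,
            "chromosome_lengths": list(spec.chromosome_lengths),
            "genes_per_chromosome": spec.genes_per_chromosome,
            "families": [f.name for f in spec.families],
            "proportions": list(spec.proportions),
            "proximal_distance": spec.proximal_distance,
            "taxon": spec.taxon,
        },
        "genes": {
            chrom.chrom_id: [
                {
                    "name": f.gene_name,
                    "start": f.region.start,
                    "end": f.region.end,
                    "strand": f.region.strand,
                    "gene_numeric_id": f.gene_numeric_id,
                }
                for f in chrom.features
            ]
            for chrom in genome.chromosomes
        },
        "gene_go": gene_go,
        "gene_slim": gene_slim,
        "slim_terms": slim_ids,
        "copies": copies,
        "category_counts_by_family": category_counts,
        "chromosome_counts_by_family": chrom_counts,
        "overall_category_counts": overall,
        "overall_category_proportions": {
            c: v / n_total for c, v in overall.items()
        } if n_total else {},
        "expected_feature_table_rows": expected_rows,
        "expected_neighbor_go": neighbor_go,
        "expected_baseline_go": baseline_go,
    }


def spec_from_json(path_or_dict, seed: Optional[int] = None) -> SyntheticSpec:
    """Build a SyntheticSpec from a JSON file or dict (CLI `simulate --spec`)."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = json.load(fh)
    if "families" in raw:
        raw["families"] = tuple(
            FamilySpec(**f) if isinstance(f, dict) else FamilySpec(str(f))
            for f in raw["families"]
        )
    for key in ("chromosome_lengths", "gene_length_bounds", "proportions"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if seed is not None:
        raw["seed"] = seed
    return SyntheticSpec(**raw)
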