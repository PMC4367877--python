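import json
from pathlib import Path

import pytest

from telandscape.annotation_io import ChromosomeRecord, GeneFeature, GenomeAnnotation
from telandscape.core_model import SeqRegion
from telandscape.fixtures import FamilySpec, SyntheticSpec, make_synthetic_genome
from telandscape.repeat_io import TECopy


#: a smaller study layout for multi-seed property sweeps
SMALL_SPEC_KW = dict(
    chromosome_lengths=(400_000, 400_000),
    genes_per_chromosome=20,
    families=(
        FamilySpec("TEfam1", n_copies=50),
        FamilySpec("TEfam2", n_copies=50),
        FamilySpec("TEfam3", n_copies=50),
    ),
)


def small_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(seed=seed, **SMALL_SPEC_KW)


@pytest.fixture(scope="session")
def sim42(tmp_path_factory):
    """Default synthetic genome (seed 42) written once per session."""
    out = tmp_path_factory.mktemp("sim42")
    truth = make_synthetic_genome(SyntheticSpec(seed=42), out)
    return out, truth


def make_te(chrom="chr1", start=1000, end=1500, family="fam", sim=90.0, strand="+"):
    return TECopy(
        family=family,
        region=SeqRegion(chrom, start, end, strand),
        similarity=sim,
        source="test",
    )


def make_gene(chrom="chr1", start=100, end=400, name="g", strand="+", numeric=None, kind="gene"):
    return GeneFeature(
        feature_id=f"{chrom}.{name}",
        gene_name=name,
        kind=kind,
        region=SeqRegion(chrom, start, end, strand),
        gene_numeric_id=numeric,
    )


def make_genome(chrom_len=100_000, genes=(), chrom="chr1", organism="test"):
    return GenomeAnnotation(
        organism=organism,
        chromosomes=[
            ChromosomeRecord(
                chrom_id=chrom, length=chrom_len, organism=organism, features=list(genes)
            )
        ],
    )
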