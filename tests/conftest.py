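import numpy as np
import pandas as pd
import pytest

from mitosoma.genome import GeneticCode, ReferenceGenome, RegionAnnotation
from mitosoma.simulate import GenomeSpec, generate_genome
from mitosoma.variants import ConditionTable, VARIANT_COLUMNS


@pytest.fixture(scope="session")
def toy_genome():
    """12 nt of D-loop followed by a 30 nt (10 codon) plus-strand gene.

    Gene codons: ATG AAA CGA TTT CCC GGG ACG TAC TGA-free ... chosen to cover
    synonymous, missense, and nonsense substitutions under the mitochondrial
    code; ends with TAA.
    """
    dloop = "ACGTACGTACGT"
    gene = "ATG" + "AAA" + "CGA" + "TTT" + "CCC" + "GGG" + "ACG" + "TAC" + "CTT" + "TAA"
    regions = [
        RegionAnnotation("D-loop", "D-loop", 1, 12),
        RegionAnnotation("geneA", "protein_coding", 13, 42, "+"),
    ]
    return ReferenceGenome(dloop + gene, regions)


@pytest.fixture(scope="session")
def default_genome():
    genome, _ = generate_genome(GenomeSpec(), seed=1)
    return genome


@pytest.fixture(scope="session")
def reversion_genome():
    """Default genome layout plus 4 haplotype sites inside the NUMT interval."""
    return generate_genome(
        GenomeSpec(n_haplotype_sites=4, haplotype_interval=(1000, 3000)), seed=1
    )


def make_table(L, rows, depth=10_000.0, condition=("B6", "liver", "young")):
    """Small helper to build a ConditionTable from (position, ref, alt, kind, alt_depth) rows."""
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    d = np.full(L, float(depth)) if np.isscalar(depth) else np.asarray(depth, dtype=float)
    return ConditionTable(condition, variants, d)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def mito_code():
    return GeneticCode()
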