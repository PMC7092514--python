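"""Shared fixtures: toy annotations and a small simulated cohort."""

import pytest

from splicescape.simulate import (
    SimConfig,
    simulate_genome_annotation,
    simulate_psi_tables,
)

# one gene, one mRNA, three exons, two UTR-crossing CDS ends
TOY_GFF_PLUS = """\
##gff-version 3
chrT\ttest\tgene\t1\t500\t.\t+\t.\tID=geneA
chrT\ttest\tmRNA\t1\t500\t.\t+\t.\tID=geneA.t1;Parent=geneA
chrT\ttest\texon\t1\t100\t.\t+\t.\tParent=geneA.t1
chrT\ttest\texon\t201\t300\t.\t+\t.\tParent=geneA.t1
chrT\ttest\texon\t401\t500\t.\t+\t.\tParent=geneA.t1
chrT\ttest\tCDS\t51\t100\t.\t+\t0\tParent=geneA.t1
chrT\ttest\tCDS\t201\t300\t.\t+\t1\tParent=geneA.t1
chrT\ttest\tCDS\t401\t450\t.\t+\t0\tParent=geneA.t1
"""

# the same structure mirrored onto the minus strand (x -> 601 - x)
TOY_GFF_MINUS = """\
##gff-version 3
chrT\ttest\tgene\t101\t600\t.\t-\t.\tID=geneB
chrT\ttest\tmRNA\t101\t600\t.\t-\t.\tID=geneB.t1;Parent=geneB
chrT\ttest\texon\t501\t600\t.\t-\t.\tParent=geneB.t1
chrT\ttest\texon\t301\t400\t.\t-\t.\tParent=geneB.t1
chrT\ttest\texon\t101\t200\t.\t-\t.\tParent=geneB.t1
chrT\ttest\tCDS\t501\t550\t.\t-\t0\tParent=geneB.t1
chrT\ttest\tCDS\t301\t400\t.\t-\t1\tParent=geneB.t1
chrT\ttest\tCDS\t151\t200\t.\t-\t0\tParent=geneB.t1
"""


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF_PLUS)
    return path


@pytest.fixture
def toy_gff3_minus(tmp_path):
    path = tmp_path / "toy_minus.gff3"
    path.write_text(TOY_GFF_MINUS)
    return path


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A small simulated genome/annotation bundle shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(seed=11, n_genes=20)
    bundle = simulate_genome_annotation(cfg, out)
    return cfg, bundle


@pytest.fixture(scope="session")
def sim_psi(tmp_path_factory, sim_bundle):
    cfg, bundle = sim_bundle
    out = tmp_path_factory.mktemp("psi")
    return simulate_psi_tables(cfg, bundle, out)


@pytest.fixture(scope="session")
def toy_dag(tmp_path_factory):
    from splicescape.ontology import OntologyDag
    from splicescape.simulate import _write_obo

    path = tmp_path_factory.mktemp("obo") / "toy.obo"
    _write_obo(path)
    return OntologyDag.from_obo(path)
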