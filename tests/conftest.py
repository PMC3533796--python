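"""Shared fixtures: designs, small synthetic experiments, toy annotations."""

from __future__ import annotations

import numpy as np
import pytest

from erps.design import default_design
from erps.synth import SelectionModel, generate_experiment


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def neutral_experiment():
    """A small all-neutral experiment reused across read-only tests."""
    return generate_experiment(n_snps=3000, seed=101)


@pytest.fixture(scope="session")
def selection_experiment():
    """2000 neutral + 30 additive + 15 overdominant planted loci."""
    planted = [(i, SelectionModel("additive", s=0.1, p0=0.05 + 0.15 * i / 29))
               for i in range(30)]
    planted += [(i, SelectionModel("overdominant", s1=0.45, s2=0.55, p0=0.3))
                for i in range(30, 45)]
    return generate_experiment(n_snps=2045, seed=202, planted=planted)


# --- toy gene models for annotation tests ---------------------------------

GENOME_LEN = 2000


def _toy_sequence() -> str:
    seq = list("A" * GENOME_LEN)
    # gene gA (+): exons 1001-1060 / 1101-1190, CDS 1021-1060 + 1101-1141
    cds_a = "ATG" + "GAT" * 12 + "TAA"  # 42 bp
    for i, b in enumerate(cds_a[:40]):
        seq[1020 + i] = b          # first CDS segment, 0-based 1020..1059
    rest = "GAT" * 13 + "TA"       # 41 bp second segment (total 81, /3)
    for i, b in enumerate(rest):
        seq[1100 + i] = b
    return "".join(seq)


TOY_GFF = """\
##gff-version 3
2L\ttoy\tgene\t1001\t1190\t.\t+\t.\tID=gA
2L\ttoy\tmRNA\t1001\t1190\t.\t+\t.\tID=gA.t1;Parent=gA
2L\ttoy\texon\t1001\t1060\t.\t+\t.\tID=gA.e1;Parent=gA.t1
2L\ttoy\texon\t1101\t1190\t.\t+\t.\tID=gA.e2;Parent=gA.t1
2L\ttoy\tCDS\t1021\t1060\t.\t+\t0\tID=gA.c1;Parent=gA.t1
2L\ttoy\tCDS\t1101\t1141\t.\t+\t0\tID=gA.c2;Parent=gA.t1
2L\ttoy\tgene\t1061\t1120\t.\t-\t.\tID=gB
2L\ttoy\tmRNA\t1061\t1120\t.\t-\t.\tID=gB.t1;Parent=gB
2L\ttoy\texon\t1061\t1120\t.\t-\t.\tID=gB.e1;Parent=gB.t1
2L\ttoy\tCDS\t1063\t1080\t.\t-\t0\tID=gB.c1;Parent=gB.t1
"""


@pytest.fixture(scope="session")
def toy_annotation(tmp_path_factory):
    """(gene models, GeneIndex-ready) parsed from a toy GFF3 + FASTA."""
    from erps.enrichment import load_gene_models

    d = tmp_path_factory.mktemp("ann")
    gff = d / "toy.gff3"
    fasta = d / "toy.fa"
    gff.write_text(TOY_GFF)
    fasta.write_text(">2L\n" + _toy_sequence() + "\n")
    return load_gene_models(gff, fasta)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
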