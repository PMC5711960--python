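import logging

import numpy as np
import pytest

from fusionscape.model import (
    Caller,
    ConsensusFusion,
    FusionCall,
    GeneAnnotation,
    GeneRecord,
    IgClass,
    SampleMeta,
)
from fusionscape.pipeline import analyze_simulated
from fusionscape.simulate import myeloma_preset, simulate_cohort

logging.getLogger("fusionscape").setLevel(logging.ERROR)


def make_call(
    sample="S1",
    caller=Caller.A,
    gene5="GENE1",
    gene3="GENE2",
    chrom5="chr1",
    chrom3="chr2",
    bp5=1000,
    bp3=2000,
    strand5="+",
    strand3="+",
    junction_pairs=5,
):
    return FusionCall(
        sample_id=sample,
        caller=caller,
        gene5=gene5,
        gene3=gene3,
        chrom5=chrom5,
        chrom3=chrom3,
        bp5=bp5,
        bp3=bp3,
        strand5=strand5,
        strand3=strand3,
        junction_pairs=junction_pairs,
    )


def make_fusion(
    sample="S1",
    gene5="GENE1",
    gene3="GENE2",
    chrom5="chr1",
    bp5=1000,
    chrom3="chr2",
    bp3=2000,
    strand5="+",
    strand3="+",
    jp_a=5,
    jp_b=5,
    **kwargs,
):
    return ConsensusFusion(
        sample_id=sample,
        gene5=gene5,
        gene3=gene3,
        chrom5=chrom5,
        bp5=bp5,
        chrom3=chrom3,
        bp3=bp3,
        strand5=strand5,
        strand3=strand3,
        junction_pairs_a=jp_a,
        junction_pairs_b=jp_b,
        **kwargs,
    )


@pytest.fixture(scope="session")
def toy_annotation():
    """Hand-built annotation with realistic megabase-scale coordinates."""
    genes = [
        GeneRecord("IGHG1", "chr14", 105_000_000, 105_010_000, "+", IgClass.IGH),
        GeneRecord("IGKC", "chr2", 88_000_000, 88_005_000, "-", IgClass.IGK),
        GeneRecord("NSD2", "chr4", 1_800_000, 1_900_000, "+"),
        GeneRecord("TPM4", "chr19", 16_000_000, 16_030_000, "+"),
        GeneRecord("ISYNA1", "chr19", 18_000_000, 18_005_000, "+"),
        GeneRecord("FARAWAY", "chr19", 40_000_000, 40_010_000, "-"),
        GeneRecord("NEAR_EDGE", "chr19", 29_000_000, 30_100_000, "+"),
    ]
    return GeneAnnotation(
        genes,
        chrom_lengths={"chr14": 107e6, "chr2": 243e6, "chr4": 190e6, "chr19": 59e6},
        aliases={"WHSC1": "NSD2", "MMSET": "NSD2"},
    )


@pytest.fixture(scope="session")
def tiny_sim():
    cfg = myeloma_preset(seed=11)
    cfg.n_patients = 30
    cfg.n_cell_lines = 8
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_sim):
    return analyze_simulated(tiny_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
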