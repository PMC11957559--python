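import numpy as np
import pandas as pd
import pytest

from xdose.io import CountMatrix, GeneAnnotation, SampleSheet
from xdose.sim import GroupSpec, SimConfig, simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    """Two-scaffold study used by fast unit tests."""
    return SimConfig(
        n_scaffolds=2,
        scaffold_lengths=[400_000, 300_000],
        x_scaffold=1,
        genes_per_scaffold=[30, 20],
        groups=[GroupSpec("M", "brain", "A"), GroupSpec("F", "brain", "A")],
        sex_biased_fraction=0.0,
        tissue_specific_fraction=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_annotation(small_config)


def study_config(seed, dc_mode="complete_upregulation", **kw):
    """Default-size single-group study (200 X / 2002 autosomal genes)."""
    settings = dict(
        groups=[GroupSpec("M", "brain", "A"), GroupSpec("F", "brain", "A")],
        dc_mode=dc_mode,
        sex_biased_fraction=0.0,
        tissue_specific_fraction=0.0,
        seed=seed,
    )
    settings.update(kw)
    return SimConfig(**settings)


@pytest.fixture
def toy_annotation():
    """Hand-built 4-gene annotation on two scaffolds (scaffold B is the X)."""
    genes = pd.DataFrame(
        {
            "scaffold": ["chrA", "chrA", "chrB", "chrB"],
            "strand": ["+", "-", "+", "+"],
            "start": [1, 2001, 101, 5001],
            "end": [1000, 3000, 1100, 6000],
            "exon_union_length": [1000, 500, 1000, 2000],
        },
        index=pd.Index(["gA1", "gA2", "gB1", "gB2"], name="gene_id"),
    )
    exons = {
        "gA1": [(1, 1000)],
        "gA2": [(2001, 2500)],
        "gB1": [(101, 1100)],
        "gB2": [(5001, 6000), (5001, 7000 - 1000)],
    }
    # gB2 union: (5001,6000) within a 2000bp union recorded; keep consistent
    exons["gB2"] = [(5001, 6000), (6500, 7499)]
    genes.loc["gB2", "end"] = 7499
    return GeneAnnotation(
        genes=genes,
        exons=exons,
        scaffold_lengths={"chrA": 10_000, "chrB": 10_000},
        x_scaffolds=frozenset({"chrB"}),
    )


@pytest.fixture
def toy_counts(toy_annotation):
    counts = pd.DataFrame(
        {
            "s1": [100, 200, 300, 400],
            "s2": [10, 20, 30, 40],
        },
        index=toy_annotation.gene_ids,
    )
    return CountMatrix(counts)


@pytest.fixture
def toy_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sex": ["M", "F"],
                "tissue": ["brain", "brain"],
                "stage": ["A", "A"],
                "replicate": [1, 1],
            },
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )
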