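import numpy as np
import pytest

from rvburden import AnnotatedVariant, VariantKey
from rvburden.simulate import SimConfig, simulate_cohort_data


def table1_variants():
    """The three recurrent missense variants of the worked example, with
    the published annotation fields (frequencies absent where the source
    shows '.')."""
    rows = [
        # (pos, ref, alt, af_1000g, af_exac, mt_score, mt_pred, rsvm_score, rsvm_pred, protein)
        (4, "G", "A", None, None, 0.974, "D", 0.38, "D", "p.2A>T"),
        (4553, "G", "A", 0.002, 0.001, 1.0, "D", 0.973, "D", "p.1518R>H"),
        (8539, "A", "G", None, 0.0031, 0.994, "D", 0.138, "D", "p.2847T>A"),
    ]
    return [
        AnnotatedVariant(
            key=VariantKey("chr15", pos, ref, alt),
            gene="RYR3",
            consequence="missense",
            af_1000g=af1,
            af_exac=af2,
            mt_score=mts,
            mt_pred=mtp,
            rsvm_score=rss,
            rsvm_pred=rsp,
            protein_change=prot,
        )
        for pos, ref, alt, af1, af2, mts, mtp, rss, rsp, prot in rows
    ]


@pytest.fixture
def ryr3_variants():
    return table1_variants()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    cfg = SimConfig(seed=11, n_genes=60, panel_overlap_frac=0.0)
    return cfg, simulate_cohort_data(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A full on-disk fixture bundle (VCF, annotations, panel, gene sets,
    edges) from the generator."""
    from rvburden.simulate import (
        simulate_cohort,
        simulate_edges,
        simulate_gene_sets,
        write_edges,
        write_gene_sets,
    )

    out = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=5, n_genes=80, panel_overlap_frac=0.0)
    truth = simulate_cohort(cfg, str(out))
    collection, planted = simulate_gene_sets(cfg)
    write_gene_sets(collection, str(out))
    write_edges(simulate_edges(cfg), str(out / "edges.tsv"))
    return cfg, truth, out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
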