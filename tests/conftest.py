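import pytest

from organsweep.core import RefClass
from organsweep.simulate import (
    ContigSpec,
    HgtInsert,
    SimConfig,
    Source,
    generate,
)


def mini_config(seed=7):
    """A small planted-contamination scenario that runs in seconds.

    70 kb nuclear genome (one 6 kb numt -> 76 kb final) in two contigs,
    20 kb mitogenome and 12 kb plastome as one contig each; copy ratios
    20x/50x over 10x nuclear depth.
    """
    return SimConfig(
        seed=seed,
        nuclear_len=70_000,
        mito_len=20_000,
        chlo_len=12_000,
        copy_ratio={RefClass.MITO: 20.0, RefClass.CHLO: 50.0},
        nuclear_depth=10.0,
        read_len=100,
        frag_len=250,
        hgt_inserts=(HgtInsert(RefClass.MITO, 6_000, 5_000),),
        contig_plan=(
            ContigSpec(Source.NUCLEAR, 0, 66_000),  # carries the numt, ALCR ~0.091
            ContigSpec(Source.NUCLEAR, 66_000, 76_000),
            ContigSpec(Source.MITO, 0, 20_000),
            ContigSpec(Source.CHLO, 0, 12_000),
        ),
    )


@pytest.fixture(scope="session")
def mini_scenario(tmp_path_factory):
    """Materialized mini scenario, shared across tests (read-only)."""
    outdir = tmp_path_factory.mktemp("mini_scenario")
    return generate(mini_config(), outdir, write_fastq=True)

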