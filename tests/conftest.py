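import pytest
from hypothesis import HealthCheck, settings

from wormdrift.synthetic_data import SimConfig, SVTypeSpec, derive_lineages, build_ancestor, emit

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """Two 100-kb chromosomes with a scaled-down event plan (fast unit tests)."""
    defaults = dict(
        n_chromosomes=2,
        chrom_length=100_000,
        n_te_copies=12,
        n_te_moves_intra=2,
        n_te_moves_inter=1,
        n_te_dups=1,
        min_move_displacement=10_000,
        n_genes=6,
        snp_rate=1e-3,
        indel_rate=2e-4,
        sv_spec={
            "DEL": SVTypeSpec(1, 50, 200),
            "INS": SVTypeSpec(1, 50, 200),
            "INV": SVTypeSpec(1, 100, 300),
            "DUP": SVTypeSpec(1, 100, 200),
            "TRANS": SVTypeSpec(1, 100, 200),
            "NOTAL": SVTypeSpec(1, 200, 400),
        },
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated genome pair shared across tests."""
    cfg = small_config(seed=0)
    ancestor = build_ancestor(cfg)
    genome_a, genome_b, truth = derive_lineages(ancestor, cfg)
    return cfg, genome_a, genome_b, truth


@pytest.fixture(scope="session")
def small_bundle(small_sim, tmp_path_factory):
    """The small simulated pair emitted to disk."""
    _, genome_a, genome_b, truth = small_sim
    outdir = tmp_path_factory.mktemp("bundle")
    emit(genome_a, genome_b, truth, outdir)
    return outdir
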