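import pytest

from silentshift import GeneratorConfig, gen_cds, gen_expression, gen_ribo_libraries
from silentshift.simulate import synthetic_p118_cds


@pytest.fixture(scope="session")
def p118_cds():
    """Synthetic CDS with the GAC·CCG·TCC context at codons 117-119."""
    return synthetic_p118_cds()


@pytest.fixture(scope="session")
def small_library():
    """A small but non-trivial simulated ribo-seq study, shared read-only."""
    cfg = GeneratorConfig(seed=11, n_sequences=20, codons_per_seq=120, depth=30_000)
    rng = cfg.rng()
    cds_set = gen_cds(cfg, rng)
    expression = gen_expression(cfg, [c.id for c in cds_set], rng)
    rpf, mrna, models = gen_ribo_libraries(cfg, cds_set, expression, rng)
    return cfg, cds_set, expression, rpf, mrna, models
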