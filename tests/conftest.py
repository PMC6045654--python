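import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_edge_list(tmp_path):
    """Eight-edge TSV file with header, comment, and a directed duplicate."""
    lines = [
        "source\ttarget\tfrequency\tdirection",
        "# inferred pairs",
        "GENE_A\tGENE_B\t0.62\t->",
        "GENE_B\tGENE_A\t0.55\t<-",
        "GENE_B\tGENE_C\t0.25",
        "GENE_C\tGENE_D\t0.30",
        "GENE_D\tGENE_E\t0.35",
        "GENE_E\tGENE_F\t0.50",
        "GENE_F\tGENE_G\t0.80",
        "GENE_G\tGENE_H\t1.0",
        "GENE_H\tGENE_A\t0.20",
    ]
    p = tmp_path / "edges.tsv"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture(scope="session")
def goe_spectrum():
    """Eigenvalues of a seeded 1000x1000 GOE matrix (shared across tests)."""
    from rmtnet import generate_goe, eigenvalues
    return eigenvalues(generate_goe(1000, seed=7), source="goe1000")


@pytest.fixture(scope="session")
def uniform_levels():
    from rmtnet import generate_poisson_levels
    from rmtnet.spectral import Spectrum
    return Spectrum(generate_poisson_levels(4000, seed=11), source="uniform4000")
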