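import numpy as np
import pytest

from phyloplace.likelihood import optimize_all
from phyloplace.models import load_empirical_model, uniform_model
from phyloplace.msa import MSA
from phyloplace.simulate import SimConfig, simulate_reference_package
from phyloplace.tree import parse_newick


@pytest.fixture(scope="session")
def wag():
    return load_empirical_model("WAG", alpha=1.0)


@pytest.fixture(scope="session")
def uniform1():
    """Equal-rates model without rate heterogeneity (closed forms apply)."""
    return uniform_model(n_categories=1)


@pytest.fixture
def quartet():
    return parse_newick("((A:0.1,B:0.25):0.15,(C:0.3,D:0.05):0.2);")


@pytest.fixture
def quartet_msa():
    return MSA({"A": "ACD", "B": "AC-", "C": "GCD", "D": "AXD"})


@pytest.fixture(scope="session")
def sim_pkg():
    """Small synthetic reference package shared by placement tests."""
    return simulate_reference_package(SimConfig(n_leaves=12, n_cols=200, seed=11))


@pytest.fixture(scope="session")
def sim_fit(sim_pkg):
    model = load_empirical_model("WAG", alpha=1.0)
    return optimize_all(sim_pkg.tree, sim_pkg.msa, model, estimate_alpha=False, tol=1e-3)


def random_state_msa(labels, n_cols, seed):
    """Random unrelated sequences (for structural tests, not inference)."""
    rng = np.random.default_rng(seed)
    from phyloplace.alphabet import AMINO_ACIDS

    return MSA(
        {l: "".join(rng.choice(list(AMINO_ACIDS), size=n_cols)) for l in labels}
    )
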