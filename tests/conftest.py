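import pytest
from hypothesis import HealthCheck, settings

from ypanel.panel import Marker, MarkerClass, build_tree

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mk(name, haplogroup, pos=None, anc="A", der="G", amp=None, amp_len=200,
       mclass=MarkerClass.SNP):
    """Shorthand marker constructor for hand-built panels."""
    if pos is None:
        pos = 2_650_000 + abs(hash(name)) % 20_000_000
    return Marker(
        name=name,
        position=pos,
        ancestral_allele=anc,
        derived_allele=der,
        marker_class=mclass,
        haplogroup=haplogroup,
        amplicon_id=amp or f"AMP_{name}",
        amplicon_length=amp_len,
    )


@pytest.fixture(scope="session")
def chain_panel():
    """One marker per node of a deep O1b2 chain plus outgroup clades,
    mirroring how a high-resolution panel resolves one lineage."""
    chain = ["O", "O1", "O1b", "O1b2", "O1b2a", "O1b2a1", "O1b2a1a",
             "O1b2a1a1", "O1b2a1a1a", "O1b2a1a1a1", "O1b2a1a1a1a"]
    labels = chain + ["O2", "O2a", "O2a2", "C", "C2", "N", "Q", "R1a"]
    return [mk(f"M{i:03d}", lab) for i, lab in enumerate(labels)]


@pytest.fixture(scope="session")
def chain_tree(chain_panel):
    return build_tree(chain_panel)


@pytest.fixture(scope="session")
def fixture_panel():
    from ypanel.synthdata import generate_panel_fixture

    return generate_panel_fixture(n_markers=120, seed=42)
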