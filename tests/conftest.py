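import pytest

from netrd import (
    HoleEnlargementOutcome,
    SecondaryDamage,
    SyntheticConfig,
    TextileTestResult,
    generate_lab_panel,
    make_fixture_suite,
)


def make_record(
    bursting=700.0,
    snag=200.0,
    abrasion=400,
    end_mm=3.0,
    damage=SecondaryDamage.NONE,
    net_id="net1",
    brand="brandA",
):
    return TextileTestResult(
        net_id=net_id,
        brand=brand,
        bursting_strength_kpa=bursting,
        snag_strength_n=snag,
        abrasion_rubs=abrasion,
        hole_enlargement=HoleEnlargementOutcome(end_mm, damage),
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(d)
    return d


@pytest.fixture(scope="session")
def synthetic_panel():
    """16-net panel spanning the score-matrix ranges, fixed seed."""
    return generate_lab_panel(SyntheticConfig(n_nets=16, seed=1))
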