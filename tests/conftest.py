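import pytest

from majorref.editor import apply_edits
from majorref.fixtures import ScenarioSpec, make_scenario
from majorref.liftover import build_chain, build_map
from majorref.selector import MajorAlleleEdit


@pytest.fixture(scope="session")
def toy_genome():
    return {"chr1": "ACGTACGTAC"}


@pytest.fixture(scope="session")
def toy_edits():
    """One SNP, one 1 bp deletion, one 2 bp insertion on a 10 bp genome."""
    return [
        MajorAlleleEdit("chr1", 2, "C", "G", 0.6, "SNP"),
        MajorAlleleEdit("chr1", 5, "AC", "A", 0.7, "INDEL"),
        MajorAlleleEdit("chr1", 8, "T", "TGG", 0.8, "INDEL"),
    ]


@pytest.fixture(scope="session")
def toy_applied(toy_genome, toy_edits):
    new_genome, elog = apply_edits(toy_genome, toy_edits)
    return new_genome, elog


@pytest.fixture(scope="session")
def toy_map(toy_applied):
    return build_map(toy_applied[1])


@pytest.fixture(scope="session")
def scenario():
    """The default seeded scenario, shared across the suite."""
    return make_scenario(ScenarioSpec())


@pytest.fixture(scope="session")
def scenario_applied(scenario):
    from majorref.selector import select_major_allele, resolve_all

    candidates = [
        e for v in scenario.variants
        if (e := select_major_allele(v)) is not None
    ]
    kept, dropped = resolve_all(candidates)
    new_genome, elog = apply_edits(scenario.genome, kept)
    return kept, dropped, new_genome, elog


@pytest.fixture(scope="session")
def scenario_map(scenario_applied):
    return build_map(scenario_applied[3])


@pytest.fixture(scope="session")
def scenario_chains(scenario_applied):
    return build_chain(scenario_applied[3])
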