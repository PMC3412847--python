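import pytest

from introntrace.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """Six-family, three-species bundle without snoRNAs."""
    return simulate(SimConfig(n_families=6, seed=101))


@pytest.fixture(scope="session")
def sno_bundle():
    """Bundle with heavy snoRNA planting and cis-duplication."""
    return simulate(SimConfig(
        n_families=8, seed=202,
        snorna_cd_prob=0.35, snorna_haca_prob=0.15, duplication_prob=0.5,
    ))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_bundle):
    d = tmp_path_factory.mktemp("bundle")
    small_bundle.write(d)
    return d


def families_of(bundle):
    """Group a bundle's gene models into {family_id: {species: GeneModel}}."""
    fams = {}
    by_sp = {sp: {g.gene_id: g for g in models}
             for sp, models in bundle.gene_models.items()}
    for fam_id, sp, gid in bundle.families:
        fams.setdefault(fam_id, {})[sp] = by_sp[sp][gid]
    return fams
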