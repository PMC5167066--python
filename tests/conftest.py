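import pytest

from genestruct.fixtures import FixtureBundle, make_fixed_fixtures
from genestruct.structure_mapper import MappingResources


@pytest.fixture(scope="session")
def bundle() -> FixtureBundle:
    return make_fixed_fixtures()


@pytest.fixture(scope="session")
def resources(bundle) -> MappingResources:
    return bundle.resources()


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixed_bundle")
    bundle.write(out)
    return out


@pytest.fixture()
def cli_args(bundle_dir):
    return [
        "--genome", str(bundle_dir / "genome.fa"),
        "--gff3", str(bundle_dir / "genes.gff3"),
        "--isoforms", str(bundle_dir / "isoforms.fa"),
        "--mapping", str(bundle_dir / "mapping.tsv"),
    ]
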