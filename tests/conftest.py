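import warnings

import pytest

from tmbcount import FixtureSpec, generate_fixture
from tmbcount.pipeline import run_sample


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default synthetic universe, generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    fixture = generate_fixture(FixtureSpec(seed=0), out)
    return out, fixture


def run_fixture_pipeline(directory, **overrides):
    """Run the full pipeline on a generated fixture directory."""
    kwargs = dict(strelka2=f"{directory}/strelka2.vcf",
                  mutect2=f"{directory}/mutect2.vcf",
                  manta=f"{directory}/manta.vcf",
                  reference=f"{directory}/ref.fa",
                  gtf=f"{directory}/ann.gtf",
                  panel_genes=f"{directory}/panel.txt",
                  tsg_genes=f"{directory}/tsg.txt",
                  cosmic=f"{directory}/cosmic.vcf")
    kwargs.update(overrides)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_sample(**kwargs)


@pytest.fixture(scope="session")
def fixture_run(fixture_dir):
    directory, fixture = fixture_dir
    return fixture, run_fixture_pipeline(directory)
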