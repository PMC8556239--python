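import pytest

from nbudget import synth


@pytest.fixture(scope="session")
def identity_result():
    """Default scenario with degradation switched off (identity pathway)."""
    cfg = synth.SynthConfig(seed=1, degradation=synth.DegradationSpec.none())
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def degraded_result():
    """Default moderate-degradation scenario."""
    return synth.generate(synth.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory, identity_result):
    """Undegraded scenario written to disk."""
    d = tmp_path_factory.mktemp("scenario")
    synth.write_scenario(identity_result, d)
    return d
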