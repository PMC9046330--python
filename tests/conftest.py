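import pytest

import fallscea as fc


@pytest.fixture(scope="session")
def params() -> fc.ModelParameters:
    """Packaged default inputs (published means, CIs and settings)."""
    return fc.load_parameters()


@pytest.fixture(scope="session")
def base_case(params) -> fc.CUAResult:
    return fc.run_base_case(params)
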