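import pytest

from kinstep import preset, preset_names


@pytest.fixture(scope="session")
def dmk():
    return preset("DmK")


@pytest.fixture(scope="session")
def hsk():
    return preset("HsK")


@pytest.fixture(scope="session")
def hsk6aa():
    return preset("HsK-6AA")


@pytest.fixture(scope="session")
def hskcl6aa():
    return preset("HsK-CL-6AA")


@pytest.fixture(scope="session")
def kif17():
    return preset("KIF17")


@pytest.fixture(scope="session", params=preset_names())
def any_preset(request):
    return preset(request.param)
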