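import pytest

import dietmcda as dm


@pytest.fixture(scope="session")
def pt_case() -> dm.CaseStudy:
    return dm.case_study("PT")


@pytest.fixture(scope="session")
def dk_case() -> dm.CaseStudy:
    return dm.case_study("DK")


@pytest.fixture(scope="session")
def both_cases(pt_case, dk_case):
    return {"PT": pt_case, "DK": dk_case}
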