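import hypothesis
import pytest

from phasecnv.sites import SiteSpec, SiteType

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def icn_site() -> SiteSpec:
    return SiteSpec("icn1", SiteType.ICN, (), max_total_copies=4, max_allele_copies=2)


@pytest.fixture
def snvc_site() -> SiteSpec:
    return SiteSpec("snvc1", SiteType.SNVC, ("A", "B"), max_total_copies=4, max_allele_copies=2)


@pytest.fixture
def snp_site() -> SiteSpec:
    return SiteSpec("snp1", SiteType.SNP, ("a", "t"), max_total_copies=2, max_allele_copies=1)
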