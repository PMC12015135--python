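import pytest
from hypothesis import HealthCheck, settings

from kinophos import Kinase, KinaseType, PhosphoSite
from kinophos.io import aligned_family_from_rows

settings.register_profile(
    "reproducible",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("reproducible")


@pytest.fixture
def kinase_k1():
    # 40-residue toy kinase: domain 11-30, disorder 1-8
    seq = "MAAAGSTYRKLLSDEKTYGGHRSPQWERTYASDFGHKLMT"
    return Kinase(
        kinase_id="K1",
        gene_symbol="G1",
        group="TK",
        family="FAMX",
        kinase_type=KinaseType.Y,
        sequence=seq,
        domain_intervals=[(11, 30)],
        disordered_intervals=[(1, 8)],
    )


@pytest.fixture
def sites_k1(kinase_k1):
    seq = kinase_k1.sequence

    def site(pos, ht, lt, tags=frozenset()):
        return PhosphoSite(
            kinase_id="K1", residue=seq[pos - 1], position=pos,
            ht_count=ht, lt_count=lt, function_tags=tags,
        )

    return [
        site(6, 50, 2, frozenset({"activation"})),  # S6
        site(7, 50, 5),                             # T7
        site(8, 10, 0),                             # Y8
        site(17, 3, 1, frozenset({"localization", "interaction"})),  # T17
        site(23, 0, 2),                             # S23
    ]


@pytest.fixture
def identity_family():
    seq = "MKTLSDYGGARSPQW" * 2
    return aligned_family_from_rows("IDENT", {f"K{i}": seq for i in range(3)})
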