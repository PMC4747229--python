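import pytest

from msiprofiler.cohort import Cohort, MsiStatus, Mutation, Tumor, infer_variant_class
from msiprofiler.datasets import PTEN_MUTATIONS
from msiprofiler.simulate import generate_reference_fixtures


@pytest.fixture(scope="session")
def references():
    """Synthetic coding-sequence fixtures (PTEN-like + repeat-free control)."""
    return generate_reference_fixtures()


def build_pten_reference_cohort() -> Cohort:
    """The published PTEN mutation table embedded in a cohort of the
    published group sizes (113 MSS / 29 MSI-H); all other tumors carry no
    mutations.  Case 218 and 264 carry multiple PTEN mutations."""
    tumors: dict[str, Tumor] = {}
    for case, group, hgvs_p, hgvs_c, _exon in PTEN_MUTATIONS:
        t = tumors.setdefault(case, Tumor(id=case, msi_status=MsiStatus(group)))
        t.add_mutation(
            Mutation(case, "PTEN", hgvs_c, hgvs_p, infer_variant_class(hgvs_c))
        )
    n_mss = sum(1 for t in tumors.values() if t.msi_status is MsiStatus.MSS)
    n_msih = len(tumors) - n_mss
    fillers = [
        Tumor(id=f"MSS_F{i:03d}", msi_status=MsiStatus.MSS) for i in range(113 - n_mss)
    ] + [
        Tumor(id=f"MSIH_F{i:03d}", msi_status=MsiStatus.MSI_H)
        for i in range(29 - n_msih)
    ]
    return Cohort(tumors=list(tumors.values()) + fillers, name="pten-reference")


@pytest.fixture()
def pten_cohort():
    return build_pten_reference_cohort()
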