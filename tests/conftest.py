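import pytest

from stromaclone.calls import MutationCall, SpecimenProfile
from stromaclone.datasets import synthetic_reference_cohort


def make_call(
    pos=100,
    vaf=0.2,
    depth=1000,
    gene="GENE1",
    effect="missense",
    patient="P01",
    component="neoplasm",
    chrom="1",
    ref="A",
    alt="G",
    polyphen=0.2,
    sift=0.6,
    pop_af_max=0.0,
    hq_alt_reads=None,
    **kwargs,
):
    """Terse MutationCall factory for tests."""
    if hq_alt_reads is None:
        hq_alt_reads = int(round(vaf * depth))
    return MutationCall(
        patient_id=patient,
        specimen_id=f"{patient}.{component}",
        component=component,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        effect=effect,
        hq_alt_reads=hq_alt_reads,
        depth=depth,
        vaf=vaf,
        polyphen=polyphen,
        sift=sift,
        pop_af_max=pop_af_max,
        **kwargs,
    )


def make_profile(calls, component="neoplasm", patient="P01", tcf=float("nan")):
    return SpecimenProfile(
        patient_id=patient, component=component, mutations=list(calls), tcf=tcf
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """Marginal-matched synthetic reference cohort (50 patients)."""
    return synthetic_reference_cohort()
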