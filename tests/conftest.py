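from datetime import date

import pytest

from trialtarget import (
    DrugTargetLink,
    InterventionType,
    ReferenceRecord,
    ReferenceType,
    StudyDiseaseLink,
    StudyRecord,
    StudyType,
)


def make_study(nct="NCT00000001", study_type=StudyType.INTERVENTIONAL,
               intervention_type=InterventionType.DRUG,
               start=date(2018, 1, 1), completion=date(2020, 1, 1)):
    return StudyRecord(nct_id=nct, study_type=study_type,
                       intervention_type=intervention_type,
                       start_date=start, completion_date=completion)


def make_ref(nct="NCT00000001", pmid="12345", rtype=ReferenceType.RESULT, citation="A et al."):
    return ReferenceRecord(nct_id=nct, pmid=pmid, reference_type=rtype, citation=citation)


def make_drug_link(nct="NCT00000001", drug="metformin", gene="GCK", tdl=None):
    return DrugTargetLink(nct_id=nct, drug_name=drug, gene_symbol=gene, tdl=tdl)


def make_disease_link(nct="NCT00000001", doid="DOID:9352", name="type 2 diabetes"):
    return StudyDiseaseLink(nct_id=nct, doid=doid, disease_name=name)


@pytest.fixture
def minimal_tables():
    """One interventional drug study, one drug->gene link, one disease link."""
    return dict(
        studies=[make_study()],
        references=[],
        drug_links=[make_drug_link()],
        disease_links=[make_disease_link()],
    )
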