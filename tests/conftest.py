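import pytest

from adeconcord.vocab import (AssociationSnapshot, AtcMap, DrugSynonymMap,
                              MeddraMap, VocabularyBundle)


@pytest.fixture()
def synonyms() -> DrugSynonymMap:
    return DrugSynonymMap({
        "tylenol": "acetaminophen",
        "acetaminophen": "acetaminophen",
        "advil": "ibuprofen",
        "ibuprofen": "ibuprofen",
    })


@pytest.fixture()
def meddra() -> MeddraMap:
    return MeddraMap(
        pt_to_hlt={
            "myocardial infarction": frozenset({"ischaemic coronary artery disorders",
                                                "coronary necrosis and vascular insufficiency"}),
            "headache": frozenset({"headaches nec"}),
            "migraine": frozenset({"headaches nec"}),
            "nausea": frozenset({"nausea and vomiting symptoms"}),
        },
        hlt_to_soc={
            "ischaemic coronary artery disorders": ("Cardiac disorders",),
            "coronary necrosis and vascular insufficiency": ("Cardiac disorders",),
            "headaches nec": ("Nervous system disorders",),
            "nausea and vomiting symptoms": ("Gastrointestinal disorders",),
        },
    )


@pytest.fixture()
def atc() -> AtcMap:
    return AtcMap({
        "acetaminophen": ("N02BE01",),
        "ibuprofen": ("M01AE01", "C01EB16"),
        "amoxicillin": ("J01CA04",),
    })


@pytest.fixture()
def bundle(synonyms, meddra, atc) -> VocabularyBundle:
    return VocabularyBundle(synonyms, meddra, atc)


def snap(pairs, **kw) -> AssociationSnapshot:
    defaults = dict(source="test", year=2005.0, level="HLT", freq={})
    defaults.update(kw)
    return AssociationSnapshot(pairs=frozenset(pairs), **defaults)
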