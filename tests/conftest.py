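import pytest

from annocompare import (
    AnnotationCollection,
    FeatureList,
    EnrichmentResult,
    filter_significant,
)


@pytest.fixture
def toy_collection() -> AnnotationCollection:
    return AnnotationCollection(
        members={
            "GO:1": frozenset({"g1", "g2", "g3"}),
            "GO:2": frozenset({"g2", "g3", "g4"}),
            "GO:3": frozenset({"g7", "g8"}),
        },
        description={"GO:1": "alpha", "GO:2": "beta", "GO:3": "gamma"},
    )


@pytest.fixture
def toy_universe() -> frozenset:
    return frozenset(f"g{i}" for i in range(1, 11))


@pytest.fixture
def toy_list(toy_universe) -> FeatureList:
    return FeatureList("A1", frozenset({"g1", "g2", "g3", "g7"}), toy_universe)


def make_result(aid, list_id="A1", k=3, n=8, K=6, N=20, p=0.005):
    return EnrichmentResult(
        annotation_id=aid,
        list_id=list_id,
        n_annotated_in_list=k,
        n_in_list=n,
        n_annotated_in_universe=K,
        n_universe=N,
        p_value=p,
    )


def make_sig_set(list_id, annotation_ids, p=0.001):
    results = [make_result(a, list_id=list_id, p=p) for a in annotation_ids]
    return filter_significant(results, p_cutoff=0.01, min_features=2)
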