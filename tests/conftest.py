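import numpy as np
import pandas as pd
import pytest

from gopriorit.activity_matrix import QueryDataset
from gopriorit.knowledge_base import (
    DrugTarget,
    GORegulation,
    KnowledgeBase,
    Study,
    StudySet,
)


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    """Two activating studies over four genes, two processes, two drugs.

    Hand-checkable by design: g1 is ranked 1/4 in study A and 2/4 in B, so
    its K-rank under the set-size divisor is (1.0 + 0.75)/2 = 0.875.
    """
    studies = {
        "A": Study("A", {"g1": 1, "g2": 2, "g3": 3, "g4": 4}),
        "B": Study("B", {"g1": 2, "g2": 1, "g3": 3, "g4": 4}),
    }
    return KnowledgeBase(
        studies=studies,
        study_sets={"activating": StudySet("activating", ["A", "B"])},
        regulations=[
            GORegulation("g1", "GO:0000001", "positive", "proc one"),
            GORegulation("g2", "GO:0000001", "negative", "proc one"),
            GORegulation("g3", "GO:0000002", "positive", "proc two"),
            GORegulation("g4", "GO:0000002", "negative", "proc two"),
        ],
        drug_targets=[
            DrugTarget("drugA", "g1", "alpha", "inhibitor", "synthetic"),
            DrugTarget("drugA", "g3", "alpha", "inhibitor", "synthetic"),
            DrugTarget("drugB", "g2", "beta", "inhibitor", "synthetic"),
        ],
    )


@pytest.fixture
def tiny_query() -> QueryDataset:
    samples = ["s1", "s2", "s3", "s4"]
    genes = ["g1", "g2", "g3", "g4"]

    def layer(rows, default):
        data = np.full((len(genes), len(samples)), default, dtype=object)
        df = pd.DataFrame(data, index=genes, columns=samples)
        for (g, s), v in rows.items():
            df.loc[g, s] = v
        return df

    return QueryDataset(
        expression=layer({("g1", "s1"): "up", ("g1", "s3"): "up", ("g2", "s2"): "down"}, "unchanged"),
        cna=layer({("g3", "s4"): "amplified"}, "neutral"),
        mutation=layer({}, "none"),
    )
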