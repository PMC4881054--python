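"""K-rank: the normalized multi-study cancer-essentiality score of a gene.

Each study contributes a per-study normalized rank u = (N - r + 1)/N, where
r is the gene's rank (1 = strongest evidence) and N the study size, so
u in (0, 1] and u = 1 exactly for the top-ranked gene.  The K-rank of a
gene within a study set is the sum of its u values divided by the total
number of studies in the set, so recurrence across studies is rewarded:
a gene supported by two studies outscores a gene with the same ranks in
only one.  An alternative divisor — the number of supporting studies —
is available via ``denominator="support"``.

Genes absent from every study of the set receive no K-rank (they carry no
evidence, which is different from carrying evidence of irrelevance).
"""

from __future__ import annotations

import pandas as pd

from .knowledge_base import KnowledgeBase

__all__ = ["per_study_score", "compute_kranks"]

KRANK_DENOMINATORS = ("set_size", "support")


def per_study_score(rank: int, study_size: int) -> float:
    """Normalized rank u = (N - r + 1)/N of one gene in one study.

    u is 1 for the top rank and 1/N for the bottom rank; it is the fraction
    of the study's genes ranked at or below this gene.
    """
    if study_size < 1:
        raise ValueError(f"study size must be >= 1, got {study_size}")
    if not 1 <= rank <= study_size:
        raise ValueError(f"rank {rank} outside 1..{study_size}")
    return (study_size - rank + 1) / study_size


def compute_kranks(
    kb: KnowledgeBase,
    set_id: str,
    *,
    denominator: str = "set_size",
) -> pd.DataFrame:
    """K-ranks for every gene with at least one rank in the study set.

    Returns a DataFrame with columns ``gene_id, set_id, krank, n_support``,
    sorted by descending K-rank then gene_id.  ``denominator`` selects the
    divisor: ``"set_size"`` (default) divides the summed per-study scores by
    the total number of studies in the set; ``"support"`` divides by the
    number of studies that actually rank the gene.
    """
    if set_id not in kb.study_sets:
        raise KeyError(f"unknown study set {set_id!r}")
    if denominator not in KRANK_DENOMINATORS:
        raise ValueError(f"denominator must be one of {KRANK_DENOMINATORS}")

    study_ids = kb.study_sets[set_id].study_ids
    n_studies = len(study_ids)
    sums: dict[str, float] = {}
    support: dict[str, int] = {}
    for sid in study_ids:
        study = kb.studies[sid]
        n = study.n
        for gene, rank in study.ranks.items():
            sums[gene] = sums.get(gene, 0.0) + (n - rank + 1) / n
            support[gene] = support.get(gene, 0) + 1

    genes = sorted(sums)
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "set_id": set_id,
            "krank": [
                sums[g] / (n_studies if denominator == "set_size" else support[g])
                for g in genes
            ],
            "n_support": [support[g] for g in genes],
        }
    )
    return df.sort_values(
        by=["krank", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
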