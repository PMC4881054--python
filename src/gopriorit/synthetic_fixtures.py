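"""Synthetic knowledge-bases and query cohorts with planted signal.

Every real input to the pipeline — multi-study rank tables, a process
ontology, a drug-target table, a discretized tumor cohort — is emulated
here at desk scale so that each stage and the end-to-end pipeline can be
exercised and validated without any external download.

The generator plants a coherent signal across all tables: a set of
*planted genes* receives top-decile ranks in every study of the activating
set, the *planted process* is regulated exactly by those genes, the
*planted drug* targets a subset of them, and the query cohort activates the
planted genes (expression up, often with amplification) in a configurable
fraction of samples.  Background genes get uniform ranks, background
processes and drugs draw from background genes, and background expression
cells flip to up/down at a small noise rate.  A correct pipeline should
therefore rank the planted process first (minimal permutation p) and the
planted drug first (highest priority score).

``signal=False`` produces the matched negative control: the same tables
with no planting anywhere (planted genes get background ranks and
background activation), under which the planted drug's rank should be
indistinguishable from its competitors'.

All randomness flows from a single integer seed; generation is fully
deterministic, and fixtures are written in the exact TSV dialects the
loaders read, so tests exercise the real parsers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity_matrix import QueryDataset
from .knowledge_base import (
    DrugTarget,
    GORegulation,
    KnowledgeBase,
    Study,
    StudySet,
    write_knowledge_base,
)

__all__ = ["FixtureSpec", "generate_knowledge_base", "generate_query_dataset", "write_fixture"]

STUDY_SET_IDS = ("activating", "inactivating", "survival")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 100 genes, 3 studies per set, 20 processes, 10 drugs, 50 samples,
    10 planted genes confined to the top rank decile, 60 % cohort activation
    of the planted genes, 2 % background noise.
    """

    n_genes: int = 100
    n_studies_per_set: int = 3
    n_processes: int = 20
    genes_per_process: tuple[int, int] = (4, 8)
    n_drugs: int = 10
    targets_per_drug: tuple[int, int] = (1, 3)
    n_samples: int = 50
    n_planted_genes: int | None = None  # default: top-decile capacity, n_genes // 10
    planted_process: str = "GO:0000001"
    planted_drug: str = "D001"
    activation_fraction: float = 0.6
    noise_rate: float = 0.02
    signal: bool = True
    seed: int = 0
    planted_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_planted_genes is None:
            self.n_planted_genes = max(1, self.n_genes // 10)
        for name in (
            "n_genes",
            "n_studies_per_set",
            "n_processes",
            "n_drugs",
            "n_samples",
            "n_planted_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.activation_fraction <= 1:
            raise ValueError("activation_fraction must be in [0, 1]")
        if not self.planted_genes:
            self.planted_genes = [self.gene_id(i) for i in range(self.n_planted_genes)]

    def gene_id(self, i: int) -> str:
        return f"G{i + 1:04d}"

    def sample_id(self, i: int) -> str:
        return f"S{i + 1:03d}"

    @property
    def gene_ids(self) -> list[str]:
        return [self.gene_id(i) for i in range(self.n_genes)]

    @property
    def background_genes(self) -> list[str]:
        planted = set(self.planted_genes)
        return [g for g in self.gene_ids if g not in planted]


def _study_ranks(spec: FixtureSpec, rng: np.random.Generator, planted: bool) -> dict[str, int]:
    """One study's rank permutation; planted genes confined to the top decile."""
    genes = spec.gene_ids
    n = len(genes)
    if not planted:
        perm = rng.permutation(n)
        return {g: int(r) + 1 for g, r in zip(genes, perm)}
    decile = max(1, n // 10)
    planted_genes = spec.planted_genes
    if len(planted_genes) > decile:
        raise ValueError(
            f"{len(planted_genes)} planted genes exceed top-decile capacity {decile}"
        )
    top = rng.choice(decile, size=len(planted_genes), replace=False) + 1
    remaining = [r for r in range(1, n + 1) if r not in set(int(t) for t in top)]
    rest = rng.permutation(len(remaining))
    ranks = {g: int(r) for g, r in zip(planted_genes, top)}
    for g, i in zip(spec.background_genes, rest):
        ranks[g] = remaining[int(i)]
    return ranks


def generate_knowledge_base(spec: FixtureSpec) -> KnowledgeBase:
    """Synthetic knowledge-base: three study sets, processes, drug targets.

    Planting (when ``spec.signal``) lives in the activating study set; the
    inactivating and survival sets are pure background so study-set wiring
    can be tested.
    """
    rng = np.random.default_rng(spec.seed)
    studies: dict[str, Study] = {}
    study_sets: dict[str, StudySet] = {}
    for set_id in STUDY_SET_IDS:
        ids = []
        for i in range(spec.n_studies_per_set):
            sid = f"{set_id}_study{i + 1}"
            plant = spec.signal and set_id == "activating"
            studies[sid] = Study(
                study_id=sid,
                ranks=_study_ranks(spec, rng, plant),
                source="in_house" if i % 2 == 0 else "curated",
                data_type="synthetic",
                direction_tag=set_id if set_id != "survival" else "survival",
            )
            ids.append(sid)
        study_sets[set_id] = StudySet(set_id, ids)

    regulations: list[GORegulation] = []
    # planted process: regulated exactly by the planted genes, one direction each
    for g in spec.planted_genes:
        direction = "positive" if rng.random() < 0.5 else "negative"
        regulations.append(
            GORegulation(g, spec.planted_process, direction, "planted process")
        )
    background = spec.background_genes
    lo, hi = spec.genes_per_process
    for i in range(1, spec.n_processes):
        pid = f"GO:{i + 1:07d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(background), size=min(size, len(background)), replace=False)
        for j in members:
            direction = "positive" if rng.random() < 0.5 else "negative"
            regulations.append(
                GORegulation(background[int(j)], pid, direction, f"background process {i}")
            )

    drug_targets: list[DrugTarget] = []
    lo_t, hi_t = spec.targets_per_drug
    for i in range(spec.n_drugs):
        drug_id = f"D{i + 1:03d}"
        n_t = int(rng.integers(lo_t, hi_t + 1))
        if drug_id == spec.planted_drug:
            pool = spec.planted_genes
        else:
            pool = background
        members = rng.choice(len(pool), size=min(n_t, len(pool)), replace=False)
        for j in members:
            drug_targets.append(
                DrugTarget(
                    drug_id=drug_id,
                    gene_id=pool[int(j)],
                    drug_name=f"drug {i + 1}",
                    action="inhibitor",
                    source_db="synthetic",
                )
            )

    return KnowledgeBase(
        studies=studies,
        study_sets=study_sets,
        regulations=regulations,
        drug_targets=drug_targets,
    )


def generate_query_dataset(spec: FixtureSpec) -> QueryDataset:
    """Synthetic cohort: planted genes activated in a fraction of samples.

    Planted genes (when ``spec.signal``) are expression-up in
    ``activation_fraction`` of samples, with amplification in roughly half
    of those; background cells are unchanged except for uniform up/down
    noise flips at ``noise_rate``.  Mutations are all 'none' — mutation-rule
    behaviour is tested directly on the activity-matrix rule table.
    """
    # independent stream offset so KB and query can be generated separately
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    genes = spec.gene_ids
    samples = [spec.sample_id(i) for i in range(spec.n_samples)]
    expr = np.full((spec.n_genes, spec.n_samples), "unchanged", dtype=object)
    cna = np.full((spec.n_genes, spec.n_samples), "neutral", dtype=object)
    mut = np.full((spec.n_genes, spec.n_samples), "none", dtype=object)

    planted = set(spec.planted_genes) if spec.signal else set()
    for gi, gene in enumerate(genes):
        if gene in planted:
            active = rng.random(spec.n_samples) < spec.activation_fraction
            expr[gi, active] = "up"
            amp = active & (rng.random(spec.n_samples) < 0.5)
            cna[gi, amp] = "amplified"
        else:
            flips = rng.random(spec.n_samples) < spec.noise_rate
            directions = rng.random(spec.n_samples) < 0.5
            expr[gi, flips & directions] = "up"
            expr[gi, flips & ~directions] = "down"

    return QueryDataset(
        expression=pd.DataFrame(expr, index=genes, columns=samples),
        cna=pd.DataFrame(cna, index=genes, columns=samples),
        mutation=pd.DataFrame(mut, index=genes, columns=samples),
    )


def write_fixture(spec: FixtureSpec, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the fixture's KB tables and query matrices as TSVs; returns paths."""
    out = Path(out_dir)
    kb_dir = out / "kb"
    query_dir = out / "query"
    query_dir.mkdir(parents=True, exist_ok=True)
    paths = write_knowledge_base(generate_knowledge_base(spec), kb_dir)
    q = generate_query_dataset(spec)
    for name, df in (("expression", q.expression), ("cna", q.cna), ("mutation", q.mutation)):
        p = query_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index_label="gene_id")
        paths[name] = p
    return paths
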