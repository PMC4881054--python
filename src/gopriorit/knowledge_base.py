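"""Gene-centric rank store: studies, study sets, GO regulation triples, drug targets.

The knowledge-base is the data model underlying the whole pipeline.  Its atom
is a *study*: a ranked list of genes produced by one statistical analysis of
one molecular data type (an in-house cohort analysis) or by one curated
literature source.  Storing results as ranks, rather than raw statistics,
lets heterogeneous studies — expression fold-changes, copy-number gain
frequencies, survival associations, curated cancer-gene lists — be combined
on a common scale, and makes every downstream score invariant to monotone
transformations of the underlying statistics.

Studies are grouped into *study sets* (default names: ``activating``,
``inactivating``, ``survival``) that share a biological interpretation.
The knowledge-base additionally holds gene -> GO-process regulation triples
with a direction (positive/negative) and drug -> gene-target pairs.

All tables are exchanged as plain TSV with a header row, so the store is
portable and inspectable; see the ``read_*`` / ``write_knowledge_base``
functions for the exact dialects.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Study",
    "StudySet",
    "GORegulation",
    "DrugTarget",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "write_knowledge_base",
    "build_study_from_stats",
    "derive_regulations_from_obo",
]

STUDY_SOURCES = ("in_house", "curated")
DIRECTION_TAGS = ("activating", "inactivating", "survival", "other")
REGULATION_DIRECTIONS = ("positive", "negative")
DRUG_ACTIONS = ("inhibitor", "activator", "unknown")


class KnowledgeBaseError(ValueError):
    """Raised when a knowledge-base table violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Study:
    """A ranked list of genes; rank 1 is the strongest evidence.

    ``ranks`` maps gene_id -> rank and must be a permutation of ``1..N``:
    every gene appears once, no gaps, no ties.  Tied or gapped raw ranks
    from curated sources are resolved with :meth:`from_ranked`.
    """

    study_id: str
    ranks: dict[str, int]
    source: str = "in_house"
    data_type: str = ""
    direction_tag: str = "other"
    empty: bool = False

    def __post_init__(self) -> None:
        if self.source not in STUDY_SOURCES:
            raise KnowledgeBaseError(
                f"study {self.study_id!r}: source must be one of {STUDY_SOURCES}, got {self.source!r}"
            )
        if self.direction_tag not in DIRECTION_TAGS:
            raise KnowledgeBaseError(
                f"study {self.study_id!r}: direction_tag must be one of {DIRECTION_TAGS}"
            )
        n = len(self.ranks)
        if n == 0:
            if not self.empty:
                raise KnowledgeBaseError(
                    f"study {self.study_id!r} has no ranked genes and is not flagged empty"
                )
            return
        values = sorted(self.ranks.values())
        if values != list(range(1, n + 1)):
            raise KnowledgeBaseError(
                f"study {self.study_id!r}: ranks must be a permutation of 1..{n}"
            )

    @property
    def n(self) -> int:
        """Number of ranked genes (the study size N)."""
        return len(self.ranks)

    @property
    def genes(self) -> set[str]:
        return set(self.ranks)

    @classmethod
    def from_ranked(
        cls,
        study_id: str,
        raw_ranks: Mapping[str, float],
        *,
        reverse: bool = False,
        **meta,
    ) -> "Study":
        """Build a study from possibly tied or gapped raw ranks.

        Ties are resolved to dense unique ranks by average raw rank, then
        lexicographic gene_id.  ``reverse=True`` declares that the source
        counts the other way (largest number = strongest evidence).
        """
        items = sorted(
            raw_ranks.items(),
            key=lambda kv: (-kv[1] if reverse else kv[1], kv[0]),
        )
        ranks = {gene: i + 1 for i, (gene, _) in enumerate(items)}
        return cls(study_id=study_id, ranks=ranks, **meta)


@dataclass
class StudySet:
    """A named, non-empty collection of study identifiers."""

    set_id: str
    study_ids: list[str]

    def __post_init__(self) -> None:
        if not self.study_ids:
            raise KnowledgeBaseError(f"study set {self.set_id!r} is empty")
        if len(set(self.study_ids)) != len(self.study_ids):
            raise KnowledgeBaseError(
                f"study set {self.set_id!r} contains duplicate study ids"
            )


@dataclass(frozen=True)
class GORegulation:
    """One (gene, GO process, direction) regulation triple."""

    gene_id: str
    process_id: str
    direction: str
    process_name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in REGULATION_DIRECTIONS:
            raise KnowledgeBaseError(
                f"regulation ({self.gene_id}, {self.process_id}): direction must be "
                f"one of {REGULATION_DIRECTIONS}, got {self.direction!r}"
            )


@dataclass(frozen=True)
class DrugTarget:
    """One drug -> gene-target pair with the drug's mode of action on the target."""

    drug_id: str
    gene_id: str
    drug_name: str = ""
    action: str = "unknown"
    source_db: str = ""

    def __post_init__(self) -> None:
        if self.action not in DRUG_ACTIONS:
            raise KnowledgeBaseError(
                f"drug target ({self.drug_id}, {self.gene_id}): action must be one of "
                f"{DRUG_ACTIONS}, got {self.action!r}"
            )


@dataclass
class KnowledgeBase:
    """The assembled store: studies, study sets, regulations and drug targets."""

    studies: dict[str, Study] = field(default_factory=dict)
    study_sets: dict[str, StudySet] = field(default_factory=dict)
    regulations: list[GORegulation] = field(default_factory=list)
    drug_targets: list[DrugTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for ss in self.study_sets.values():
            for sid in ss.study_ids:
                if sid not in self.studies:
                    raise KnowledgeBaseError(
                        f"study set {ss.set_id!r} references unknown study {sid!r}"
                    )
        seen_reg = set()
        for reg in self.regulations:
            key = (reg.gene_id, reg.process_id, reg.direction)
            if key in seen_reg:
                raise KnowledgeBaseError(f"duplicate regulation triple {key}")
            seen_reg.add(key)
        seen_dt = set()
        for dt in self.drug_targets:
            key = (dt.drug_id, dt.gene_id)
            if key in seen_dt:
                raise KnowledgeBaseError(f"duplicate drug-target pair {key}")
            seen_dt.add(key)

    @property
    def gene_universe(self) -> set[str]:
        """All genes ranked in at least one study."""
        universe: set[str] = set()
        for study in self.studies.values():
            universe |= study.genes
        return universe

    def regulations_by_process(self) -> dict[str, list[GORegulation]]:
        out: dict[str, list[GORegulation]] = {}
        for reg in self.regulations:
            out.setdefault(reg.process_id, []).append(reg)
        return out

    def regulations_by_gene(self) -> dict[str, list[GORegulation]]:
        out: dict[str, list[GORegulation]] = {}
        for reg in self.regulations:
            out.setdefault(reg.gene_id, []).append(reg)
        return out

    def targets_by_drug(self) -> dict[str, list[DrugTarget]]:
        out: dict[str, list[DrugTarget]] = {}
        for dt in self.drug_targets:
            out.setdefault(dt.drug_id, []).append(dt)
        return out

    def process_names(self) -> dict[str, str]:
        names: dict[str, str] = {}
        for reg in self.regulations:
            if reg.process_name and reg.process_id not in names:
                names[reg.process_id] = reg.process_name
        return names


# ---------------------------------------------------------------------------
# study construction from per-gene statistics
# ---------------------------------------------------------------------------


def benjamini_yekutieli(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (FDR under arbitrary dependence).

    Thin wrapper over statsmodels' ``fdr_by`` so the whole package shares a
    single adjustment routine.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def build_study_from_stats(
    table: pd.DataFrame,
    study_id: str,
    *,
    q_threshold: float = 0.001,
    effect_column: str = "effect",
    p_column: str = "p_value",
    gene_column: str = "gene_id",
    **meta,
) -> Study:
    """Turn a per-gene statistics table into a ranked study.

    Mirrors the inclusion rule used for in-house differential-expression
    studies: p-values are adjusted for multiple testing with
    Benjamini–Yekutieli, genes with adjusted q <= ``q_threshold`` survive,
    and survivors are ranked by descending absolute effect size (rank 1 =
    largest).  Ties on \\|effect\\| are broken by ascending raw p-value, then
    lexicographic gene_id.

    Returns an empty-flagged :class:`Study` (with a warning) when no gene
    survives the threshold.
    """
    for col in (gene_column, p_column, effect_column):
        if col not in table.columns:
            raise KnowledgeBaseError(f"statistics table lacks column {col!r}")
    df = table[[gene_column, p_column, effect_column]].copy()
    df.columns = ["gene_id", "p_value", "effect"]
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise KnowledgeBaseError(f"duplicate genes in statistics table: {dupes}")
    p_numeric = pd.to_numeric(df["p_value"], errors="coerce")
    if p_numeric.isna().any():
        bad = df.loc[p_numeric.isna(), "gene_id"].tolist()
        raise KnowledgeBaseError(f"non-numeric p-values for genes: {bad}")
    df["p_value"] = p_numeric
    df["q_value"] = benjamini_yekutieli(df["p_value"].to_numpy())

    survivors = df[df["q_value"] <= q_threshold].copy()
    if survivors.empty:
        warnings.warn(
            f"study {study_id!r}: no gene passes BY q <= {q_threshold}; returning empty study",
            stacklevel=2,
        )
        return Study(study_id=study_id, ranks={}, empty=True, **meta)

    survivors["abs_effect"] = survivors["effect"].abs()
    survivors = survivors.sort_values(
        by=["abs_effect", "p_value", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    ranks = {gene: i + 1 for i, gene in enumerate(survivors["gene_id"])}
    return Study(study_id=study_id, ranks=ranks, **meta)


# ---------------------------------------------------------------------------
# OBO-derived regulation triples
# ---------------------------------------------------------------------------

_REG_PREFIXES = (("positive regulation of ", "positive"), ("negative regulation of ", "negative"))


def derive_regulations_from_obo(
    obo_path: str | os.PathLike,
    annotations: pd.DataFrame,
    *,
    gene_column: str = "gene_id",
    term_column: str = "term_id",
) -> tuple[list[GORegulation], dict]:
    """Derive direction-tagged regulation triples from GO term names.

    A gene annotated to a term named ``positive regulation of X`` yields the
    triple (gene, term-of-X, positive), symmetrically for negative
    regulation; the regulated term X is resolved by exact name match within
    the ontology.  Annotations to non-regulation terms yield nothing here —
    direct triples are supplied via TSV instead.

    Returns the triples and a report dict with counts of skipped
    annotations (``unresolved`` names the regulation terms whose regulated
    process is absent from the OBO).
    """
    import obonet

    graph = obonet.read_obo(os.fspath(obo_path))
    name_by_id = {tid: data.get("name", "") for tid, data in graph.nodes(data=True)}
    id_by_name = {name: tid for tid, name in name_by_id.items() if name}

    triples: list[GORegulation] = []
    seen: set[tuple[str, str, str]] = set()
    report = {"n_annotations": len(annotations), "n_non_regulation": 0, "unresolved": []}
    for _, row in annotations.iterrows():
        gene, term = str(row[gene_column]), str(row[term_column])
        name = name_by_id.get(term, "")
        matched = False
        for prefix, direction in _REG_PREFIXES:
            if name.startswith(prefix):
                matched = True
                target_name = name[len(prefix):]
                target_id = id_by_name.get(target_name)
                if target_id is None:
                    report["unresolved"].append(name)
                    break
                key = (gene, target_id, direction)
                if key not in seen:
                    seen.add(key)
                    triples.append(
                        GORegulation(
                            gene_id=gene,
                            process_id=target_id,
                            direction=direction,
                            process_name=target_name,
                        )
                    )
                break
        if not matched:
            report["n_non_regulation"] += 1
    return triples, report


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise KnowledgeBaseError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"{path}: missing required columns {missing}")
    return df


def read_studies(path: str | os.PathLike) -> dict[str, Study]:
    """Read studies from a TSV with columns study_id, gene_id, rank.

    Optional per-study metadata columns (source, data_type, direction_tag,
    reverse) are taken from the first row of each study.  Raw ranks may be
    tied or gapped; they are densified per :meth:`Study.from_ranked`.
    """
    df = _read_tsv(path, ["study_id", "gene_id", "rank"])
    dup = df.duplicated(subset=["study_id", "gene_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise KnowledgeBaseError(
            f"{path}: gene {row['gene_id']!r} listed twice in study {row['study_id']!r}"
        )
    studies: dict[str, Study] = {}
    for study_id, group in df.groupby("study_id", sort=True):
        try:
            raw = {g: float(r) for g, r in zip(group["gene_id"], group["rank"])}
        except ValueError as exc:
            raise KnowledgeBaseError(f"{path}: non-numeric rank in study {study_id!r}") from exc
        meta = {}
        first = group.iloc[0]
        for col in ("source", "data_type", "direction_tag"):
            if col in group.columns and pd.notna(first[col]):
                meta[col] = first[col]
        reverse = False
        if "reverse" in group.columns and pd.notna(first["reverse"]):
            reverse = str(first["reverse"]).lower() in ("1", "true", "yes")
        studies[str(study_id)] = Study.from_ranked(str(study_id), raw, reverse=reverse, **meta)
    return studies


def read_study_sets(path: str | os.PathLike) -> dict[str, StudySet]:
    df = _read_tsv(path, ["set_id", "study_id"])
    sets = {}
    for set_id, group in df.groupby("set_id", sort=True):
        sets[str(set_id)] = StudySet(str(set_id), [str(s) for s in group["study_id"]])
    return sets


def read_regulations(path: str | os.PathLike) -> list[GORegulation]:
    df = _read_tsv(path, ["gene_id", "process_id", "direction"])
    name_col = "process_name" if "process_name" in df.columns else None
    triples = []
    for _, row in df.iterrows():
        triples.append(
            GORegulation(
                gene_id=str(row["gene_id"]),
                process_id=str(row["process_id"]),
                direction=str(row["direction"]),
                process_name=str(row[name_col]) if name_col and pd.notna(row[name_col]) else "",
            )
        )
    return triples


def read_drug_targets(path: str | os.PathLike) -> list[DrugTarget]:
    df = _read_tsv(path, ["drug_id", "gene_id"])
    targets = []
    for _, row in df.iterrows():
        action = row.get("action")
        targets.append(
            DrugTarget(
                drug_id=str(row["drug_id"]),
                gene_id=str(row["gene_id"]),
                drug_name=str(row["drug_name"]) if pd.notna(row.get("drug_name")) else "",
                action=str(action) if pd.notna(action) and str(action) else "unknown",
                source_db=str(row["source_db"]) if pd.notna(row.get("source_db")) else "",
            )
        )
    return targets


def load_knowledge_base(
    studies: str | os.PathLike | Iterable[str | os.PathLike],
    study_sets: str | os.PathLike | None = None,
    regulations: str | os.PathLike | None = None,
    drug_targets: str | os.PathLike | None = None,
) -> KnowledgeBase:
    """Load and validate a knowledge-base from its TSV tables.

    ``studies`` may be a single TSV, a directory of ``*.tsv`` study files,
    or an iterable of paths.  Any cross-reference that does not resolve
    (a study set naming an unknown study) is a fatal error.
    """
    if isinstance(studies, (str, os.PathLike)):
        p = Path(studies)
        if p.is_dir():
            study_paths: list[Path] = sorted(p.glob("*.tsv"))
            if not study_paths:
                raise KnowledgeBaseError(f"no study TSVs found in directory {p}")
        else:
            study_paths = [p]
    else:
        study_paths = [Path(s) for s in studies]

    all_studies: dict[str, Study] = {}
    for path in study_paths:
        for sid, study in read_studies(path).items():
            if sid in all_studies:
                raise KnowledgeBaseError(f"study {sid!r} defined in more than one file")
            all_studies[sid] = study

    kb = KnowledgeBase(
        studies=all_studies,
        study_sets=read_study_sets(study_sets) if study_sets else {},
        regulations=read_regulations(regulations) if regulations else [],
        drug_targets=read_drug_targets(drug_targets) if drug_targets else [],
    )
    return kb


def write_knowledge_base(kb: KnowledgeBase, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write a knowledge-base back to its four TSV tables; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for study in kb.studies.values():
        for gene, rank in sorted(study.ranks.items(), key=lambda kv: kv[1]):
            rows.append(
                {
                    "study_id": study.study_id,
                    "gene_id": gene,
                    "rank": rank,
                    "source": study.source,
                    "data_type": study.data_type,
                    "direction_tag": study.direction_tag,
                }
            )
    paths["studies"] = out / "studies.tsv"
    pd.DataFrame(
        rows, columns=["study_id", "gene_id", "rank", "source", "data_type", "direction_tag"]
    ).to_csv(paths["studies"], sep="\t", index=False)

    rows = [
        {"set_id": ss.set_id, "study_id": sid}
        for ss in kb.study_sets.values()
        for sid in ss.study_ids
    ]
    paths["study_sets"] = out / "study_sets.tsv"
    pd.DataFrame(rows, columns=["set_id", "study_id"]).to_csv(
        paths["study_sets"], sep="\t", index=False
    )

    rows = [
        {
            "gene_id": r.gene_id,
            "process_id": r.process_id,
            "process_name": r.process_name,
            "direction": r.direction,
        }
        for r in kb.regulations
    ]
    paths["regulations"] = out / "regulations.tsv"
    pd.DataFrame(rows, columns=["gene_id", "process_id", "process_name", "direction"]).to_csv(
        paths["regulations"], sep="\t", index=False
    )

    rows = [
        {
            "drug_id": t.drug_id,
            "drug_name": t.drug_name,
            "gene_id": t.gene_id,
            "action": t.action,
            "source_db": t.source_db,
        }
        for t in kb.drug_targets
    ]
    paths["drug_targets"] = out / "drug_targets.tsv"
    pd.DataFrame(rows, columns=["drug_id", "drug_name", "gene_id", "action", "source_db"]).to_csv(
        paths["drug_targets"], sep="\t", index=False
    )
    return paths
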