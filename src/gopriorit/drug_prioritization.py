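"""Harmonic-mean recalibration of gene scores and drug priority ranking.

Recalibration replaces a gene's K-rank with the harmonic mean H of the
permutation p-values of the GO processes the gene regulates.  Processes the
gene is annotated to as both a positive and a negative regulator are
ambiguous and excluded.  The harmonic mean is bounded by the smallest and
largest constituent p-value and is independent of how many processes enter
when their p-values are equal, so genes wired into large, highly connected
processes gain no advantage from connectivity alone.  The working score is
-log10(H): larger = more cancer-essential.

Drug priority balances three signals: the number of known targets of the
drug, the recalibrated relevance of each target, and the target's measured
activity in the query cohort.  For drug d with required target status
determined by its mode of action (inhibitor -> active, activator ->
inactive, unknown -> inhibitor semantics),

    D_d = sum over altered targets g of score_g * f_g  /  n_targets(d)

where f_g is the fraction of samples in which g holds the required status,
and an "altered target" is a target with a recalibrated score whose
required status occurs in at least one sample.  Dividing by the total
target count penalizes diffuse polypharmacology.  Drugs with no altered
target are omitted.  ``drug_score_mode="per_altered_targets"`` divides by
the altered-target count instead.

A drug's *sensitive samples* are the union, over its altered targets, of
the samples in which the target holds the required status.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity_matrix import ActivityMatrix
from .knowledge_base import GORegulation, KnowledgeBase

__all__ = [
    "harmonic_mean",
    "recalibrate_gene",
    "recalibrate_all",
    "prioritize_drugs",
    "sensitive_samples",
    "render_stratification",
]

DRUG_SCORE_MODES = ("per_total_targets", "per_altered_targets")

_REQUIRED_STATUS = {"inhibitor": "active", "activator": "inactive", "unknown": "active"}


def harmonic_mean(p_values: Sequence[float]) -> float:
    """Harmonic mean H = n / sum(1/p) of strictly positive p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("harmonic mean of an empty collection")
    if np.any(p <= 0):
        raise ValueError("harmonic mean requires strictly positive p-values")
    # all-equal vectors return the common value exactly, independent of count
    if np.all(p == p[0]):
        return float(p[0])
    return p.size / float(np.sum(1.0 / p))


def _gene_processes(
    gene: str, regulations: Sequence[GORegulation]
) -> tuple[set[str], set[str]]:
    """(unambiguous, ambiguous) process ids the gene regulates."""
    directions: dict[str, set[str]] = {}
    for reg in regulations:
        if reg.gene_id == gene:
            directions.setdefault(reg.process_id, set()).add(reg.direction)
    ambiguous = {p for p, d in directions.items() if len(d) > 1}
    return set(directions) - ambiguous, ambiguous


def recalibrate_gene(
    gene: str,
    regulations: Sequence[GORegulation],
    go_results: pd.DataFrame,
) -> dict | None:
    """Recalibrated rank of one gene, or None if no usable process.

    Uses the processes the gene regulates in exactly one direction and that
    carry a p-value in ``go_results``; returns a dict with keys ``gene_id,
    harmonic_mean_p, score, n_processes_used, n_processes_ambiguous``.
    """
    unambiguous, ambiguous = _gene_processes(gene, regulations)
    pmap = dict(zip(go_results["process_id"], go_results["p_value"]))
    usable = sorted(p for p in unambiguous if p in pmap)
    if not usable:
        return None
    h = harmonic_mean([pmap[p] for p in usable])
    return {
        "gene_id": gene,
        "harmonic_mean_p": h,
        "score": -math.log10(h),
        "n_processes_used": len(usable),
        "n_processes_ambiguous": len(ambiguous),
    }


def recalibrate_all(
    kb: KnowledgeBase,
    go_results: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Recalibrated ranks for every regulating gene (or the given subset).

    Genes with no unambiguous scored process are omitted.  Returns a
    DataFrame sorted by descending score then gene_id.
    """
    by_gene = kb.regulations_by_gene()
    candidates = sorted(by_gene) if genes is None else sorted(set(genes) & set(by_gene))
    rows = []
    for gene in candidates:
        rec = recalibrate_gene(gene, by_gene[gene], go_results)
        if rec is not None:
            rows.append(rec)
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "harmonic_mean_p", "score", "n_processes_used", "n_processes_ambiguous"],
    )
    return df.sort_values(
        by=["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _required_status(action: str, mode_map: Mapping[str, str] | None) -> str:
    table = dict(_REQUIRED_STATUS)
    if mode_map:
        table.update(mode_map)
    return table.get(action, "active")


def _eligible_targets(
    drug_id: str,
    kb: KnowledgeBase,
    am: ActivityMatrix,
    recal_scores: Mapping[str, float] | None,
    mode_map: Mapping[str, str] | None,
) -> list[dict]:
    """Altered (and, when recal given, scored) targets with their f fractions."""
    targets = kb.targets_by_drug().get(drug_id, [])
    n_samples = len(am.samples)
    out = []
    for dt in sorted(targets, key=lambda t: t.gene_id):
        if recal_scores is not None and dt.gene_id not in recal_scores:
            continue
        if dt.gene_id not in am.statuses.index:
            continue
        required = _required_status(dt.action, mode_map)
        hit = am.stratify_by_gene(dt.gene_id, required)
        if not hit:
            continue
        out.append(
            {
                "gene_id": dt.gene_id,
                "required_status": required,
                "samples": hit,
                "fraction": len(hit) / n_samples,
                "score": recal_scores[dt.gene_id] if recal_scores is not None else float("nan"),
            }
        )
    return out


def sensitive_samples(
    drug_id: str,
    kb: KnowledgeBase,
    am: ActivityMatrix,
    mode_map: Mapping[str, str] | None = None,
    recal: pd.DataFrame | None = None,
) -> set[str]:
    """Union over the drug's altered targets of the samples holding the required status.

    When ``recal`` is given, only targets with a recalibrated score count
    (the same eligibility rule :func:`prioritize_drugs` uses).
    """
    if drug_id not in kb.targets_by_drug():
        raise KeyError(f"unknown drug {drug_id!r}")
    scores = dict(zip(recal["gene_id"], recal["score"])) if recal is not None else None
    eligible = _eligible_targets(drug_id, kb, am, scores, mode_map)
    out: set[str] = set()
    for entry in eligible:
        out |= entry["samples"]
    return out


def prioritize_drugs(
    kb: KnowledgeBase,
    recal: pd.DataFrame,
    am: ActivityMatrix,
    mode_map: Mapping[str, str] | None = None,
    *,
    drug_score_mode: str = "per_total_targets",
) -> pd.DataFrame:
    """Priority-ranked drugs with scores and sensitive-sample sets.

    Returns a DataFrame sorted by descending score, ties broken by more
    altered targets then drug_id, with columns ``drug_id, drug_name, score,
    n_targets, n_altered_targets, n_sensitive_samples, sensitive_samples
    (semicolon-joined), target_detail (gene:score:fraction triplets)``.
    Drugs with no altered target never appear.
    """
    if drug_score_mode not in DRUG_SCORE_MODES:
        raise ValueError(f"drug_score_mode must be one of {DRUG_SCORE_MODES}")
    if not am.samples:
        import warnings

        warnings.warn("empty activity matrix; returning empty drug ranking", stacklevel=2)
    scores = dict(zip(recal["gene_id"], recal["score"]))
    by_drug = kb.targets_by_drug()
    rows = []
    for drug_id in sorted(by_drug):
        targets = by_drug[drug_id]
        eligible = _eligible_targets(drug_id, kb, am, scores, mode_map)
        if not eligible:
            continue
        denom = len(targets) if drug_score_mode == "per_total_targets" else len(eligible)
        d_score = sum(e["score"] * e["fraction"] for e in eligible) / denom
        sens: set[str] = set()
        for e in eligible:
            sens |= e["samples"]
        rows.append(
            {
                "drug_id": drug_id,
                "drug_name": next((t.drug_name for t in targets if t.drug_name), ""),
                "score": d_score,
                "n_targets": len(targets),
                "n_altered_targets": len(eligible),
                "n_sensitive_samples": len(sens),
                "sensitive_samples": ";".join(sorted(sens)),
                "target_detail": ";".join(
                    f"{e['gene_id']}:{e['score']:.6g}:{e['fraction']:.6g}" for e in eligible
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "drug_id",
            "drug_name",
            "score",
            "n_targets",
            "n_altered_targets",
            "n_sensitive_samples",
            "sensitive_samples",
            "target_detail",
        ],
    )
    return df.sort_values(
        by=["score", "n_altered_targets", "drug_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def render_stratification(
    am: ActivityMatrix,
    drugs: Sequence[str],
    extra_genes: Sequence[str] = (),
    annotations: pd.DataFrame | None = None,
    *,
    kb: KnowledgeBase | None = None,
    recal: pd.DataFrame | None = None,
    mode_map: Mapping[str, str] | None = None,
    drug_sensitive: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Categorical stratification table: drug-sensitivity rows, gene-status rows, annotations.

    Samples (columns) are ordered by sensitivity to the first drug, then by
    annotation values, then by sample id, so repeated calls are stable.
    Per-drug sensitive sets are either supplied via ``drug_sensitive`` or
    computed from ``kb``/``recal``.  Unknown annotation columns (samples
    missing from the annotation table) raise.
    """
    samples = am.samples
    sens: dict[str, set[str]] = {}
    for drug in drugs:
        if drug_sensitive is not None and drug in drug_sensitive:
            sens[drug] = set(drug_sensitive[drug])
        elif kb is not None:
            sens[drug] = sensitive_samples(drug, kb, am, mode_map, recal)
        else:
            raise ValueError(f"no sensitivity information for drug {drug!r}")

    for gene in extra_genes:
        if gene not in am.statuses.index:
            raise KeyError(f"gene {gene!r} not in activity matrix")

    if annotations is not None:
        missing = set(samples) - set(annotations.index)
        if missing:
            raise KeyError(f"annotation table lacks samples {sorted(missing)}")

    rows = {}
    for drug in drugs:
        rows[f"drug:{drug}"] = [
            "sensitive" if s in sens[drug] else "insensitive" for s in samples
        ]
    for gene in extra_genes:
        rows[f"gene:{gene}"] = list(am.statuses.loc[gene, samples])
    if annotations is not None:
        for col in annotations.columns:
            rows[f"annotation:{col}"] = [str(annotations.loc[s, col]) for s in samples]

    table = pd.DataFrame(rows, index=samples).T

    sort_keys = []
    if drugs:
        first = drugs[0]
        sort_keys.append([0 if s in sens[first] else 1 for s in samples])
    if annotations is not None:
        for col in annotations.columns:
            sort_keys.append([str(annotations.loc[s, col]) for s in samples])
    sort_keys.append(list(samples))
    order = sorted(range(len(samples)), key=lambda i: tuple(k[i] for k in sort_keys))
    return table.iloc[:, order]


def plot_stratification(table: pd.DataFrame, path: str) -> None:
    """Write the stratification table as a categorical heat map image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    categories = sorted({v for v in table.to_numpy(dtype=object).ravel()})
    code = {c: i for i, c in enumerate(categories)}
    mat = np.vectorize(code.get)(table.to_numpy(dtype=object))
    fig, ax = plt.subplots(
        figsize=(max(4, table.shape[1] * 0.12), max(2, table.shape[0] * 0.35))
    )
    im = ax.imshow(mat, aspect="auto", cmap="tab20", interpolation="nearest")
    ax.set_yticks(range(table.shape[0]))
    ax.set_yticklabels(table.index, fontsize=7)
    ax.set_xticks([])
    cbar = fig.colorbar(im, ax=ax, ticks=range(len(categories)))
    cbar.ax.set_yticklabels(categories, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
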