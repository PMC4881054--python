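"""Gene-by-sample activity matrix fused from expression, copy-number and mutation.

The activity matrix assigns every (gene, sample) cell one of three statuses
— ``active``, ``inactive``, ``unchanged`` — by applying evidence layers in a
fixed precedence order:

1. mutation:    activating -> active, inactivating -> inactive
2. copy-number: amplified  -> active, deleted      -> inactive
3. expression:  up         -> active, down         -> inactive
4. otherwise unchanged

Point mutations are the most direct evidence of protein-level change, so
they win.  Copy-number, when altered, overrides expression in both the
conflict case (expression down but the locus amplified -> active) and the
silent-expression case; genomic alterations are more stable across cohorts
than expression shifts, which makes them the preferable biomarker evidence.
A layer with a missing value simply does not fire — it never forces a cell
to unchanged.  Each cell's ``provenance`` records which layer decided it.

The full precedence table is reproduced in ``docs/methods.md`` so users can
diff it against their own conventions.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EXPRESSION_STATES",
    "CNA_STATES",
    "MUTATION_STATES",
    "ACTIVITY_STATES",
    "QueryDataset",
    "ActivityMatrix",
    "discretize_expression",
    "build_activity_matrix",
    "cell_status",
]

EXPRESSION_STATES = ("up", "down", "unchanged", "missing")
CNA_STATES = ("amplified", "deleted", "neutral", "missing")
MUTATION_STATES = ("activating", "inactivating", "none", "missing")
ACTIVITY_STATES = ("active", "inactive", "unchanged")


@dataclass
class QueryDataset:
    """Discretized molecular data for the cohort in which drugs are prioritized.

    Each layer is a gene-by-sample DataFrame of status strings; all layers
    must share the same sample columns.  A gene may be absent from a layer
    (treated as missing there).
    """

    expression: pd.DataFrame
    cna: pd.DataFrame
    mutation: pd.DataFrame

    def __post_init__(self) -> None:
        layers = {"expression": self.expression, "cna": self.cna, "mutation": self.mutation}
        sample_lists = {n: list(df.columns) for n, df in layers.items() if df.shape[1] > 0}
        if sample_lists:
            ref_name, ref = next(iter(sample_lists.items()))
            for name, cols in sample_lists.items():
                if cols != ref:
                    raise ValueError(
                        f"sample sets differ between {ref_name} and {name} layers: "
                        f"{sorted(set(cols) ^ set(ref))}"
                    )
        allowed = {
            "expression": set(EXPRESSION_STATES),
            "cna": set(CNA_STATES),
            "mutation": set(MUTATION_STATES),
        }
        for name, df in layers.items():
            if df.size == 0:
                continue
            bad = set(np.unique(df.to_numpy(dtype=object))) - allowed[name]
            if bad:
                raise ValueError(f"{name} layer contains invalid states {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        for df in (self.expression, self.cna, self.mutation):
            if df.shape[1]:
                return list(df.columns)
        return []

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for df in (self.expression, self.cna, self.mutation):
            out |= set(df.index)
        return sorted(out)

    @classmethod
    def from_tsv(
        cls,
        expression: str | os.PathLike | None = None,
        cna: str | os.PathLike | None = None,
        mutation: str | os.PathLike | None = None,
        *,
        discretize: str | None = None,
        **discretize_kwargs,
    ) -> "QueryDataset":
        """Read layers from wide TSVs (genes in rows, samples in columns).

        ``discretize`` (``"zscore"`` or ``"quantile"``) treats the expression
        TSV as continuous and discretizes it.  A mutation TSV with columns
        ``gene_id, sample_id, effect`` is accepted in long form and pivoted.
        """
        def read(path):
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
            df.index.name = None
            return df

        samples: list[str] | None = None
        if expression is not None:
            if discretize:
                cont = pd.read_csv(expression, sep="\t", index_col=0).astype(float)
                expr = discretize_expression(cont, method=discretize, **discretize_kwargs)
            else:
                expr = read(expression)
            samples = list(expr.columns)
        else:
            expr = pd.DataFrame()

        cna_df = read(cna) if cna is not None else pd.DataFrame()
        if samples is None and cna_df.shape[1]:
            samples = list(cna_df.columns)

        if mutation is not None:
            raw = pd.read_csv(mutation, sep="\t", dtype=str)
            if {"gene_id", "sample_id", "effect"}.issubset(raw.columns):
                mut = (
                    raw.pivot_table(
                        index="gene_id", columns="sample_id", values="effect", aggfunc="first"
                    )
                    .reindex(columns=samples)
                    .fillna("none")
                )
                mut.columns.name = None
                mut.index.name = None
            else:
                mut = pd.read_csv(mutation, sep="\t", index_col=0, dtype=str)
        else:
            mut = pd.DataFrame()

        def empty_like():
            return pd.DataFrame(index=pd.Index([], dtype=object), columns=samples or [])

        return cls(
            expression=expr if expr.size else empty_like(),
            cna=cna_df if cna_df.size else empty_like(),
            mutation=mut if mut.size else empty_like(),
        )


def discretize_expression(
    values: pd.DataFrame,
    method: str = "zscore",
    *,
    z_threshold: float = 2.0,
    q: float = 0.1,
) -> pd.DataFrame:
    """Discretize a continuous gene-by-sample matrix into up/down/unchanged.

    ``zscore``: per-gene robust z = (x - median) / (MAD * 1.4826); cells with
    z >= +z_threshold are up, z <= -z_threshold are down.  A gene whose MAD
    is zero but whose values are not constant (more than half the samples
    tied at the median) falls back to the ordinary moment z-score
    (x - mean)/std with population std; a truly constant gene is left
    entirely unchanged (with a warning).

    ``quantile``: per gene, the floor(q * n) highest cells are up and the
    floor(q * n) lowest are down (rank-based, so exactly that many on
    distinct values).
    """
    if method not in ("zscore", "quantile"):
        raise ValueError(f"unknown discretization method {method!r}")
    x = values.to_numpy(dtype=float)
    out = np.full(x.shape, "unchanged", dtype=object)
    if method == "zscore":
        med = np.median(x, axis=1, keepdims=True)
        mad = np.median(np.abs(x - med), axis=1, keepdims=True) * 1.4826
        constant = np.ptp(x, axis=1, keepdims=True) == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene(s) left unchanged", stacklevel=2
            )
        # degenerate spread (zero MAD, non-constant row): moment z-score fallback
        mean = x.mean(axis=1, keepdims=True)
        std = x.std(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(
                mad > 0,
                (x - med) / mad,
                np.where(~constant & (std > 0), (x - mean) / np.where(std > 0, std, 1.0), 0.0),
            )
        out[z >= z_threshold] = "up"
        out[z <= -z_threshold] = "down"
    else:
        n = x.shape[1]
        k = int(np.floor(q * n))
        if k > 0:
            order = np.argsort(x, axis=1, kind="stable")
            rows = np.arange(x.shape[0])[:, None]
            out[rows, order[:, :k]] = "down"
            out[rows, order[:, n - k:]] = "up"
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def cell_status(expression: str, cna: str, mutation: str) -> tuple[str, str]:
    """Status and provenance of a single cell under the precedence rules.

    Scalar reference form of the rule table; :func:`build_activity_matrix`
    is the vectorized equivalent.
    """
    if mutation == "activating":
        return "active", "mutation"
    if mutation == "inactivating":
        return "inactive", "mutation"
    if cna == "amplified":
        return "active", "cna"
    if cna == "deleted":
        return "inactive", "cna"
    if expression == "up":
        return "active", "expression"
    if expression == "down":
        return "inactive", "expression"
    return "unchanged", "default"


@dataclass
class ActivityMatrix:
    """Ternary gene-by-sample status matrix plus per-cell provenance."""

    statuses: pd.DataFrame
    provenance: pd.DataFrame

    def stratify_by_gene(self, gene: str, status: str) -> set[str]:
        """Samples whose status for ``gene`` equals ``status``."""
        if gene not in self.statuses.index:
            raise KeyError(f"gene {gene!r} not in activity matrix")
        if status not in ACTIVITY_STATES:
            raise ValueError(f"status must be one of {ACTIVITY_STATES}")
        row = self.statuses.loc[gene]
        return set(row.index[row == status])

    @property
    def samples(self) -> list[str]:
        return list(self.statuses.columns)

    def to_tsv(self, status_path: str | os.PathLike, provenance_path: str | os.PathLike | None = None) -> None:
        self.statuses.to_csv(status_path, sep="\t", index_label="gene_id")
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, status_path: str | os.PathLike, provenance_path: str | os.PathLike | None = None) -> "ActivityMatrix":
        statuses = pd.read_csv(status_path, sep="\t", index_col=0, dtype=str)
        statuses.index.name = None
        if provenance_path is not None and Path(provenance_path).exists():
            prov = pd.read_csv(provenance_path, sep="\t", index_col=0, dtype=str)
            prov.index.name = None
        else:
            prov = pd.DataFrame("default", index=statuses.index, columns=statuses.columns)
        return cls(statuses=statuses, provenance=prov)


def build_activity_matrix(q: QueryDataset) -> ActivityMatrix:
    """Fuse the three layers into one activity matrix via the precedence rules."""
    samples = q.samples
    genes = q.genes

    def layer(df: pd.DataFrame) -> np.ndarray:
        return (
            df.reindex(index=genes, columns=samples)
            .fillna("missing")
            .to_numpy(dtype=object)
        )

    expr, cna, mut = layer(q.expression), layer(q.cna), layer(q.mutation)

    conditions = [
        mut == "activating",
        mut == "inactivating",
        cna == "amplified",
        cna == "deleted",
        expr == "up",
        expr == "down",
    ]
    status_choices = ["active", "inactive", "active", "inactive", "active", "inactive"]
    prov_choices = ["mutation", "mutation", "cna", "cna", "expression", "expression"]

    statuses = np.select(conditions, status_choices, default="unchanged")
    provenance = np.select(conditions, prov_choices, default="default")
    return ActivityMatrix(
        statuses=pd.DataFrame(statuses, index=genes, columns=samples),
        provenance=pd.DataFrame(provenance, index=genes, columns=samples),
    )
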