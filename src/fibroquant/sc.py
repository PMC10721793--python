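"""Single-cell RNA-seq computations: QC filtering, log-normalization,
signature scoring, and per-phase relative-abundance tables.

The clustering / embedding / label-transfer machinery that produced the
cell-type labels is out of scope here; labels arrive as inputs. What this
module owns is the arithmetic applied to a gene-by-cell count matrix:

* QC: keep cells with 200-5,000 detected features (inclusive) and a
  mitochondrial count fraction <= 5% (cells strictly above 5% are treated
  as apoptotic and removed);
* normalization: counts / cell total x 10,000, then log1p (natural log);
* signature scores: per-cell arithmetic mean of the log-normalized values
  of a marker gene set (ILC1/ILC2/ILC3 signatures);
* abundance: within-compartment cell-type frequencies per disease phase and
  their log2 fold change against the intact phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "QCParams",
    "NormMatrix",
    "SignatureScore",
    "qc_filter",
    "log_normalize",
    "signature_score",
    "relative_abundance",
]

DEFAULT_MITO_PREFIX = "mt-"


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer counts with a mito-gene flag."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray
    mito_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells array")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.mito_genes = frozenset(self.mito_genes)
        unknown = self.mito_genes - set(self.genes)
        if unknown:
            raise ValueError(f"mito_genes not in gene list: {sorted(unknown)[:5]}")

    @classmethod
    def with_mito_prefix(cls, genes, cells, counts, prefix: str = DEFAULT_MITO_PREFIX) -> "CountMatrix":
        mito = frozenset(g for g in genes if g.lower().startswith(prefix.lower()))
        return cls(list(genes), list(cells), counts, mito)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def n_features(self) -> np.ndarray:
        """Detected (count > 0) features per cell."""
        return (self.counts > 0).sum(axis=0)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def mito_fraction(self) -> np.ndarray:
        """Per-cell mitochondrial count fraction; NaN for zero-total cells."""
        totals = self.totals().astype(np.float64)
        mito_rows = [i for i, g in enumerate(self.genes) if g in self.mito_genes]
        mito_sum = self.counts[mito_rows].sum(axis=0) if mito_rows else np.zeros(self.n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, mito_sum / totals, np.nan)

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.genes,
            [self.cells[i] for i in keep],
            self.counts[:, keep],
            self.mito_genes,
        )


@dataclass
class QCParams:
    """Cell-level QC bounds. Feature bounds are inclusive; the mito cutoff
    is strict (exactly 5% is retained, above 5% removed)."""

    min_features: int = 200
    max_features: int = 5000
    max_mito_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_features > self.max_features:
            raise ValueError("min_features must be <= max_features")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class NormMatrix:
    """log1p(count / cell_total x scale) expression values (natural log)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    scale: float = 10_000.0


@dataclass
class SignatureScore:
    """Per-cell mean log-normalized expression over a gene set."""

    scores: pd.Series
    gene_set: list[str]
    missing_genes: list[str]


def qc_filter(matrix: CountMatrix, params: QCParams | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the feature-count and mitochondrial-fraction filter.

    Returns the filtered matrix and a report listing every removed cell and
    the reasons (``zero_total``, ``low_features``, ``high_features``,
    ``high_mito``), plus the measured values.
    """
    if params is None:
        params = QCParams()
    nfeat = matrix.n_features()
    totals = matrix.totals()
    mito = matrix.mito_fraction()
    rows = []
    keep = np.ones(matrix.n_cells, dtype=bool)
    for i, cell in enumerate(matrix.cells):
        reasons = []
        if totals[i] == 0:
            reasons.append("zero_total")
        else:
            if nfeat[i] < params.min_features:
                reasons.append("low_features")
            if nfeat[i] > params.max_features:
                reasons.append("high_features")
            if mito[i] > params.max_mito_fraction:
                reasons.append("high_mito")
        if reasons:
            keep[i] = False
            rows.append(
                {
                    "cell": cell,
                    "n_features": int(nfeat[i]),
                    "total_counts": int(totals[i]),
                    "mito_fraction": float(mito[i]) if totals[i] else float("nan"),
                    "reason": ";".join(reasons),
                }
            )
    report = pd.DataFrame(rows, columns=["cell", "n_features", "total_counts", "mito_fraction", "reason"])
    return matrix.subset_cells(keep), report


def log_normalize(matrix: CountMatrix, scale: float = 10_000.0) -> NormMatrix:
    """value(g, c) = log1p(count(g, c) / total(c) * scale)."""
    totals = matrix.totals().astype(np.float64)
    if (totals == 0).any():
        bad = [matrix.cells[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(
            f"cells with zero total counts (e.g. {bad}); run qc_filter before log_normalize"
        )
    values = np.log1p(matrix.counts / totals[None, :] * scale)
    return NormMatrix(matrix.genes, matrix.cells, values, scale)


def signature_score(norm: NormMatrix, gene_set) -> SignatureScore:
    """Arithmetic mean of log-normalized values over the genes of a set
    that are present in the matrix; absent genes are reported, an entirely
    absent set is an error."""
    gene_set = list(gene_set)
    index = {g: i for i, g in enumerate(norm.genes)}
    present = [g for g in gene_set if g in index]
    missing = [g for g in gene_set if g not in index]
    if not present:
        raise ValueError(f"none of the requested signature genes are in the matrix: {gene_set}")
    rows = [index[g] for g in present]
    scores = norm.values[rows].mean(axis=0)
    return SignatureScore(
        scores=pd.Series(scores, index=pd.Index(norm.cells, name="cell"), name="score"),
        gene_set=present,
        missing_genes=missing,
    )


def relative_abundance(
    cell_labels,
    phase_labels,
    compartment_labels=None,
    reference_phase: str = "intact",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Within-compartment cell-type frequencies per phase and log2FC vs the
    reference (intact) phase.

    freq(type, phase) = n(type, phase, compartment) / n(phase, compartment);
    log2FC(type, phase) = log2(freq(type, phase) / freq(type, reference)).
    A type absent from the reference phase has undefined log2FC and is
    emitted as NaN unless ``pseudocount`` > 0, in which case the pseudocount
    is added to every (type, phase) cell count before forming frequencies.
    """
    cell_labels = pd.Series(list(cell_labels), name="cell_type")
    phase_labels = pd.Series(list(phase_labels), name="phase")
    if len(cell_labels) != len(phase_labels):
        raise ValueError("cell_labels and phase_labels must have equal length")
    if compartment_labels is None:
        compartment_labels = pd.Series(["all"] * len(cell_labels), name="compartment")
    else:
        compartment_labels = pd.Series(list(compartment_labels), name="compartment")
        if len(compartment_labels) != len(cell_labels):
            raise ValueError("compartment_labels must match cell_labels in length")
    if reference_phase not in set(phase_labels):
        raise ValueError(f"reference phase {reference_phase!r} absent from phase_labels")

    df = pd.DataFrame(
        {"cell_type": cell_labels, "phase": phase_labels, "compartment": compartment_labels}
    )
    out_rows = []
    for comp, comp_df in df.groupby("compartment", sort=True):
        types = sorted(comp_df["cell_type"].unique())
        phases = sorted(comp_df["phase"].unique())
        counts = (
            comp_df.groupby(["phase", "cell_type"]).size().unstack(fill_value=0).reindex(columns=types, fill_value=0)
        )
        for phase in phases:
            if phase not in counts.index:
                raise ValueError(f"compartment {comp!r} empty in phase {phase!r}")
        counts = counts.astype(float) + pseudocount
        freqs = counts.div(counts.sum(axis=1), axis=0)
        ref = freqs.loc[reference_phase]
        for phase in phases:
            for t in types:
                f = freqs.loc[phase, t]
                r = ref[t]
                with np.errstate(divide="ignore", invalid="ignore"):
                    l2fc = np.log2(f / r) if r > 0 else np.nan
                out_rows.append(
                    {
                        "compartment": comp,
                        "cell_type": t,
                        "phase": phase,
                        "n_cells": int(round(counts.loc[phase, t] - pseudocount)),
                        "frequency": f,
                        "log2fc_vs_reference": float(l2fc) if np.isfinite(l2fc) or np.isnan(l2fc) else l2fc,
                    }
                )
    return pd.DataFrame(out_rows)
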