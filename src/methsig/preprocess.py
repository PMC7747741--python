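"""Probe filtering, per-probe min-max normalization, and probe-to-gene
aggregation.

The stage order is fixed: id-prefix filter -> degenerate filter ->
min-max normalization -> gene aggregation.  SNP probes ("rs" prefix) and
non-CpG probes ("ch"/"ch." prefix) are dropped first; probes that are zero
in every sample or missing in any sample are dropped next; each surviving
probe is then rescaled to span [0, 1]; finally every annotated gene
receives the arithmetic mean of its mapped probes, per sample.  A probe
annotated to several genes contributes to each of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .methio import AnnotationMap, BetaMatrix, GROUP_LABELS, _first_duplicate

DEFAULT_PREFIX_BLACKLIST = ("rs", "ch")


@dataclass
class GeneMatrix:
    """Gene-by-sample methylation vectors (no missing values).

    Rows are official gene symbols, each the mean of >= 1 retained probe;
    values are unitless and lie in [0, 1] after normalization.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    groups: dict | None = None

    def __post_init__(self):
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if np.isnan(self.values).any():
            raise ValidationError("gene matrix must not contain missing values")
        if self.groups is not None:
            missing = [s for s in self.sample_ids if s not in self.groups]
            if missing:
                raise ValidationError(f"sample {missing[0]!r} has no group label")
            bad = set(self.groups.values()) - set(GROUP_LABELS)
            if bad:
                raise ValidationError(f"group labels must be in {GROUP_LABELS}")
            self.groups = {s: self.groups[s] for s in self.sample_ids}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_genes(self, keep) -> "GeneMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        ids = [self.gene_ids[i] for i in idx]
        return GeneMatrix(ids, self.sample_ids, self.values[idx], self.groups)

    def restrict_to(self, genes: Sequence[str]) -> "GeneMatrix":
        """Subset to the given genes, keeping this matrix's row order."""
        wanted = set(genes)
        mask = np.array([g in wanted for g in self.gene_ids])
        return self.select_genes(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def filter_probe_ids(m: BetaMatrix,
                     blacklist: Sequence[str] = DEFAULT_PREFIX_BLACKLIST) -> BetaMatrix:
    """Drop probes whose id starts with a blacklisted prefix.

    Matching is case-sensitive; the default blacklist ("rs", "ch")
    removes SNP probes and non-CpG "ch." probes, leaving "cg" CpGs.
    Survivor order is preserved.
    """
    prefixes = tuple(blacklist)
    keep = np.array([not f.startswith(prefixes) for f in m.feature_ids])
    return m.select_features(keep)


def filter_degenerate(m: BetaMatrix) -> BetaMatrix:
    """Drop probes that are zero in every sample or missing in any sample.

    The result contains no missing values.
    """
    has_nan = np.isnan(m.values).any(axis=1)
    with np.errstate(invalid="ignore"):
        all_zero = np.nansum(np.abs(m.values), axis=1) == 0
    return m.select_features(~(has_nan | all_zero))


def minmax_normalize(m: BetaMatrix, drop_constant_rows: bool = False) -> BetaMatrix:
    """Rescale each probe row to span [0, 1].

    x -> (x - min(x)) / (max(x) - min(x)); a constant row maps to all
    zeros (or is dropped when ``drop_constant_rows`` is set).  Requires a
    missing-free matrix.
    """
    if np.isnan(m.values).any():
        raise ValidationError("min-max normalization requires a missing-free matrix")
    lo = m.values.min(axis=1, keepdims=True)
    hi = m.values.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0
    values = (m.values - lo) / span
    values[constant] = 0.0
    out = BetaMatrix(m.feature_ids, m.sample_ids, values, m.groups)
    if drop_constant_rows:
        out = out.select_features(~constant)
    return out


def aggregate_to_genes(m: BetaMatrix, ann: AnnotationMap) -> GeneMatrix:
    """Average the probes of each annotated gene into one vector per gene.

    Probes annotated to several genes contribute to each; unannotated
    probes are dropped.  Gene rows are emitted in sorted symbol order for
    determinism.
    """
    if np.isnan(m.values).any():
        raise ValidationError("aggregation requires a missing-free matrix")
    gene_rows: dict = {}
    for i, probe in enumerate(m.feature_ids):
        for gene in ann.genes_for(probe):
            gene_rows.setdefault(gene, []).append(i)
    if not gene_rows:
        raise ValidationError("no overlap between matrix probes and annotation")
    gene_ids = sorted(gene_rows)
    values = np.empty((len(gene_ids), m.n_samples))
    for r, gene in enumerate(gene_ids):
        values[r] = m.values[gene_rows[gene]].mean(axis=0)
    return GeneMatrix(gene_ids, m.sample_ids, values, m.groups)


def run_preprocess(m: BetaMatrix, ann: AnnotationMap,
               blacklist: Sequence[str] = DEFAULT_PREFIX_BLACKLIST,
               drop_constant_rows: bool = False) -> tuple:
    """Run the full stage in the fixed order and return
    ``(gene_matrix, counts)`` where ``counts`` records the accounting at
    every step."""
    counts = {"total_ids": m.n_features}
    m1 = filter_probe_ids(m, blacklist)
    counts["after_id_filter"] = m1.n_features
    m2 = filter_degenerate(m1)
    counts["after_degenerate_filter"] = m2.n_features
    m3 = minmax_normalize(m2, drop_constant_rows=drop_constant_rows)
    counts["after_normalization"] = m3.n_features
    g = aggregate_to_genes(m3, ann)
    counts["gene_vectors"] = g.n_genes
    return g, counts
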