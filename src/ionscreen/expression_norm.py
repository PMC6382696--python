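"""Fixed-quantile normalization for FPKM expression matrices.

A variant of upper-quartile normalization in which, per sample, the 70th
percentile of FPKM values — computed over an *included* gene set that
excludes members of high-homology gene families and genes whose longest
transcript is under 500 bp — is fixed at an anchor value of 10.  The
excluded genes never influence the scale factor but are rescaled in the
output like every other gene.

Quantiles use linear interpolation between order statistics, so the
post-condition "the included 70th percentile equals the anchor exactly"
holds, and the normalization is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "normalize_fixed_quantile",
    "read_expression_tsv",
    "read_annotation_tsv",
    "MIN_TRANSCRIPT_BP",
]

MIN_TRANSCRIPT_BP = 500
_MIN_INCLUDED_GENES = 10


@dataclass
class ExpressionMatrix:
    """Genes × samples FPKM matrix with the per-gene annotations the
    normalization needs: a high-homology-family flag and the maximal
    transcript length in bp."""

    values: pd.DataFrame          # index: gene_id, columns: sample ids
    homology_flag: pd.Series      # bool per gene
    max_transcript_bp: pd.Series  # int per gene

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValueError("FPKM values must be >= 0")
        genes = self.values.index
        for name, ann in (("homology_flag", self.homology_flag),
                          ("max_transcript_bp", self.max_transcript_bp)):
            if not genes.isin(ann.index).all():
                raise ValueError(f"annotation '{name}' missing for some genes")
        self.homology_flag = self.homology_flag.reindex(genes).astype(bool)
        self.max_transcript_bp = self.max_transcript_bp.reindex(genes)

    def included_genes(self) -> pd.Index:
        keep = (~self.homology_flag) & (self.max_transcript_bp >= MIN_TRANSCRIPT_BP)
        return self.values.index[keep]


def normalize_fixed_quantile(mat: ExpressionMatrix, quantile: float = 0.70,
                             anchor: float = 10.0
                             ) -> tuple[ExpressionMatrix, pd.Series]:
    """Scale each sample so the ``quantile`` of included-gene FPKM equals
    ``anchor``.  Returns (normalized matrix, per-sample scale factors).

    Samples whose included-gene quantile is zero cannot be normalized and
    are reported with a NaN scale factor (values passed through unchanged).
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    included = mat.included_genes()
    if len(included) < _MIN_INCLUDED_GENES:
        raise ValueError(
            f"only {len(included)} genes remain after exclusions; "
            f"need >= {_MIN_INCLUDED_GENES}"
        )
    sub = mat.values.loc[included]
    q = sub.quantile(quantile, interpolation="linear")
    scale = anchor / q.where(q > 0)
    normalized = mat.values.mul(scale.fillna(1.0), axis=1)
    out = ExpressionMatrix(values=normalized,
                           homology_flag=mat.homology_flag,
                           max_transcript_bp=mat.max_transcript_bp)
    return out, scale


def read_expression_tsv(path, sep: str | None = None) -> pd.DataFrame:
    """Gene × sample table; first column is the gene id."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     index_col=0)
    return df.astype(float)


def read_annotation_tsv(path) -> tuple[pd.Series, pd.Series]:
    """Annotation table with columns gene_id, homology_flag, max_transcript_bp."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "homology_flag", "max_transcript_bp"}
    if not need.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(need)}")
    df = df.set_index("gene_id")
    return df["homology_flag"].astype(bool), df["max_transcript_bp"].astype(int)
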