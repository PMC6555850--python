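"""TF regulatory scores (TFRS).

A TFRS quantifies the potential of TF i to regulate gene g by combining up
to three features of g's promoter accessible region: the motif enrichment
p-value, the region's accessibility signal (RPKM), and its distance to the
TSS.  Four promoter scoring schemes are defined::

    pval           -log10(p_ig)
    pval_dhs       -log10(p_ig) * RPKM_DHS(g)
    pval_dist      -log10(p_ig) * exp(-d_ig / 100)
    pval_dhs_dist  -log10(p_ig) * RPKM_DHS(g) * exp(-d_ig / 100)

with d_ig in bp.  For distal regions the score sums an exponentially
distance-discounted contribution over every accessible region within
+/- 1 Mb of the TSS::

    distal         sum_k -log10(p_ik) * RPKM_k * exp(-d_k / 10000)

Genes with several promoter regions sum their per-region scores, mirroring
the distal summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROMOTER_SCHEMES = ("pval", "pval_dhs", "pval_dist", "pval_dhs_dist")
SCHEMES = PROMOTER_SCHEMES + ("distal",)

PROMOTER_DECAY_BP = 100.0
DISTAL_DECAY_BP = 10_000.0


@dataclass(frozen=True)
class PromoterHit:
    """TF motif enrichment at one promoter accessible region of one gene."""

    tf_name: str
    gene_id: str
    p_value: float
    rpkm_dhs: float
    distance_bp: float  # unsigned midpoint-to-TSS distance

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")
        if self.rpkm_dhs < 0 or self.distance_bp < 0:
            raise ValueError("rpkm_dhs and distance_bp must be non-negative")


@dataclass(frozen=True)
class DistalHit:
    """TF motif enrichment at one distal accessible region near one gene."""

    tf_name: str
    gene_id: str
    dhs_index: str
    p_value: float
    rpkm_dhs: float
    distance_bp: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")
        if not 3000 < self.distance_bp <= 1_000_000:
            raise ValueError(
                f"distal distance must be in (3000, 1e6] bp, got {self.distance_bp}"
            )
        if self.rpkm_dhs < 0:
            raise ValueError("rpkm_dhs must be non-negative")


def _neg_log10(p: float) -> float:
    if p == 0.0:
        warnings.warn("p-value of 0 clamped to machine minimum", RuntimeWarning)
        p = np.finfo(float).tiny
    return -np.log10(p)


def tfrs_promoter(hit: PromoterHit, scheme: str) -> float:
    """Score one promoter hit under one of the four promoter schemes."""
    if scheme not in PROMOTER_SCHEMES:
        raise ValueError(f"unknown promoter scheme {scheme!r}")
    score = _neg_log10(hit.p_value)
    if scheme in ("pval_dhs", "pval_dhs_dist"):
        score *= hit.rpkm_dhs
    if scheme in ("pval_dist", "pval_dhs_dist"):
        score *= np.exp(-hit.distance_bp / PROMOTER_DECAY_BP)
    return float(score)


def tfrs_distal(hits: Iterable[DistalHit]) -> float:
    """Distance-decayed sum over all distal hits of one (TF, gene) pair."""
    hits = list(hits)
    if not hits:
        return 0.0
    keys = {(h.tf_name, h.gene_id) for h in hits}
    if len(keys) > 1:
        raise ValueError(f"hits span multiple (tf, gene) pairs: {sorted(keys)}")
    return float(
        sum(
            _neg_log10(h.p_value)
            * h.rpkm_dhs
            * np.exp(-h.distance_bp / DISTAL_DECAY_BP)
            for h in hits
        )
    )


@dataclass
class TFRSMatrix:
    """Gene x TF regulatory-score matrix under a named scheme."""

    scheme: str
    genes: list[str]
    tfs: list[str]
    scores: np.ndarray  # shape (n_genes, n_tfs)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.tfs)):
            raise ValueError("scores shape does not match genes x tfs")
        if (self.scores < 0).any():
            raise ValueError("TFRS scores must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genes, columns=self.tfs)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = self.scheme
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "TFRSMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            scheme=df.index.name or "pval",
            genes=[str(g) for g in df.index],
            tfs=[str(t) for t in df.columns],
            scores=df.values,
        )


def build_design_matrix(
    hits: Sequence[PromoterHit] | Sequence[DistalHit],
    genes: Sequence[str],
    tfs: Sequence[str],
    scheme: str,
) -> TFRSMatrix:
    """Assemble the gene x TF score matrix for a scheme.

    Promoter schemes sum per-region scores over a gene's promoter regions;
    the distal scheme applies the decayed sum.  (TF, gene) pairs without
    hits score 0.  Hits referencing unlisted genes/TFs, or exact duplicate
    (tf, gene, region) records, are errors.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    gene_idx = {g: i for i, g in enumerate(genes)}
    tf_idx = {t: j for j, t in enumerate(tfs)}
    scores = np.zeros((len(genes), len(tfs)))
    seen: set[tuple] = set()
    for h in hits:
        if h.gene_id not in gene_idx:
            raise ValueError(f"hit references unlisted gene {h.gene_id!r}")
        if h.tf_name not in tf_idx:
            raise ValueError(f"hit references unlisted TF {h.tf_name!r}")
        key = (h.tf_name, h.gene_id, getattr(h, "dhs_index", h.distance_bp))
        if key in seen:
            raise ValueError(f"duplicate hit {key}")
        seen.add(key)
        i, j = gene_idx[h.gene_id], tf_idx[h.tf_name]
        if scheme == "distal":
            if not isinstance(h, DistalHit):
                raise TypeError("distal scheme requires DistalHit records")
            scores[i, j] += tfrs_distal([h])
        else:
            if not isinstance(h, PromoterHit):
                raise TypeError(f"scheme {scheme!r} requires PromoterHit records")
            scores[i, j] += tfrs_promoter(h, scheme)
    return TFRSMatrix(scheme=scheme, genes=list(genes), tfs=list(tfs), scores=scores)
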