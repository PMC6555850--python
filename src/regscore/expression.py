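"""Expression tables, cell-type-enriched gene selection, knockdown DE,
and the accessibility-expression rank-sum association check.

Enrichment uses the filter cascade: mean target FPKM > fpkm_min,
fold-change strictly > fc_min against EACH reference cell type, and
(when both sides have >= 2 replicates) BH-corrected q-value < q_max from a
moderated two-sample t-test on log2(FPKM + 1).  The moderated-t/BH pair is
a declared stand-in for a count-based negative-binomial test: externally
computed q-values can be supplied instead via ``q_values=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: pseudo-FPKM added to numerator and denominator of every fold-change
FC_EPSILON = 0.01


class ExpressionTable:
    """Gene x sample FPKM matrix; sample labels are ``celltype.repN``."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression table")
        if (values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.values = values

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.values.columns:
            seen.setdefault(c.rsplit(".", 1)[0])
        return list(seen)

    def slice(self, cell_type: str) -> pd.DataFrame:
        """Columns belonging to one cell type (all replicates)."""
        cols = [c for c in self.values.columns if c.rsplit(".", 1)[0] == cell_type]
        if not cols:
            raise KeyError(f"no samples for cell type {cell_type!r}")
        return self.values[cols]

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class EnrichmentCall:
    gene_id: str
    log2_fc_per_reference: np.ndarray
    q_value: float | None  # None in single-replicate mode
    passed: bool


#: prior degrees of freedom of the variance moderation
MODERATION_PRIOR_DF = 4.0


def _moderated_q(target: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """BH-corrected q-values from a moderated two-sample t-test on
    log2(FPKM+1).

    Each gene's pooled within-group variance is shrunk toward the median
    variance across genes (prior df = 4, limma-style), so the test keeps
    honest power at two replicates per condition — the regime where a plain
    per-gene t-test has ~2 df and cannot reach small p-values even for
    clean large fold-changes.  Degenerate rows (zero moderated variance)
    get p = 0 when the means differ and p = 1 when they coincide.
    """
    a = np.log2(target.values + 1.0)
    b = np.log2(reference.values + 1.0)
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    d_g = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / d_g
    s2_prior = float(np.median(s2))
    d0 = MODERATION_PRIOR_DF
    s2_mod = (d0 * s2_prior + d_g * s2) / (d0 + d_g)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    p = np.ones(len(diff))
    ok = se > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(diff[ok]) / se[ok], df=d0 + d_g)
    p[~ok & ~np.isclose(diff, 0.0)] = 0.0
    return stats.false_discovery_control(p, method="bh")


def select_enriched_genes(
    target: pd.DataFrame,
    references: list[pd.DataFrame],
    fc_min: float = 4.0,
    q_max: float = 0.001,
    fpkm_min: float = 1.0,
    q_values: np.ndarray | None = None,
) -> list[EnrichmentCall]:
    """Call genes enriched in the target cell type versus every reference.

    ``target`` and each reference are gene x replicate FPKM frames sharing
    one index.  A gene passes iff mean target FPKM > fpkm_min and its
    fold-change against each reference is strictly > fc_min; when both the
    target and a reference have >= 2 replicates the q-value clause
    (q < q_max) applies as well.  With a single replicate anywhere only the
    FC and FPKM clauses are used.  ``q_values`` (aligned to the gene index)
    overrides the internal moderated-t/BH stand-in, e.g. with DESeq2 output.
    """
    if not references:
        raise ValueError("at least one reference cell type is required")
    for i, ref in enumerate(references):
        if ref.shape[1] == 0:
            raise ValueError(f"reference {i} has zero samples")
        if not ref.index.equals(target.index):
            raise ValueError(f"reference {i} gene index differs from target")

    t_mean = target.values.mean(axis=1)
    replicated = target.shape[1] >= 2 and all(r.shape[1] >= 2 for r in references)

    fcs = np.column_stack(
        [
            (t_mean + FC_EPSILON) / (ref.values.mean(axis=1) + FC_EPSILON)
            for ref in references
        ]
    )
    if q_values is not None:
        q = np.asarray(q_values, dtype=float)
        have_q = True
    elif replicated:
        # gene must beat q_max against every reference: keep the worst q
        q = np.column_stack([_moderated_q(target, ref) for ref in references]).max(axis=1)
        have_q = True
    else:
        q = np.full(len(target), np.nan)
        have_q = False

    calls: list[EnrichmentCall] = []
    for i, gene in enumerate(target.index):
        passed = bool(
            t_mean[i] > fpkm_min
            and (fcs[i] > fc_min).all()
            and (not have_q or q[i] < q_max)
        )
        calls.append(
            EnrichmentCall(
                gene_id=str(gene),
                log2_fc_per_reference=np.log2(fcs[i]),
                q_value=float(q[i]) if have_q else None,
                passed=passed,
            )
        )
    return calls


def knockdown_de(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    fc_min: float = 2.0,
    q_max: float = 0.05,
    fpkm_min: float = 1.0,
    q_values: np.ndarray | None = None,
) -> tuple[list[str], list[str]]:
    """Down- and up-regulated genes under the relaxed knockdown cutoffs.

    A gene is called iff max(mean FPKM) across the two conditions exceeds
    fpkm_min, |fold change| > fc_min and q < q_max; direction follows the
    treatment/control mean ratio.  Returns (down_genes, up_genes).
    """
    if treatment.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("knockdown DE requires >= 2 replicates per condition")
    if not control.index.equals(treatment.index):
        raise ValueError("treatment/control gene indices differ")
    t_mean = treatment.values.mean(axis=1)
    c_mean = control.values.mean(axis=1)
    fc = (t_mean + FC_EPSILON) / (c_mean + FC_EPSILON)
    q = (
        np.asarray(q_values, dtype=float)
        if q_values is not None
        else _moderated_q(treatment, control)
    )
    expressed = np.maximum(t_mean, c_mean) > fpkm_min
    sig = expressed & (q < q_max)
    down = [str(g) for i, g in enumerate(treatment.index) if sig[i] and fc[i] < 1 / fc_min]
    up = [str(g) for i, g in enumerate(treatment.index) if sig[i] and fc[i] > fc_min]
    return down, up


def dhs_expression_association(
    expr: pd.DataFrame, genes_with_promoter_dhs: set[str]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney-Wilcoxon test: expression of genes with a
    promoter accessible region versus genes without one.

    ``expr`` is a gene x replicate FPKM frame for one cell type; per-gene
    mean FPKM is compared between the two groups.  Returns (U, p).
    """
    mean = expr.values.mean(axis=1)
    mask = np.array([g in genes_with_promoter_dhs for g in expr.index])
    with_dhs = mean[mask]
    without = mean[~mask]
    if len(with_dhs) < 2 or len(without) < 2:
        raise ValueError(
            f"degenerate groups: {len(with_dhs)} genes with promoter DHS, "
            f"{len(without)} without (need >= 2 each)"
        )
    res = stats.mannwhitneyu(with_dhs, without, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def association_from_annotations(expr: pd.DataFrame, annotations) -> tuple[float, float]:
    """Convenience wrapper deriving the promoter-DHS gene set from
    :class:`~regscore.genomics.PeakAnnotation` records."""
    with_dhs = {
        a.gene_id for a in annotations if a.category == "promoter" and a.gene_id
    }
    return dhs_expression_association(expr, with_dhs)
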