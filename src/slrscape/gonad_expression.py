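"""Gonadal expression screening: TPM, tissue specificity (tau), candidate
sex-determining patterns, and PCH vs non-PCH expression comparison.

The candidate screen looks for the two patterns characteristic of a young
XY system's sex-determining region: a gene expressed in testis and the early
stages of the intersex (ovotestis) transition but depleted in ovary, and a
gene exclusively expressed in testis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pch_compartments import PCHBlock
from .sexlink_scan import ranksum_p

EARLY_INTERSEX_STAGES = ("I1", "I2", "I3")
LATE_INTERSEX_STAGES = ("I4", "I5")


@dataclass
class CandidateReport:
    gene: str
    pattern: str  # testis_plus_early_intersex | testis_exclusive | none
    group_means: dict[str, float]
    in_slr: bool


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a genes x samples count table.

    TPM_g = 1e6 * (c_g/l_g) / sum_i (c_i/l_i). An all-zero sample stays
    all-zero (flagged via an attrs note rather than an error).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    denom = denom.replace(0, np.nan)
    out = rate.div(denom, axis=1) * 1e6
    out[out.columns[zero]] = 0.0
    out.attrs["zero_samples"] = list(out.columns[zero])
    return out


def _group_means(expr: pd.DataFrame, groups: pd.Series, log: bool = False) -> pd.DataFrame:
    groups = groups.reindex(expr.columns)
    mat = np.log2(expr + 1.0) if log else expr
    return mat.T.groupby(groups).mean().T


def tau(expr: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Tissue-specificity index on log2(TPM+1) group means.

    tau = sum_i (1 - x_i / max_i x_i) / (n_groups - 1), in [0, 1]; genes with
    all-zero expression are missing.
    """
    gm = _group_means(expr, groups, log=True)
    if gm.shape[1] < 2:
        raise ValueError("tau needs >= 2 groups")
    mx = gm.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (1.0 - gm.div(mx, axis=0)).sum(axis=1) / (gm.shape[1] - 1)
    t[mx <= 0] = np.nan
    return t


def screen_candidates(
    expr: pd.DataFrame,
    groups: pd.Series,
    slr_genes: set[str] | None = None,
    fold: float = 4.0,
    expressed_min: float = 1.0,
) -> list[CandidateReport]:
    """Screen genes for sex-determining candidate expression patterns.

    Group labels must include ``testis``, ``ovary`` and ``intersex_early``
    (others, e.g. ``intersex_late`` or somatic tissues, are used for the
    exclusivity check). A gene is expressed in a group when its mean TPM
    exceeds ``expressed_min``. Patterns:

    * ``testis_plus_early_intersex`` — expressed in testis AND early
      intersex, both group means >= ``fold`` x ovary mean, and the testis and
      early-intersex means within 2-fold of each other.
    * ``testis_exclusive`` — expressed in testis and in no other group.

    When ``slr_genes`` is given, the report is restricted to those genes.
    """
    gm = _group_means(expr, groups)
    for need in ("testis", "ovary", "intersex_early"):
        if need not in gm.columns:
            raise ValueError(f"missing sample group: {need}")
    genes = gm.index if slr_genes is None else [g for g in gm.index if g in slr_genes]
    out = []
    for g in genes:
        row = gm.loc[g]
        t, o, e = row["testis"], row["ovary"], row["intersex_early"]
        others = row.drop("testis")
        pattern = "none"
        if t > expressed_min and (others <= expressed_min).all():
            pattern = "testis_exclusive"
        elif (
            t > expressed_min
            and e > expressed_min
            and t >= fold * o
            and e >= fold * o
            and max(t, e) <= 2.0 * min(t, e)
        ):
            pattern = "testis_plus_early_intersex"
        out.append(
            CandidateReport(
                g, pattern, {k: float(v) for k, v in row.items()},
                in_slr=(slr_genes is not None and g in slr_genes),
            )
        )
    return out


def pch_expression_compare(
    expr: pd.DataFrame,
    groups: pd.Series,
    blocks: list[PCHBlock],
    gene_positions: pd.DataFrame,
    expressed_min: float = 1.0,
) -> dict:
    """Compare expression of genes inside vs outside PCH.

    ``gene_positions``: DataFrame indexed by gene with chrom, start, end;
    membership is by gene midpoint. Reports, per class, the proportion of
    expressed genes (max group-mean TPM > ``expressed_min``), median TPM and
    median tau, plus two-sided Wilcoxon rank-sum p values on TPM and tau.
    """
    if not blocks:
        return {"note": "no PCH blocks; comparison skipped"}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chromosome, []).append(b.interval)
    gp = gene_positions.reindex(expr.index).dropna()
    mids = ((gp.start + gp.end) // 2).astype(int)
    in_pch = pd.Series(False, index=gp.index)
    for g in gp.index:
        for s, e in by_chrom.get(gp.loc[g, "chrom"], []):
            if s <= mids[g] < e:
                in_pch[g] = True
                break
    gm_max = _group_means(expr, groups).max(axis=1)
    taus = tau(expr, groups)
    report = {}
    cls_values = {}
    for name, genes in (("pch", in_pch[in_pch].index), ("non_pch", in_pch[~in_pch].index)):
        if len(genes) == 0:
            return {"note": f"class '{name}' empty; comparison skipped"}
        v = gm_max.loc[genes]
        report[name] = {
            "n_genes": int(len(genes)),
            "prop_expressed": float((v > expressed_min).mean()),
            "median_tpm": float(v.median()),
            "median_tau": float(taus.loc[genes].median(skipna=True)),
        }
        cls_values[name] = (v.to_numpy(), taus.loc[genes].dropna().to_numpy())
    report["p_tpm"] = ranksum_p(cls_values["pch"][0], cls_values["non_pch"][0])
    report["p_tau"] = ranksum_p(cls_values["pch"][1], cls_values["non_pch"][1])
    return report
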