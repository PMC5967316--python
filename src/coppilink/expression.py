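"""Expression calls, tissue-specificity z-scores and co-expression.

A gene is called *expressed* at a spatiotemporal site when its RPKM exceeds 1
in at least one sample of that site. Tissue specificity of a gene is the
z-score of its per-tissue mean expression across tissues,

    z_i = (expr_i - mean(Expr)) / sd(Expr),

where Expr collects the gene's mean expression over all tissues; a higher z
means more tissue-specific expression. Co-expression between two genes is the
absolute Pearson correlation coefficient |PCC| of their expression profiles
over the samples of one site.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ExpressionPanel:
    """Per-site genes x samples RPKM matrices plus site metadata.

    ``sites`` maps site_id -> DataFrame (index: gene symbols, columns:
    sample ids). ``metadata`` has columns site_id, stage, region.
    """

    sites: dict[str, pd.DataFrame]
    metadata: pd.DataFrame

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites)

    @property
    def genes(self) -> pd.Index:
        first = next(iter(self.sites.values()))
        return first.index

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        for site, mat in self.sites.items():
            mat.to_csv(
                outdir / f"expression_{site}.tsv",
                sep="\t",
                index_label="gene",
                float_format="%.6g",
            )

    @classmethod
    def read(cls, outdir: str | Path) -> "ExpressionPanel":
        outdir = Path(outdir)
        meta = pd.read_csv(outdir / "sites.tsv", sep="\t", dtype=str)
        sites = {}
        for site in meta["site_id"]:
            path = outdir / f"expression_{site}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing expression matrix: {path}")
            sites[site] = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(sites=sites, metadata=meta)


def call_expressed(
    matrix: pd.DataFrame, rpkm_threshold: float = 1.0, min_samples: int = 1
) -> pd.Series:
    """Boolean expression call per gene: RPKM > threshold in >= min_samples."""
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative RPKM values in expression matrix")
    flags = (values > rpkm_threshold).sum(axis=1) >= min_samples
    return pd.Series(flags, index=matrix.index, name="expressed")


def panel_calls(
    panel: ExpressionPanel, rpkm_threshold: float = 1.0, min_samples: int = 1
) -> pd.DataFrame:
    """Expression calls for every gene at every site (genes x sites)."""
    cols = {
        site: call_expressed(mat, rpkm_threshold, min_samples)
        for site, mat in panel.sites.items()
    }
    return pd.DataFrame(cols)


def site_mean_expression(panel: ExpressionPanel) -> pd.DataFrame:
    """Per-gene mean RPKM at each site/tissue (genes x sites)."""
    return pd.DataFrame({s: m.mean(axis=1) for s, m in panel.sites.items()})


def tissue_z(mean_expr: Mapping[str, float] | pd.Series) -> pd.Series:
    """z-score of one gene's mean expression across tissues.

    Degenerate case: if the per-tissue means are constant (sd = 0) every z is
    defined as 0 — the gene carries no tissue-specificity signal.
    """
    s = pd.Series(mean_expr, dtype=float)
    if len(s) < 2:
        raise ValueError("tissue z-score needs >= 2 tissues")
    sd = s.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return pd.Series(0.0, index=s.index)
    return (s - s.mean()) / sd


def tissue_z_matrix(means: pd.DataFrame) -> pd.DataFrame:
    """Row-wise tissue z-scores for a genes x tissues mean-expression table."""
    if means.shape[1] < 2:
        raise ValueError("tissue z-score needs >= 2 tissues")
    arr = means.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mu) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=means.index, columns=means.columns)


def coexpression(matrix: pd.DataFrame, gene_i: str, gene_j: str) -> float:
    """|PCC| between two genes over the samples of one site, in [0, 1].

    A zero-variance gene has no defined correlation; its co-expression is
    reported as 0 with a logged warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError("co-expression needs >= 3 samples")
    x = matrix.loc[gene_i].to_numpy(dtype=float)
    y = matrix.loc[gene_j].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        logger.warning(
            "zero-variance gene in pair (%s, %s); co-expression set to 0",
            gene_i, gene_j,
        )
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return min(abs(r), 1.0)


def compare_tissue_specificity(
    z: pd.DataFrame,
    sets: Sequence,
    tissues: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """One-sided t-tests of tissue z-scores, set vs non-set, per tissue.

    For every (gene set, tissue) cell: Welch t statistic for "members have
    higher z than non-members", raw p, and BH-adjusted p computed over the
    full set x tissue grid. Degenerate groups give missing p.
    """
    tissues = list(tissues) if tissues is not None else list(z.columns)
    rows = []
    for gs in sets:
        members = sorted(set(gs.genes) & set(z.index))
        others = sorted(set(z.index) - set(members))
        for tissue in tissues:
            a = z.loc[members, tissue].to_numpy(dtype=float)
            b = z.loc[others, tissue].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2 or (a.std() == 0 and b.std() == 0):
                t = p = np.nan
            else:
                t, p = stats.ttest_ind(
                    a, b, equal_var=False, alternative="greater"
                )
            rows.append(
                {"set": gs.label, "tissue": tissue, "n_set": len(a),
                 "t": t, "p": p}
            )
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["p_bh"] = np.nan
    if ok.any():
        table.loc[ok, "p_bh"] = multipletests(
            table.loc[ok, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return table


def group_expression_summary(sets: Sequence, calls: pd.DataFrame) -> pd.DataFrame:
    """Proportion of each gene set called expressed at each site."""
    rows = []
    for gs in sets:
        members = sorted(gs.genes)
        if not members:
            raise ValueError(f"gene set {gs.label!r} is empty")
        present = [g for g in members if g in calls.index]
        for site in calls.columns:
            n_expr = int(calls.loc[present, site].sum()) if present else 0
            rows.append(
                {
                    "set": gs.label,
                    "site": site,
                    "n_genes": len(members),
                    "n_expressed": n_expr,
                    "proportion": n_expr / len(members),
                }
            )
    return pd.DataFrame(rows)


def _abs_corr_matrix(sub: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(sub)
    c = np.abs(c)
    c[~np.isfinite(c)] = 0.0  # zero-variance genes contribute 0
    return np.clip(c, 0.0, 1.0)


def within_set_coexpression_profile(
    genes: Iterable[str], matrix: pd.DataFrame
) -> pd.Series:
    """Per-gene mean |PCC| to the other members of the set, at one site."""
    members = sorted(set(genes) & set(matrix.index))
    if len(members) < 2:
        raise ValueError("co-expression profile needs >= 2 genes in matrix")
    c = _abs_corr_matrix(matrix.loc[members].to_numpy(dtype=float))
    np.fill_diagonal(c, 0.0)
    means = c.sum(axis=1) / (len(members) - 1)
    return pd.Series(means, index=members, name="mean_abs_pcc")


def random_set_coexpression_profiles(
    matrix: pd.DataFrame,
    set_size: int,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pooled per-gene mean |PCC| values for size-matched random gene sets."""
    genes = np.asarray(sorted(matrix.index))
    out = []
    for _ in range(n_draws):
        pick = rng.choice(genes, size=set_size, replace=False)
        out.append(within_set_coexpression_profile(pick, matrix).to_numpy())
    return np.concatenate(out)
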