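"""Cross-species ortholog expression comparison and gene-movement counts.

Compares normalized ortholog expression between an outgroup species (where
the neo-X element is still autosomal) and the ingroup, per tissue and
stratified by MSL proximity, and tabulates inter-chromosomal gene movement
with Fisher's exact test.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .mslmap import categorize_msl  # noqa: F401  (re-exported convenience)


def _fold_eps(num: np.ndarray, den: np.ndarray, eps: float) -> np.ndarray:
    both_pos = (num > 0) & (den > 0)
    return np.where(both_pos, 0.0, eps)


def ortholog_fold_difference(
    expr_out: pd.DataFrame,
    expr_in: pd.DataFrame,
    pairs: pd.DataFrame,
    tissue: str,
    eps: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair log2 fold-difference (outgroup / ingroup) in one tissue.

    ``pairs`` needs columns outgroup_id, ingroup_id, ingroup_chrom. Pairs
    where both members are zero are dropped. Returns the per-pair table and a
    per-ingroup-chromosome summary (median log2 FD, Wilcoxon rank-sum p of
    each chromosome class against all other pairs).
    """
    for tbl, name in ((expr_out, "outgroup"), (expr_in, "ingroup")):
        if tissue not in tbl.columns:
            raise ValueError(f"tissue {tissue!r} absent from {name} table")
    p = pairs[pairs.outgroup_id.isin(expr_out.index)
              & pairs.ingroup_id.isin(expr_in.index)].copy()
    out = expr_out.loc[p.outgroup_id, tissue].to_numpy(float)
    ing = expr_in.loc[p.ingroup_id, tissue].to_numpy(float)
    keep = ~((out == 0) & (ing == 0))
    p, out, ing = p[keep], out[keep], ing[keep]
    e = _fold_eps(out, ing, eps)
    p["log2_fd"] = np.log2((out + e) / (ing + e))
    p["tissue"] = tissue

    rows = []
    for chrom in pd.unique(p.ingroup_chrom):
        mask = (p.ingroup_chrom == chrom).to_numpy()
        a, b = p.log2_fd.to_numpy()[mask], p.log2_fd.to_numpy()[~mask]
        pv = (stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
              if len(a) >= 3 and len(b) >= 3 else np.nan)
        rows.append((chrom, float(np.median(a)), len(a), pv))
    summary = pd.DataFrame(
        rows, columns=["ingroup_chrom", "median_log2_fd", "n_pairs", "p_vs_rest"])
    return p.reset_index(drop=True), summary


def msl_stratified_fold(
    fold_table: pd.DataFrame,
    msl: pd.DataFrame,
    scheme: str = "binary",
    expr_out: pd.DataFrame | None = None,
    min_genes: int = 3,
) -> dict:
    """Stratify ortholog fold-differences by MSL proximity.

    ``fold_table`` is long format with columns ingroup_id, tissue, log2_fd
    (the ortholog_fold_difference output, possibly concatenated over
    tissues); ``msl`` is the annotate_msl output indexed by ingroup gene id.
    Returns a dict with per-(tissue, category) medians, proximal-vs-distal
    Wilcoxon tests per tissue, and — when ``expr_out`` is provided — the
    Pearson correlation between MSL distance and outgroup expression.
    """
    cat_col = "category2" if scheme == "binary" else "category5"
    ft = fold_table.copy()
    ft["category"] = msl[cat_col].reindex(ft.ingroup_id).to_numpy()
    ft["category2"] = msl["category2"].reindex(ft.ingroup_id).to_numpy()
    ft = ft.dropna(subset=["category"])

    medians = (ft.groupby(["tissue", "category"], observed=True)["log2_fd"]
               .agg(["median", "size"]).rename(columns={"size": "n"}))
    tests = []
    for tissue, sub in ft.groupby("tissue", observed=True):
        prox = sub.log2_fd[sub.category2 == "proximal"]
        dist = sub.log2_fd[sub.category2 == "distal"]
        pv = (stats.mannwhitneyu(prox, dist, alternative="two-sided").pvalue
              if len(prox) >= min_genes and len(dist) >= min_genes else np.nan)
        tests.append((tissue, len(prox), len(dist), pv))
    tests = pd.DataFrame(tests, columns=["tissue", "n_proximal", "n_distal", "p"])

    result = {"medians": medians, "proximal_vs_distal": tests}
    if expr_out is not None:
        genes = msl.index.intersection(expr_out.index)
        d = msl.loc[genes, "distance_bp"].to_numpy(float)
        e = expr_out.loc[genes].mean(axis=1).to_numpy(float)
        ok = np.isfinite(d)
        if ok.sum() >= 3:
            r, pv = stats.pearsonr(d[ok], e[ok])
        else:
            r, pv = np.nan, np.nan
        result["distance_expression_pearson"] = {"r": float(r), "p": float(pv),
                                                 "n": int(ok.sum())}
    return result


def movement_flags(pairs: pd.DataFrame) -> pd.Series:
    """Derived moved flag: ingroup chromosome differs from the source.

    The source chromosome is ``ancestral_chrom`` when present (outgroup-of-
    outgroup assignment), else ``outgroup_chrom``.
    """
    source = pairs["ancestral_chrom"] if "ancestral_chrom" in pairs else \
        pairs["outgroup_chrom"]
    return (pairs["ingroup_chrom"].to_numpy() != source.to_numpy())


def gene_movement_table(
    pairs: pd.DataFrame,
    focal_chrom: str,
    contrast_chrom: str,
) -> tuple[np.ndarray, float]:
    """2x2 moved/retained counts for two source chromosomes + Fisher p.

    Rows are the focal and contrast source chromosomes, columns (moved,
    retained). Returns the table and the two-sided Fisher exact p (NaN with a
    warning when a source class is empty).
    """
    source = pairs["ancestral_chrom"] if "ancestral_chrom" in pairs else \
        pairs["outgroup_chrom"]
    moved = movement_flags(pairs)
    table = np.zeros((2, 2), dtype=int)
    for i, chrom in enumerate((focal_chrom, contrast_chrom)):
        mask = (source == chrom).to_numpy()
        table[i, 0] = int((moved & mask).sum())
        table[i, 1] = int((~moved & mask).sum())
    if table.sum(axis=1).min() == 0:
        warnings.warn("empty source chromosome class; p undefined", stacklevel=2)
        return table, float("nan")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
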