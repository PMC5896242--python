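"""Temporal classification and signature set algebra for regression genes.

Significant genes are classified by the pairwise contrast in which they
first exceed the 10-fold threshold: *early* genes change between the
progressive and stationary phases (S vs P), *late* genes between stationary
and regressive (R vs S) but not earlier, and *progressive* genes only
accumulate enough change over the whole course (R vs P) without crossing the
threshold in either single step.  The three classes are disjoint by
construction.

Directed gene sets are plain ``{gene_id: +1 | -1}`` mappings (sign = up /
down in the qualifying contrast), which keeps the set algebra — Venn
overlaps, the interaction-filtered candidate signature and the core
regression signature — explicit and easy to audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LABELS",
    "SignatureSets",
    "classify_temporal",
    "build_heatmap_matrix",
    "set_overlap",
    "core_signature",
    "logfc_concordance",
    "rank_outliers",
    "signature_enrichment",
]

LABELS = ("EARLY_UP", "EARLY_DOWN", "LATE_UP", "LATE_DOWN", "PROG_UP", "PROG_DOWN", "NONE")

DirectedSet = dict


def _suffix(direction: int) -> str:
    return "UP" if direction > 0 else "DOWN"


def classify_temporal(
    sig_sp: DirectedSet,
    sig_rs: DirectedSet,
    sig_rp: DirectedSet,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Classify genes as early, late or progressive from the three directed
    significant sets.

    Early = significant in S vs P; late = significant in R vs S but not in
    S vs P; progressive = significant in R vs P but in neither single step.
    The direction suffix comes from the qualifying contrast.  Returns a frame
    indexed by gene with columns ``label``, ``qualifying_contrast`` and
    ``direction``; genes in no set (or outside all sets in ``universe``) are
    ``NONE``.
    """
    genes = set(sig_sp) | set(sig_rs) | set(sig_rp)
    if universe is not None:
        genes |= set(universe)
    rows = {}
    for g in genes:
        if g in sig_sp:
            label, contrast, d = f"EARLY_{_suffix(sig_sp[g])}", "S_vs_P", sig_sp[g]
        elif g in sig_rs:
            label, contrast, d = f"LATE_{_suffix(sig_rs[g])}", "R_vs_S", sig_rs[g]
        elif g in sig_rp:
            label, contrast, d = f"PROG_{_suffix(sig_rp[g])}", "R_vs_P", sig_rp[g]
        else:
            label, contrast, d = "NONE", None, 0
        rows[g] = {"label": label, "qualifying_contrast": contrast, "direction": d}
    out = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
    if out.empty:
        out = pd.DataFrame(columns=["label", "qualifying_contrast", "direction"])
    out = out.sort_index()
    out.index.name = "gene_id"
    return out


def build_heatmap_matrix(
    normalized_counts: pd.DataFrame,
    baseline_sample_ids: list[str],
    sort_samples: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 expression relative to the geometric mean of the baseline samples.

    Entry = log2(x + pc) - mean over baselines of log2(x_b + pc) (the mean of
    the logs).  Rows are sorted descending by the mean relative expression
    over ``sort_samples`` (default: all non-baseline samples).
    """
    if not baseline_sample_ids:
        raise ValueError("empty baseline sample set")
    missing = set(baseline_sample_ids) - set(normalized_counts.columns)
    if missing:
        raise ValueError(f"baseline samples not in matrix: {sorted(missing)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    logx = np.log2(normalized_counts + pseudocount)
    rel = logx.sub(logx[baseline_sample_ids].mean(axis=1), axis=0)
    if sort_samples is None:
        sort_samples = [c for c in rel.columns if c not in set(baseline_sample_ids)] or list(rel.columns)
    key = rel[sort_samples].mean(axis=1)
    return rel.loc[key.sort_values(ascending=False).index]


def set_overlap(a, b) -> dict:
    """Venn counts and the percent of the first set shared, to one decimal.

    The percentage is truncated (not rounded) to one decimal place
    (e.g. 648/1016 = 63.78% appears as 63.7%).
    ``percent_of_a`` is None for an empty first set.
    """
    sa, sb = set(a), set(b)
    inter = sa & sb
    if sa:
        pct = np.floor(round(1000.0 * len(inter) / len(sa), 6)) / 10.0
    else:
        pct = None
    return {
        "a_only": len(sa - sb),
        "intersection": len(inter),
        "b_only": len(sb - sa),
        "percent_of_a": pct,
    }


@dataclass
class SignatureSets:
    """Candidate and core regression signatures with direction concordance.

    candidate = significant in the regressive validation arm AND in the
    regression-status interaction; core = candidate genes also significant in
    the regressing index case but NOT in the non-regressing one.  Genes whose
    direction differs between the validation arm and the index case are
    retained but flagged in ``discordant``.
    """

    sig_reg_7xx: DirectedSet
    sig_interaction: set
    sig_c5: DirectedSet
    sig_c6: DirectedSet
    candidate: DirectedSet
    core: DirectedSet
    discordant: set


def core_signature(
    sig_reg_7xx: DirectedSet,
    sig_interaction,
    sig_c5: DirectedSet,
    sig_c6: DirectedSet,
) -> SignatureSets:
    """Core-regression-signature set algebra.

    ``sig_interaction`` may be a directed set or a plain collection of gene
    ids (directions are irrelevant to membership).
    """
    inter_ids = set(sig_interaction)
    candidate = {g: d for g, d in sig_reg_7xx.items() if g in inter_ids}
    core = {g: d for g, d in candidate.items() if g in sig_c5 and g not in sig_c6}
    discordant = {g for g in candidate if g in sig_c5 and sig_c5[g] * candidate[g] < 0}
    return SignatureSets(
        sig_reg_7xx=dict(sig_reg_7xx),
        sig_interaction=inter_ids,
        sig_c5=dict(sig_c5),
        sig_c6=dict(sig_c6),
        candidate=candidate,
        core=core,
        discordant=discordant,
    )


def logfc_concordance(
    result_a,
    result_b,
    gene_subset: list[str] | None = None,
) -> tuple[float, int, int]:
    """Pearson correlation of per-gene log2 fold changes between two contrasts.

    Accepts :class:`~ctvtreg.count_model.ContrastResult` objects or frames
    with ``log2fc`` (and optionally ``tested``) columns.  Genes not tested in
    either result are excluded and counted.  Returns (r, n_used, n_excluded).
    """

    def extract(res) -> pd.Series:
        tab = res.table if hasattr(res, "table") else res
        s = tab["log2fc"]
        if "tested" in tab:
            s = s[tab["tested"]]
        return s.dropna()

    a, b = extract(result_a), extract(result_b)
    genes = a.index.intersection(b.index)
    if gene_subset is not None:
        genes = genes.intersection(pd.Index(gene_subset))
    total = len(a.index.union(b.index)) if gene_subset is None else len(set(gene_subset))
    n_excluded = total - len(genes)
    if len(genes) < 3:
        raise ValueError("need >= 3 genes with finite log2fc in both results")
    x, y = a.loc[genes].to_numpy(), b.loc[genes].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the log2fc vectors")
    r = float(stats.pearsonr(x, y).statistic)
    return r, len(genes), n_excluded


def rank_outliers(mean_expr_a: pd.Series, mean_expr_b: pd.Series) -> pd.DataFrame:
    """Rank genes by absolute residual from the least-squares line of B on A.

    Both inputs are mean normalised expression per gene; they are transformed
    to log2(x + 1) before the fit.  Returns a frame sorted by |residual|
    descending with the signed residual, so the most discrepant genes between
    the two conditions come first.
    """
    common = mean_expr_a.index.intersection(mean_expr_b.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes")
    x = np.log2(mean_expr_a.loc[common].to_numpy(float) + 1.0)
    y = np.log2(mean_expr_b.loc[common].to_numpy(float) + 1.0)
    if np.std(x) == 0:
        raise ValueError("zero variance in the x expression vector")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    out = pd.DataFrame({"log2_a": x, "log2_b": y, "residual": resid}, index=common)
    out["abs_residual"] = out["residual"].abs()
    out = out.sort_values("abs_residual", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["slope"] = float(slope)
    out.attrs["intercept"] = float(intercept)
    return out


def signature_enrichment(
    expr_matrix: pd.DataFrame,
    gene_set,
    sample_groups: dict[str, list[str]] | None = None,
) -> tuple[pd.Series, float | None]:
    """Per-sample enrichment of a gene signature, with an optional group test.

    Score = mean over the signature genes of the within-gene z-score of each
    sample (a generic relative-enrichment score).  If ``sample_groups`` names
    two groups of >= 2 samples, they are compared by a two-sided Wilcoxon
    rank-sum test and its p-value is returned (else None).
    """
    genes = [g for g in set(gene_set) if g in expr_matrix.index]
    if not set(gene_set):
        raise ValueError("empty gene set")
    if not genes:
        raise ValueError("gene set does not intersect the expression matrix")
    sub = expr_matrix.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0)
    scores = z.mean(axis=0, skipna=True)
    scores.name = "enrichment_score"
    pval = None
    if sample_groups is not None:
        if len(sample_groups) != 2:
            raise ValueError("exactly two sample groups are required for the test")
        (g1, s1), (g2, s2) = sample_groups.items()
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError("each group needs >= 2 samples")
        pval = float(stats.ranksums(scores[s1], scores[s2]).pvalue)
    return scores, pval
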