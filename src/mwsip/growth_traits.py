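"""Life-history and growth traits of ¹³C-incorporating taxa.

Computes, from bulk (unfractionated) community time series and incorporator
calls: rrn- and biomass-normalized abundances, the maximum log₂-fold change
after carbon addition relative to an unamended baseline (zero-floored),
latency between peak substrate mineralization and first detected labeling,
rarefaction, alpha diversity (richness, Pielou's evenness, Faith's PD), and
Wilcoxon rank-sum comparisons of traits between groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .exceptions import AnalysisError, DomainError, InvalidDesignError
from .gradient_sip import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_RAREFY_DEPTH = 1567


def rarefy(counts: pd.DataFrame, depth: int = DEFAULT_RAREFY_DEPTH, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample without replacement to an even depth.

    Samples whose total is below ``depth`` are dropped with a warning.
    Deterministic under ``seed``.
    """
    if depth < 1:
        raise InvalidDesignError("depth must be at least 1")
    rng = np.random.default_rng(seed)
    kept = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            logger.warning("sample %r total %d < depth %d; dropped", sample, total, depth)
            continue
        if total == depth:
            kept[sample] = col
        else:
            kept[sample] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(kept, index=counts.index)


def normalize_abundance(rel_abundance, taxon_rrn, sample_mean_rrn, dna_yield):
    """rrn-corrected, biomass-weighted abundance.

    Relative abundance is divided by the taxon's predicted rrn copy number
    and by the sample-level mean rrn, then weighted by the sample's DNA
    yield (ng/µL) as a biomass proxy:
    ``(rel / taxon_rrn / sample_mean_rrn) × dna_yield``.
    """
    rel = np.asarray(rel_abundance, dtype=float)
    taxon_rrn = np.asarray(taxon_rrn, dtype=float)
    if np.any(rel < 0):
        raise DomainError("rel_abundance must be nonnegative")
    if np.any(taxon_rrn <= 0) or sample_mean_rrn <= 0 or dna_yield <= 0:
        raise DomainError("rrn and dna_yield must be positive")
    out = rel / taxon_rrn / sample_mean_rrn * dna_yield
    return float(out) if out.ndim == 0 else out


def normalize_table(counts: pd.DataFrame, rrn: pd.Series, dna_yield: pd.Series) -> pd.DataFrame:
    """Apply :func:`normalize_abundance` columnwise to a count table.

    The sample mean rrn is the relative-abundance-weighted mean rrn over
    the taxa detected in that sample.
    """
    rrn = rrn.reindex(counts.index)
    if rrn.isna().any():
        missing = rrn[rrn.isna()].index.tolist()[:5]
        raise AnalysisError(f"taxa without rrn prediction: {missing}")
    dna_yield = dna_yield.reindex(counts.columns)
    if dna_yield.isna().any():
        raise AnalysisError("every sample needs a dna_yield")
    out = {}
    for sample in counts.columns:
        rel = counts[sample] / counts[sample].sum()
        mean_rrn = float((rel * rrn).sum())
        out[sample] = normalize_abundance(rel, rrn, mean_rrn, float(dna_yield[sample]))
    return pd.DataFrame(out, index=counts.index)


def max_l2fc(normalized_series_after_c, baseline_no_c: float) -> float:
    """Maximum log₂-fold change after C addition, floored at zero.

    ``log₂(max(series)/baseline)``; when the post-addition maximum is below
    the unamended baseline the value is zero, and an empty series yields
    NaN (undefined).
    """
    series = np.asarray(normalized_series_after_c, dtype=float)
    if series.size == 0:
        return float("nan")
    if baseline_no_c <= 0:
        raise DomainError("baseline must be positive (apply pseudo-abundance first)")
    return max(0.0, float(np.log2(series.max() / baseline_no_c)))


def baseline_with_pseudo(baseline: pd.Series) -> pd.Series:
    """Replace zero baseline abundances with the smallest nonzero value.

    The baseline-ratio in :func:`max_l2fc` is undefined for taxa absent
    from the unamended control; they receive the control sample's smallest
    nonzero normalized abundance as a pseudo-abundance.
    """
    nonzero = baseline[baseline > 0]
    if nonzero.empty:
        raise AnalysisError("baseline sample has no nonzero abundances")
    return baseline.where(baseline > 0, nonzero.min())


def latency(first_label_day, peak_mineralization_day) -> float:
    """Days between peak substrate mineralization and first detected labeling.

    ``max(0, first_label_day − peak_mineralization_day)``: taxa labeled on
    or before the mineralization peak get latency zero.  A missing
    ``first_label_day`` (never labeled) yields NaN.
    """
    if first_label_day is None or (
        isinstance(first_label_day, float) and np.isnan(first_label_day)
    ):
        return float("nan")
    if first_label_day < 0 or peak_mineralization_day < 0:
        raise DomainError("days must be nonnegative")
    return max(0.0, float(first_label_day) - float(peak_mineralization_day))


def wilcoxon_rank_sum(group_a, group_b, alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum (Mann–Whitney) test with midrank tie handling.

    Uses exact enumeration for small untied samples (both n ≤ 20) and the
    normal approximation with continuity correction otherwise.  ``W`` is
    the rank-sum-derived U statistic of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidDesignError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return {"W": float(res.statistic), "p": float(res.pvalue)}


def faith_pd(present_taxa, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity of a set of present tips.

    Total branch length of the subtree spanning the present taxa and the
    root (union of all root-to-tip branches); accepts multifurcating trees.
    """
    tips = {t.name: t for t in tree.tips()}
    edges = set()
    total = 0.0
    for name in present_taxa:
        if name not in tips:
            raise AnalysisError(f"taxon missing from tree: {name!r}")
        node = tips[name]
        while node.parent is not None:
            if id(node) in edges:
                break
            edges.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def alpha_diversity(counts: pd.DataFrame, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats), Pielou's evenness and Faith's PD.

    Pielou's evenness is the ratio of Shannon diversity to the natural log
    of richness (NaN when richness ≤ 1).  Faith's PD (requires ``tree``) is
    the total branch length of the subtree spanning the present taxa and
    the root.
    """
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = [t for t in counts.index if t not in tips]
        if missing:
            raise AnalysisError(f"taxon missing from tree: {missing[0]!r}")
    rows = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        present = col > 0
        richness = int(present.sum())
        p = col[present] / col[present].sum() if richness else np.array([])
        shannon = float(-(p * np.log(p)).sum()) if richness else 0.0
        pielou = shannon / np.log(richness) if richness > 1 else float("nan")
        row = {"richness": richness, "shannon": shannon, "pielou_evenness": pielou}
        if tree is not None:
            row["faith_pd"] = faith_pd(counts.index[present], tree)
        rows[sample] = row
    return pd.DataFrame(rows).T


def incorporator_diversity(
    calls: pd.DataFrame, counts: pd.DataFrame, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Alpha diversity of the incorporator subcommunity, per sample."""
    inc = calls.index[calls["is_incorporator"]]
    sub = counts.loc[counts.index.intersection(inc)]
    return alpha_diversity(sub, tree=tree)


def build_trait_table(
    calls: pd.DataFrame,
    window_results: pd.DataFrame,
    normalized: pd.DataFrame,
    baseline_sample: str,
    rrn: pd.Series,
    peak_day: float,
    substrate: str,
    tillage: str = "NTH",
) -> pd.DataFrame:
    """Assemble the per-incorporator trait table for one substrate × tillage.

    ``normalized`` is the rrn/biomass-normalized bulk table whose
    ``baseline_sample`` column is the unamended (water-only) control;
    remaining columns are post-addition sampling days.
    """
    from .gradient_sip import degree_of_assimilation

    inc = calls.index[calls["is_incorporator"]]
    base = baseline_with_pseudo(normalized[baseline_sample])
    after = normalized.drop(columns=[baseline_sample])
    degree = degree_of_assimilation(window_results)

    rows = []
    for taxon in inc:
        first = calls.loc[taxon, "first_label_day"]
        series = after.loc[taxon] if taxon in after.index else pd.Series(dtype=float)
        rows.append(
            {
                "taxon_id": taxon,
                "substrate": substrate,
                "tillage": tillage,
                "rrn": float(rrn.get(taxon, np.nan)),
                "latency": latency(first, peak_day),
                "max_l2fc": max_l2fc(series.to_numpy(), float(base.get(taxon, np.nan)))
                if taxon in after.index else float("nan"),
                "degree_assimilation": float(degree.get(taxon, np.nan)),
                "first_label_day": first,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def compare_groups(
    traits: pd.DataFrame,
    trait_cols: list[str],
    group_col: str,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of each trait between the two levels
    of ``group_col``, with BH adjustment across traits."""
    levels = sorted(traits[group_col].dropna().unique())
    if len(levels) != 2:
        raise InvalidDesignError(f"{group_col!r} must have exactly 2 levels, got {levels}")
    rows = []
    for col in trait_cols:
        a = traits.loc[traits[group_col] == levels[0], col].dropna()
        b = traits.loc[traits[group_col] == levels[1], col].dropna()
        if a.empty or b.empty:
            continue
        res = wilcoxon_rank_sum(a, b)
        rows.append({"trait": col, "group_a": levels[0], "group_b": levels[1],
                     "n_a": len(a), "n_b": len(b), "W": res["W"], "p": res["p"]})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
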