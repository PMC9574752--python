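"""Dropout-screen scoring: total-count normalization, per-guide T14/T0 fold
changes, per-gene aggregation, and hit calling against a non-targeting null.

The per-gene score is the mean of guide log2 fold changes (the geometric
mean of the fold changes); a ``mean_ratio`` aggregation preserving the
literal arithmetic-mean-of-ratios reading is available as an option.
Empirical p-values use the add-one convention and Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .library_model import LibraryManifest, NON_TARGETING_GENE
from .screen_quant import GuideCountTable

DEFAULT_PSEUDOCOUNT = 0.5


def normalize_total(
    counts: GuideCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scale: float = 1e6,
) -> pd.DataFrame:
    """Counts-per-``scale`` normalization against per-sample totals.

    n[g, t] = scale * (c[g, t] + pseudocount) / sum_g (c[g, t] + pseudocount)
    """
    raw = counts.counts.astype(float)
    if (raw.sum(axis=0) == 0).any():
        bad = raw.columns[raw.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    shifted = raw + pseudocount
    return scale * shifted / shifted.sum(axis=0)


def guide_log2fc(
    normalized: pd.DataFrame, samples: Sequence | GuideCountTable
) -> pd.DataFrame:
    """Per-guide fold change between timepoints.

    Replicates are averaged on the normalized scale within each timepoint
    before the T14/T0 ratio.  Returns columns n_T0, n_T14, fc, log2fc.
    """
    if isinstance(samples, GuideCountTable):
        samples = samples.samples
    t0_cols = [s.sample_id for s in samples if s.timepoint == "T0"]
    t14_cols = [s.sample_id for s in samples if s.timepoint == "T14"]
    if not t0_cols or not t14_cols:
        raise ValueError("both T0 and T14 samples are required")
    n_t0 = normalized[t0_cols].mean(axis=1)
    n_t14 = normalized[t14_cols].mean(axis=1)
    if (n_t0 == 0).any():
        raise ValueError(
            "zero normalized T0 abundance; re-normalize with a pseudocount > 0"
        )
    fc = n_t14 / n_t0
    return pd.DataFrame(
        {"n_T0": n_t0, "n_T14": n_t14, "fc": fc, "log2fc": np.log2(fc)}
    )


def aggregate_gene(
    guide_table: pd.DataFrame,
    manifest: LibraryManifest,
    gene_agg: str = "mean_log2",
) -> pd.DataFrame:
    """Per-gene score from per-guide log2 fold changes.

    ``mean_log2`` (default): S = mean of log2 fold changes.
    ``mean_ratio``: S = log2 of the arithmetic-mean fold change.
    Non-targeting guides are excluded (they feed the null model instead).
    """
    if gene_agg not in ("mean_log2", "mean_ratio"):
        raise ValueError(f"unknown gene_agg {gene_agg!r}")
    gene_of = {r.guide_id: r.gene for r in manifest.records if r.category != "non_targeting"}
    unknown = set(guide_table.index) - set(r.guide_id for r in manifest.records)
    if unknown:
        raise ValueError(f"guides absent from manifest: {sorted(unknown)[:5]}")
    sub = guide_table.loc[guide_table.index.isin(gene_of)].copy()
    sub["gene"] = [gene_of[g] for g in sub.index]
    grouped = sub.groupby("gene", sort=False)
    if gene_agg == "mean_log2":
        score = grouped["log2fc"].mean()
    else:
        score = np.log2(grouped["fc"].mean())
    out = pd.DataFrame({"score": score, "n_guides": grouped.size()})
    out.index.name = "gene"
    return out


def nontargeting_log2fc(
    guide_table: pd.DataFrame, manifest: LibraryManifest
) -> pd.Series:
    nt = [r.guide_id for r in manifest.records if r.category == "non_targeting"]
    return guide_table.loc[guide_table.index.isin(nt), "log2fc"]


@dataclass
class NullModel:
    """Pseudo-gene score distribution built from non-targeting guides."""

    scores: np.ndarray
    guides_per_gene: int
    mode: str
    seed: int | None = None

    @property
    def n_pseudo(self) -> int:
        return self.scores.size


def build_null(
    nt_log2fc: pd.Series | np.ndarray,
    guides_per_gene: int = 3,
    mode: str = "exhaustive",
    n_pseudo: int = 1000,
    seed: int = 0,
) -> NullModel:
    """Pseudo-gene scores: means of ``guides_per_gene``-subsets of the
    non-targeting guide log2 fold changes.

    ``exhaustive`` enumerates all combinations (220 for the default 12-guide
    library); ``resampled`` draws ``n_pseudo`` subsets without replacement
    within each draw.
    """
    values = np.asarray(nt_log2fc, dtype=float)
    if values.size < guides_per_gene:
        raise ValueError(
            f"need at least {guides_per_gene} non-targeting guides, got {values.size}"
        )
    if mode == "exhaustive":
        scores = np.array(
            [np.mean(c) for c in itertools.combinations(values, guides_per_gene)]
        )
        return NullModel(scores, guides_per_gene, mode)
    if mode == "resampled":
        rng = np.random.default_rng(seed)
        idx = np.array(
            [
                rng.choice(values.size, size=guides_per_gene, replace=False)
                for _ in range(n_pseudo)
            ]
        )
        return NullModel(values[idx].mean(axis=1), guides_per_gene, mode, seed)
    raise ValueError(f"unknown null mode {mode!r}")


def empirical_pvalues(
    scores: np.ndarray, null: np.ndarray, direction: str
) -> np.ndarray:
    """Add-one empirical p: (1 + #{null <= S}) / (1 + n_null) for depletion,
    mirrored (>=) for enrichment."""
    null = np.sort(np.asarray(null, dtype=float))
    n = null.size
    if direction == "depletion":
        cnt = np.searchsorted(null, scores, side="right")
    elif direction == "enrichment":
        cnt = n - np.searchsorted(null, scores, side="left")
    else:
        raise ValueError(f"direction must be 'depletion' or 'enrichment', got {direction!r}")
    return (1.0 + cnt) / (1.0 + n)


def call_hits(
    gene_scores: pd.DataFrame,
    null: NullModel,
    direction: str = "depletion",
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Rank genes against the non-targeting null.

    Returns the gene table with empirical p, BH q and a ``hit`` flag,
    sorted by score (ascending for depletion, descending for enrichment).
    """
    if null.n_pseudo == 0:
        raise ValueError("null model is empty")
    out = gene_scores.copy()
    out["p"] = empirical_pvalues(out["score"].to_numpy(), null.scores, direction)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["hit"] = out["q"] < fdr_threshold
    return out.sort_values("score", ascending=(direction == "depletion"), kind="mergesort")


@dataclass
class EssentialQcReport:
    passed: bool
    quantile: float
    threshold_score: float
    control_ranks: Dict[str, int]   # rank 1 = most depleted
    control_scores: Dict[str, float]


def qc_essential_controls(
    gene_scores: pd.DataFrame,
    manifest: LibraryManifest,
    quantile: float = 0.25,
) -> EssentialQcReport:
    """Pass iff every essential-control gene scores below the given quantile
    of the non-essential gene scores."""
    essential = set(manifest.genes("essential_control"))
    if not essential:
        raise ValueError("manifest declares no essential_control genes")
    scored_ess = [g for g in gene_scores.index if g in essential]
    if not scored_ess:
        raise ValueError("no essential_control gene present in the score table")
    others = gene_scores.loc[~gene_scores.index.isin(essential), "score"]
    threshold = float(others.quantile(quantile))
    ranks = gene_scores["score"].rank(method="min").astype(int)
    return EssentialQcReport(
        passed=bool((gene_scores.loc[scored_ess, "score"] < threshold).all()),
        quantile=quantile,
        threshold_score=threshold,
        control_ranks={g: int(ranks[g]) for g in scored_ess},
        control_scores={g: float(gene_scores.loc[g, "score"]) for g in scored_ess},
    )


def competition_normalize(
    series: Mapping, reference_time
) -> Dict:
    """Normalize a reporter-positive/negative ratio time course to its value
    at ``reference_time`` (which maps to 1)."""
    if reference_time not in series:
        raise ValueError(f"reference time {reference_time!r} absent from series")
    ref = series[reference_time]
    if ref <= 0:
        raise ValueError(f"reference value at {reference_time!r} must be > 0, got {ref}")
    return {t: v / ref for t, v in series.items()}


def score_screen(
    counts: GuideCountTable,
    manifest: LibraryManifest,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gene_agg: str = "mean_log2",
    null_mode: str = "exhaustive",
    n_pseudo: int = 1000,
    direction: str = "depletion",
    fdr_threshold: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, NullModel]:
    """Convenience pipeline: normalize -> guide log2fc -> gene scores -> hits.

    Returns (guide_table, gene_table_with_hits, null_model).
    """
    norm = normalize_total(counts, pseudocount=pseudocount)
    guides = guide_log2fc(norm, counts)
    genes = aggregate_gene(guides, manifest, gene_agg=gene_agg)
    null = build_null(
        nontargeting_log2fc(guides, manifest),
        mode=null_mode,
        n_pseudo=n_pseudo,
        seed=seed,
    )
    hits = call_hits(genes, null, direction=direction, fdr_threshold=fdr_threshold)
    return guides, hits, null
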