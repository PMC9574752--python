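"""Weighted pre-ranked gene-set enrichment, differential-regulation filter,
and row z-transform.

The enrichment score walks the ranked list: hits increment the running sum
by |metric|^p normalized to the in-set total, misses decrement by
1/(N - N_hits); ES is the signed maximum deviation from zero.  Significance
uses gene-set permutation (random same-size sets), with NES normalized by
the mean |null ES| of matching sign and a sign-stratified permutation FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class RankedList:
    """Genes with a ranking metric, kept sorted by metric descending."""

    genes: List[str]
    metrics: np.ndarray

    def __post_init__(self) -> None:
        self.metrics = np.asarray(self.metrics, dtype=float)
        if len(self.genes) != self.metrics.size:
            raise ValueError("genes and metrics must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("genes must be unique")
        if not np.isfinite(self.metrics).all():
            raise ValueError("metrics must be finite")
        # stable sort: ties keep input order
        order = np.argsort(-self.metrics, kind="mergesort")
        self.genes = [self.genes[i] for i in order]
        self.metrics = self.metrics[order]

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        return cls(list(s.index), s.to_numpy())

    def __len__(self) -> int:
        return len(self.genes)

    def index_of(self, gene_set: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        return np.array(sorted(pos[g] for g in gene_set if g in pos), dtype=int)


def es_statistic(
    ranked: RankedList, gene_set: Sequence[str], weight: float = 1.0
) -> Tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score.

    Returns (ES, running-sum profile of length N).  Errors if the set has
    an empty intersection with the universe or covers it entirely.
    """
    n = len(ranked)
    hits = ranked.index_of(gene_set)
    if hits.size == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if hits.size == n:
        raise ValueError("gene set covers the whole universe (no misses)")
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hits] = True
    w = np.abs(ranked.metrics) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all in-set metrics are exactly zero: fall back to equal weights
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~is_hit) / (n - hits.size)
    running = np.cumsum(steps)
    hi, lo = running.max(), running.min()
    es = hi if hi >= -lo else lo  # positive deviation wins exact ties
    return float(es), running


def _es_only(
    sorted_hits: np.ndarray, w: np.ndarray, n: int
) -> float:
    """ES from sorted hit positions without materializing the profile.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit (local max candidates) or immediately before one
    (local min candidates), plus the terminal value.
    """
    k = sorted_hits.size
    hw = w[sorted_hits]
    total = hw.sum()
    if total == 0:
        hw = np.ones(k)
        total = float(k)
    miss = 1.0 / (n - k)
    cum_hw = np.cumsum(hw) / total
    j = np.arange(1, k + 1)
    after = cum_hw - (sorted_hits + 1 - j) * miss       # just after hit j
    before = np.concatenate(([0.0], cum_hw[:-1])) - (sorted_hits - (j - 1)) * miss
    hi = after.max()
    lo = min(before.min(), after[-1] - (n - 1 - sorted_hits[-1]) * miss)
    return float(hi if hi >= -lo else lo)


@dataclass
class GseaResult:
    table: pd.DataFrame                      # per set: ES, NES, p, q, size
    leading_edge: Dict[str, List[str]] = field(default_factory=dict)
    skipped: Dict[str, str] = field(default_factory=dict)


def leading_edge_genes(
    ranked: RankedList, gene_set: Sequence[str], weight: float = 1.0
) -> List[str]:
    es, running = es_statistic(ranked, gene_set, weight)
    members = set(gene_set)
    if es >= 0:
        peak = int(np.argmax(running))
        return [g for g in ranked.genes[: peak + 1] if g in members]
    peak = int(np.argmin(running))
    return [g for g in ranked.genes[peak:] if g in members]


def gsea_preranked(
    ranked: RankedList,
    collection: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
    max_size: int = 500,
) -> GseaResult:
    """Pre-ranked enrichment over a gene-set collection with gene-set
    permutation (random same-size sets drawn from the ranked universe).

    NES = ES / mean |null ES| of matching sign; nominal p is one-sided
    within sign; FDR q follows the sign-stratified NES-null recipe.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    w = np.abs(ranked.metrics) ** weight

    names, sizes, es_obs = [], [], []
    skipped: Dict[str, str] = {}
    leading: Dict[str, List[str]] = {}
    for name, members in collection.items():
        hits = ranked.index_of(members)
        if hits.size < min_size or hits.size > max_size:
            skipped[name] = (
                f"set size {hits.size} outside [{min_size}, {max_size}] after "
                "intersection with the ranked universe"
            )
            continue
        if hits.size == n:
            skipped[name] = "set covers the whole universe"
            continue
        names.append(name)
        sizes.append(hits.size)
        es_obs.append(_es_only(hits, w, n))
        leading[name] = leading_edge_genes(ranked, members, weight)

    if not names:
        return GseaResult(
            pd.DataFrame(columns=["es", "nes", "size", "p", "q"]), {}, skipped
        )

    es_obs_arr = np.array(es_obs)
    # one shared null per distinct set size
    null_by_size: Dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = np.sort(rng.choice(n, size=k, replace=False))
            null[i] = _es_only(idx, w, n)
        null_by_size[k] = null

    nes_obs = np.empty_like(es_obs_arr)
    pvals = np.empty_like(es_obs_arr)
    nes_null_all: List[np.ndarray] = []
    for i, (k, es) in enumerate(zip(sizes, es_obs_arr)):
        null = null_by_size[k]
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        nes_null = np.where(null >= 0, null / mean_pos, null / mean_neg)
        nes_null_all.append(nes_null)
        if es >= 0:
            nes_obs[i] = es / mean_pos if pos.size else np.nan
            pvals[i] = (1 + np.sum(pos >= es)) / (1 + pos.size) if pos.size else 1.0
        else:
            nes_obs[i] = -np.abs(es) / mean_neg if neg.size else np.nan
            pvals[i] = (1 + np.sum(neg <= es)) / (1 + neg.size) if neg.size else 1.0

    qvals = _signed_fdr(nes_obs, np.concatenate(nes_null_all))

    table = pd.DataFrame(
        {"es": es_obs_arr, "nes": nes_obs, "size": sizes, "p": pvals, "q": qvals},
        index=pd.Index(names, name="gene_set"),
    )
    return GseaResult(table, leading, skipped)


def _signed_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """Sign-stratified permutation FDR on NES values (canonical recipe):
    q(NES*) = [null fraction at least as extreme, same sign] /
              [observed fraction at least as extreme, same sign], capped at 1.
    """
    q = np.ones_like(nes_obs)
    pos_null = nes_null[nes_null >= 0]
    neg_null = nes_null[nes_null < 0]
    pos_obs = nes_obs[nes_obs >= 0]
    neg_obs = nes_obs[nes_obs < 0]
    for i, nes in enumerate(nes_obs):
        if np.isnan(nes):
            continue
        if nes >= 0:
            null_frac = np.mean(pos_null >= nes) if pos_null.size else 1.0
            obs_frac = np.mean(pos_obs >= nes) if pos_obs.size else 1.0
        else:
            null_frac = np.mean(neg_null <= nes) if neg_null.size else 1.0
            obs_frac = np.mean(neg_obs <= nes) if neg_obs.size else 1.0
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    return q


def de_filter(
    table: pd.DataFrame,
    lfc_min: float = 1.0,
    padj_max: float = 0.01,
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> List[str]:
    """Differentially-regulated genes: |LFC| >= lfc_min (inclusive) AND
    adjusted p < padj_max (strict)."""
    if not np.isfinite(table[[lfc_col, padj_col]].to_numpy()).all():
        raise ValueError("DE table contains non-finite values")
    keep = (table[lfc_col].abs() >= lfc_min) & (table[padj_col] < padj_max)
    return list(table.index[keep])


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-transform with the population (n-denominator) standard
    deviation; constant rows become all zeros with a warning."""
    if matrix.shape[1] < 2:
        raise ValueError("z-transform requires at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) mapped to zeros", RuntimeWarning,
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        (values - mean) / sd, index=matrix.index, columns=matrix.columns
    )


# ---------------------------------------------------------------------------
# GMT / ranked-list I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs name, description, >=1 gene")
            name, _desc, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_ranked_tsv(path) -> RankedList:
    df = pd.read_csv(path, sep="\t")
    return RankedList(list(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float))


def write_ranked_tsv(ranked: RankedList, path) -> None:
    pd.DataFrame({"gene": ranked.genes, "metric": ranked.metrics}).to_csv(
        path, sep="\t", index=False
    )
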