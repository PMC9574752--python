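"""Synthetic inputs with known ground truth for every pipeline stage.

Screen counts follow a minimal exponential-growth model: a guide with gene
fitness ``s`` (per-doubling relative growth effect) and efficiency ``e``
changes its expected abundance by ``2**(d * s * e)`` over ``d`` population
doublings.  Sequencing adds negative-binomial noise around depth-scaled
abundances.  Intensity tables mimic paired bait/control label-free screens
with intensity-dependent missingness; ranked expression lists carry planted
concordant gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .library_model import LibraryManifest
from .screen_quant import DEFAULT_ANCHOR, GuideCountTable, SampleInfo

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# pooled screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Parameters of the pooled dropout-screen simulator.

    guide_efficiency: either a float (every guide gets that efficiency) or
    Beta(a, b) parameters as a tuple; efficiencies are in [0, 1].
    gene_fitness: gene -> s; genes absent from the mapping are neutral
    (s = 0) and non-targeting guides are always forced to s = 0.
    """

    manifest: LibraryManifest
    coverage: float = 2000.0
    doublings: float = 8.0
    guide_efficiency: float | Tuple[float, float] = (5.0, 1.0)
    gene_fitness: Mapping[str, float] = field(default_factory=dict)
    depth: float = 500.0
    dispersion: float = 0.05
    t0_gamma_shape: float = 10.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0 or self.depth <= 0 or self.doublings <= 0:
            raise ValueError("coverage, depth and doublings must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.manifest) == 0:
            raise ValueError("manifest must not be empty")


@dataclass
class ScreenTruth:
    gene_fitness: Dict[str, float]
    guide_efficiency: pd.Series      # indexed by guide_id
    expected_log2fc: pd.Series       # d * s * e per guide; 0 for non-targeting


def _draw_efficiencies(
    spec: float | Tuple[float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(spec, (int, float)):
        e = np.full(n, float(spec))
    else:
        a, b = spec
        e = rng.beta(a, b, size=n)
    if ((e < 0) | (e > 1)).any():
        raise ValueError("guide efficiencies must lie in [0, 1]")
    return e


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB draw with Var = mu + dispersion * mu^2; Poisson when dispersion=0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean / shape))


def simulate_screen_counts(
    params: ScreenSimParams,
) -> Tuple[GuideCountTable, ScreenTruth]:
    """Simulate T0/T14 guide counts under the exponential-growth model."""
    rng = np.random.default_rng(params.seed)
    manifest = params.manifest
    guide_ids = [r.guide_id for r in manifest.records]
    n = len(guide_ids)

    e = _draw_efficiencies(params.guide_efficiency, n, rng)
    s = np.array(
        [
            0.0
            if r.category == "non_targeting"
            else float(params.gene_fitness.get(r.gene, 0.0))
            for r in manifest.records
        ]
    )
    expected_l2fc = params.doublings * s * e

    # T0 abundance: Gamma around `coverage` cells per guide
    shape = params.t0_gamma_shape
    t0_abund = rng.gamma(shape, params.coverage / shape, size=n)
    t14_abund = t0_abund * np.exp2(expected_l2fc)

    samples: List[SampleInfo] = []
    columns: Dict[str, np.ndarray] = {}
    for tp, abund in (("T0", t0_abund), ("T14", t14_abund)):
        for rep in range(1, params.n_replicates + 1):
            sid = f"{tp}_r{rep}"
            total_reads = params.depth * n
            mu = total_reads * abund / abund.sum()
            columns[sid] = _nb_counts(mu, params.dispersion, rng).astype(np.int64)
            samples.append(SampleInfo(sid, tp, rep))

    counts = pd.DataFrame(columns, index=pd.Index(guide_ids, name="guide_id"))
    truth = ScreenTruth(
        gene_fitness={
            g: float(params.gene_fitness.get(g, 0.0))
            for g in manifest.genes()
            if g != "NT"
        },
        guide_efficiency=pd.Series(e, index=guide_ids, name="efficiency"),
        expected_log2fc=pd.Series(expected_l2fc, index=guide_ids, name="expected_log2fc"),
    )
    return GuideCountTable(counts=counts, samples=samples), truth


@dataclass(frozen=True)
class ReadStructure:
    """Fixed read layout: 5' anchor + spacer + random fill to read_length."""

    anchor: str = DEFAULT_ANCHOR
    read_length: int = 50


def render_screen_fastq(
    counts: GuideCountTable,
    manifest: LibraryManifest,
    out_dir,
    read_structure: ReadStructure = ReadStructure(),
    error_rate: float = 0.0,
    seed: int = 0,
) -> Dict[str, Path]:
    """Write one FASTQ per sample; each guide is emitted exactly its count
    times, with iid per-base substitution errors at ``error_rate`` and a
    constant Phred-40 ('I') quality string.
    """
    structure_len = len(read_structure.anchor) + manifest.spacer_length
    if structure_len > read_structure.read_length:
        raise ValueError(
            f"anchor + spacer ({structure_len} nt) exceeds read length "
            f"{read_structure.read_length}"
        )
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacers = {r.guide_id: r.spacer for r in manifest.records}
    qual = "I" * read_structure.read_length
    fill_len = read_structure.read_length - structure_len

    paths: Dict[str, Path] = {}
    for sample_id in counts.sample_ids():
        path = out_dir / f"{sample_id}.fastq"
        with open(path, "w") as fh:
            i = 0
            for guide_id, count in counts.counts[sample_id].items():
                base = read_structure.anchor + spacers[guide_id]
                for _ in range(int(count)):
                    fill = "".join(
                        "ACGT"[j] for j in rng.integers(0, 4, size=fill_len)
                    )
                    seq = _mutate(base + fill, error_rate, rng)
                    fh.write(f"@{sample_id}:{guide_id}:{i}\n{seq}\n+\n{qual}\n")
                    i += 1
        paths[sample_id] = path
    return paths


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        # substitute with one of the three other bases, uniformly
        idx = np.nonzero(hit)[0]
        cur = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# dual intensity screens
# ---------------------------------------------------------------------------

@dataclass
class IpSimParams:
    """Parameters of the paired affinity/proximity intensity simulator."""

    n_background: int = 150
    n_true: int = 10
    true_enrichment_fold: float = 4.0
    bait_id: str = "BAIT"
    missing_rate_base: float = 0.01
    missing_intensity_slope: float = 1.5
    missing_midpoint: float = 14.0   # log2 intensity of 50% dropout
    lfq_sigma: float = 0.3
    specific_fraction: float = 0.2   # share of background enriched in one screen only
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate_base <= 1):
            raise ValueError("missing_rate_base must be in [0, 1]")
        if self.true_enrichment_fold <= 1:
            raise ValueError("true_enrichment_fold must be > 1")
        if self.n_true < 0 or self.n_background < 0:
            raise ValueError("protein counts must be >= 0")
        if not (0 <= self.specific_fraction <= 0.5):
            raise ValueError("specific_fraction must be in [0, 0.5]")


@dataclass
class IntensityTable:
    """Protein x sample intensities for one screen; NaN marks not identified."""

    screen_id: str
    intensities: pd.DataFrame          # index protein_id, columns sample_id
    sample_roles: Dict[str, str]       # sample_id -> 'bait' | 'control'

    def __post_init__(self) -> None:
        roles = set(self.sample_roles.values())
        if not {"bait", "control"} <= roles:
            raise ValueError("both bait and control samples must be declared")
        if set(self.sample_roles) != set(self.intensities.columns):
            raise ValueError("sample sheet does not match intensity columns")
        vals = self.intensities.to_numpy(dtype=float)
        present = vals[~np.isnan(vals)]
        if present.size and (present <= 0).any():
            raise ValueError("present intensities must be positive")

    def samples(self, role: str) -> List[str]:
        return [s for s, r in self.sample_roles.items() if r == role]


@dataclass
class IpTruth:
    true_interactors: List[str]
    flag_specific: List[str]
    bioid_specific: List[str]
    bait_id: str


def simulate_ip_screens(
    params: IpSimParams,
) -> Tuple[IntensityTable, IntensityTable, IpTruth]:
    """Simulate FLAG-IP and BioID intensity tables around shared truth.

    True interactors are enriched ``true_enrichment_fold``-fold in the bait
    sample of both screens; a fraction of the background is enriched in
    exactly one screen (screen-specific binders); the rest is flat.
    Missingness follows logistic(slope * (midpoint - log2 I)) plus a base
    rate, so faint proteins drop out more often.
    """
    rng = np.random.default_rng(params.seed)
    true_ids = [f"TRUE{i:03d}" for i in range(params.n_true)]
    bg_ids = [f"BG{i:04d}" for i in range(params.n_background)]
    n_spec = int(round(params.specific_fraction * params.n_background))
    flag_specific = bg_ids[:n_spec]
    bioid_specific = bg_ids[n_spec : 2 * n_spec]
    proteins = [params.bait_id] + true_ids + bg_ids

    # shared base abundance on log2 scale (the two screens see the same
    # molecules but with independent noise); screen-specific binders are
    # abundant sticky proteins, reliably detected in both controls
    base_log2 = {p: rng.normal(20.0, 2.0) for p in proteins}
    for p in flag_specific + bioid_specific:
        base_log2[p] = rng.normal(21.0, 1.0)
    log2_fold = np.log2(params.true_enrichment_fold)

    def build(screen_id: str, specific: List[str]) -> IntensityTable:
        cols = {}
        for role in ("bait", "control"):
            sid = f"{screen_id}_{role}"
            vals = []
            for p in proteins:
                mu = base_log2[p]
                if role == "bait":
                    if p in true_ids or p in specific:
                        mu = mu + log2_fold + 1.0  # comfortably above threshold
                    elif p == params.bait_id:
                        mu = mu + 6.0
                else:
                    if p == params.bait_id:
                        mu = mu - 6.0  # bait barely present in control pulldown
                x = mu + rng.normal(0.0, params.lfq_sigma)
                p_missing = params.missing_rate_base + (
                    1 - params.missing_rate_base
                ) / (
                    1.0
                    + np.exp(
                        -params.missing_intensity_slope
                        * (params.missing_midpoint - x)
                    )
                )
                if p == params.bait_id and role == "bait":
                    p_missing = 0.0  # bait always identified in its own pulldown
                vals.append(np.nan if rng.random() < p_missing else 2.0 ** x)
            cols[sid] = vals
        df = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))
        roles = {f"{screen_id}_bait": "bait", f"{screen_id}_control": "control"}
        return IntensityTable(screen_id, df, roles)

    flag = build("flag_ip", flag_specific)
    bioid = build("bioid", bioid_specific)
    truth = IpTruth(true_ids, flag_specific, bioid_specific, params.bait_id)
    return flag, bioid, truth


# ---------------------------------------------------------------------------
# ranked expression
# ---------------------------------------------------------------------------

def simulate_ranked_expression(
    n_genes: int,
    planted_sets: Mapping[str, Sequence[str]] | None = None,
    effect: float = 2.0,
    seed: int = 0,
    planted_size: int = 20,
) -> Tuple[pd.Series, Dict[str, List[str]]]:
    """Ranking metric ~ N(0, 1) with planted sets shifted by ``effect``.

    If ``planted_sets`` is None a single set of ``planted_size`` genes is
    planted.  Returns (metric sorted descending, gene sets).
    """
    rng = np.random.default_rng(seed)
    universe = [f"GENE{i:05d}" for i in range(n_genes)]
    if planted_sets is None:
        chosen = rng.choice(n_genes, size=min(planted_size, n_genes), replace=False)
        planted_sets = {"PLANTED_SET": [universe[i] for i in sorted(chosen)]}
    sets: Dict[str, List[str]] = {}
    uni = set(universe)
    for name, members in planted_sets.items():
        inter = [g for g in members if g in uni]
        if not inter:
            raise ValueError(f"gene set {name!r} does not overlap the universe")
        sets[name] = inter

    metric = pd.Series(rng.normal(0.0, 1.0, size=n_genes), index=universe)
    for members in sets.values():
        metric[members] += effect
    metric = metric.sort_values(ascending=False, kind="mergesort")
    metric.name = "metric"
    metric.index.name = "gene"
    return metric, sets
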