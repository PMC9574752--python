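"""sgRNA library manifest: domain types, default catalog, and I/O.

The default library targets a fixed catalog of 98 deubiquitylase genes and
six essential-control genes with three guides per gene, plus 12 non-targeting
guides.  Spacer sequences are generated programmatically (deterministic,
collision-free) because only synthetic sequences are needed downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

CATEGORIES = ("dub", "essential_control", "non_targeting")
NON_TARGETING_GENE = "NT"
DEFAULT_SPACER_LENGTH = 20
DEFAULT_GUIDES_PER_GENE = 3
DEFAULT_N_NONTARGETING = 12
#: minimum pairwise Hamming distance between spacers; 3 keeps 1-mismatch
#: assignment unambiguous (2 * max_mismatches + 1 with max_mismatches = 1)
MIN_SPACER_DISTANCE = 3
_ALPHABET = "ACGT"


class LibraryError(ValueError):
    """Raised on invalid library construction or parsing."""


@dataclass(frozen=True)
class GuideRecord:
    guide_id: str
    gene: str
    category: str
    spacer: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LibraryError(
                f"unknown category {self.category!r} for guide {self.guide_id!r}; "
                f"expected one of {CATEGORIES}"
            )
        if not self.spacer or set(self.spacer) - set(_ALPHABET):
            raise LibraryError(
                f"spacer for guide {self.guide_id!r} must be non-empty ACGT, "
                f"got {self.spacer!r}"
            )
        if self.category == "non_targeting" and self.gene != NON_TARGETING_GENE:
            raise LibraryError(
                f"non-targeting guide {self.guide_id!r} must carry the reserved "
                f"gene label {NON_TARGETING_GENE!r}, got {self.gene!r}"
            )


@dataclass
class LibraryManifest:
    """Ordered collection of guide records with a uniform spacer length."""

    records: List[GuideRecord]
    spacer_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise LibraryError("manifest must contain at least one guide record")
        lengths = {len(r.spacer) for r in self.records}
        if len(lengths) != 1:
            raise LibraryError(f"spacer length must be constant, found {sorted(lengths)}")
        self.spacer_length = lengths.pop()
        seen_ids: Dict[str, str] = {}
        seen_spacers: Dict[str, str] = {}
        for r in self.records:
            if r.guide_id in seen_ids:
                raise LibraryError(f"duplicate guide_id {r.guide_id!r}")
            seen_ids[r.guide_id] = r.gene
            if r.spacer in seen_spacers:
                raise LibraryError(
                    f"duplicate spacer {r.spacer!r} shared by genes "
                    f"{seen_spacers[r.spacer]!r} and {r.gene!r}"
                )
            seen_spacers[r.spacer] = r.gene

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LibraryManifest) and self.records == other.records

    def category_counts(self) -> Dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for r in self.records:
            counts[r.category] += 1
        return counts

    def genes(self, category: str | None = None) -> List[str]:
        """Distinct gene symbols, in first-appearance order."""
        out: List[str] = []
        seen = set()
        for r in self.records:
            if category is not None and r.category != category:
                continue
            if r.gene not in seen:
                seen.add(r.gene)
                out.append(r.gene)
        return out

    def guides_per_gene(self) -> Dict[str, int]:
        """Guide count per targeted gene (non-targeting excluded)."""
        out: Dict[str, int] = {}
        for r in self.records:
            if r.category != "non_targeting":
                out[r.gene] = out.get(r.gene, 0) + 1
        return out

    def targeting_spacers(self) -> List[str]:
        return [r.spacer for r in self.records if r.category != "non_targeting"]

    def spacer_to_guide(self) -> Dict[str, str]:
        return {r.spacer: r.guide_id for r in self.records}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def generate_spacers(
    n: int,
    length: int = DEFAULT_SPACER_LENGTH,
    seed: int = 0,
    avoid: Sequence[str] = (),
    min_distance: int = MIN_SPACER_DISTANCE,
) -> List[str]:
    """Generate ``n`` random spacers pairwise >= ``min_distance`` apart
    (Hamming), also at least that far from every sequence in ``avoid``.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    accepted: List[str] = []
    reference = list(avoid)
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 1000 * (n + 1):
            raise LibraryError("spacer generation failed to satisfy distance constraint")
        cand = _random_spacer(rng, length)
        if all(_hamming(cand, s) >= min_distance for s in reference):
            accepted.append(cand)
            reference.append(cand)
    return accepted


def load_default_gene_lists() -> tuple[List[str], List[str]]:
    """Packaged (dub_genes, essential_control_genes) symbol lists."""
    pkg = resources.files("dubscreen.data")
    dubs = pkg.joinpath("dub_genes.txt").read_text().split()
    essentials = pkg.joinpath("essential_genes.txt").read_text().split()
    return dubs, essentials


def default_catalog(
    guides_per_gene: int = DEFAULT_GUIDES_PER_GENE,
    spacer_length: int = DEFAULT_SPACER_LENGTH,
    seed: int = 0,
) -> Dict[str, List[str]]:
    """gene -> spacer-list mapping for the default 98 + 6 gene catalog."""
    dubs, essentials = load_default_gene_lists()
    genes = dubs + essentials
    spacers = generate_spacers(len(genes) * guides_per_gene, spacer_length, seed=seed)
    it = iter(spacers)
    return {g: [next(it) for _ in range(guides_per_gene)] for g in genes}


def build_library(
    catalog: Mapping[str, Sequence[str]],
    n_nontargeting: int = DEFAULT_N_NONTARGETING,
    essential_genes: Iterable[str] = (),
    seed: int = 0,
) -> LibraryManifest:
    """Build a manifest from a gene -> spacers catalog plus generated
    non-targeting spacers.

    Genes listed in ``essential_genes`` are categorised ``essential_control``;
    all other catalog genes are ``dub``.  Non-targeting spacers are generated
    deterministically from ``seed`` and rejected if within Hamming distance
    ``MIN_SPACER_DISTANCE - 1`` of any targeting spacer.
    """
    if not catalog:
        raise LibraryError("catalog must not be empty")
    essential = set(essential_genes)
    declared = {len(v) for v in catalog.values()}
    if len(declared) != 1:
        raise LibraryError(
            f"every gene must have the same number of guides, found counts {sorted(declared)}"
        )
    lengths = {len(s) for v in catalog.values() for s in v}
    if len(lengths) != 1:
        raise LibraryError(f"spacers must have uniform length, found {sorted(lengths)}")
    spacer_length = lengths.pop()

    seen: Dict[str, str] = {}
    records: List[GuideRecord] = []
    for gene, spacers in catalog.items():
        for i, spacer in enumerate(spacers, start=1):
            if spacer in seen:
                raise LibraryError(
                    f"spacer {spacer!r} assigned to both {seen[spacer]!r} and {gene!r}"
                )
            seen[spacer] = gene
            category = "essential_control" if gene in essential else "dub"
            records.append(GuideRecord(f"{gene}_sg{i}", gene, category, spacer))

    nt_spacers = generate_spacers(
        n_nontargeting, spacer_length, seed=seed, avoid=list(seen)
    )
    for i, spacer in enumerate(nt_spacers, start=1):
        records.append(
            GuideRecord(f"{NON_TARGETING_GENE}_sg{i}", NON_TARGETING_GENE,
                        "non_targeting", spacer)
        )
    return LibraryManifest(records)


def build_default_library(
    catalog: Mapping[str, Sequence[str]] | None = None,
    n_nontargeting: int = DEFAULT_N_NONTARGETING,
    seed: int = 0,
) -> LibraryManifest:
    """Default library: 98 DUB genes x3, 6 essential controls x3, 12
    non-targeting guides, all spacers synthetic and collision-free.
    """
    if catalog is None:
        catalog = default_catalog(seed=seed)
    _, essentials = load_default_gene_lists()
    return build_library(
        catalog, n_nontargeting=n_nontargeting, essential_genes=essentials, seed=seed + 1
    )


MANIFEST_COLUMNS = ["guide_id", "gene", "category", "spacer"]


def write_manifest(manifest: LibraryManifest, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in manifest.records:
            writer.writerow([r.guide_id, r.gene, r.category, r.spacer])


def read_manifest(path) -> LibraryManifest:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LibraryError(f"{path}: empty manifest file") from None
        if header != MANIFEST_COLUMNS:
            raise LibraryError(
                f"{path}: expected header {','.join(MANIFEST_COLUMNS)}, got {','.join(header)}"
            )
        records = [GuideRecord(*row) for row in reader if row]
    return LibraryManifest(records)


def write_spacer_fasta(manifest: LibraryManifest, path) -> None:
    """One FASTA record per guide; header = guide_id, sequence = spacer."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in manifest.records:
            fh.write(f">{r.guide_id}\n{r.spacer}\n")
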