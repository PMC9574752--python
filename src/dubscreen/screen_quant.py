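"""Guide counting from screen FASTQ files and count-table QC.

Counting is alignment-free: the spacer is extracted at a fixed offset behind
a 5' anchor and looked up in a hash of manifest spacers (exact) or of their
1-mismatch neighborhoods.  A read at minimal distance to two or more spacers
is never assigned.  This requires manifest spacers to be pairwise at Hamming
distance >= 2*max_mismatches + 1, which is checked up front.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_model import LibraryManifest, _hamming

TIMEPOINTS = ("T0", "T14")
#: default 5' scaffold shared with the FASTQ simulator
DEFAULT_ANCHOR = "ACCTGTTG"
_ALPHABET = "ACGT"


class FastqFormatError(ValueError):
    """Malformed FASTQ input; message carries the record number."""


class MatcherError(ValueError):
    """Manifest violates the spacer-separation precondition."""


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    timepoint: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )


@dataclass
class GuideCountTable:
    """Nonnegative integer guide x sample counts with sample metadata.

    ``counts`` is indexed by guide_id with one column per sample_id;
    ``unassigned`` holds, per sample, the number of reads that could not be
    assigned to any guide (so assigned + unassigned = reads processed).
    """

    counts: pd.DataFrame
    samples: List[SampleInfo]
    unassigned: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample metadata")
        if list(self.counts.columns) != ids:
            raise ValueError("count columns must match sample metadata order")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise ValueError("counts must be integers")
        for s in ids:
            self.unassigned.setdefault(s, 0)

    def sample_ids(self, timepoint: str | None = None) -> List[str]:
        return [
            s.sample_id
            for s in self.samples
            if timepoint is None or s.timepoint == timepoint
        ]


def check_spacer_separation(spacers: Sequence[str], min_distance: int) -> None:
    """Error if any spacer pair is closer than ``min_distance`` (Hamming)."""
    for a, b in itertools.combinations(spacers, 2):
        if _hamming(a, b) < min_distance:
            raise MatcherError(
                f"spacers {a!r} and {b!r} are at Hamming distance "
                f"{_hamming(a, b)} < required {min_distance}"
            )


def _neighbors(spacer: str) -> Iterable[str]:
    """All sequences at Hamming distance exactly 1."""
    for i, base in enumerate(spacer):
        for sub in _ALPHABET:
            if sub != base:
                yield spacer[:i] + sub + spacer[i + 1 :]


def _build_lookup(
    manifest: LibraryManifest, max_mismatches: int
) -> Dict[str, str]:
    lookup = dict(manifest.spacer_to_guide())
    if max_mismatches == 1:
        for r in manifest.records:
            for nb in _neighbors(r.spacer):
                # separation >= 3 guarantees neighborhoods are disjoint and
                # never collide with another exact spacer
                lookup[nb] = r.guide_id
    return lookup


def iter_fastq(path) -> Iterable[Tuple[str, str]]:
    """Yield (read_id, sequence); re-raise parse errors with record numbers."""
    n = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {n + 1}: {exc}"
                ) from exc
            n += 1
            yield title, seq


def count_guides(
    fastq_by_sample: Mapping[str, Sequence] | Mapping[str, str],
    manifest: LibraryManifest,
    samples: Sequence[SampleInfo] | None = None,
    max_mismatches: int = 1,
    anchor: str = DEFAULT_ANCHOR,
    anchor_offset: int = 0,
) -> GuideCountTable:
    """Count spacer occurrences per sample.

    Parameters
    ----------
    fastq_by_sample
        sample_id -> FASTQ path or list of paths.
    samples
        Sample metadata; if omitted, timepoints are parsed from sample ids
        of the form ``<T0|T14>_r<replicate>``.
    max_mismatches
        0 for exact matching only, 1 to additionally accept unique
        1-mismatch hits.
    anchor
        Fixed 5' scaffold expected at ``anchor_offset``; reads whose anchor
        does not match exactly are unassigned.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    check_spacer_separation(
        [r.spacer for r in manifest.records], 2 * max_mismatches + 1
    )
    lookup = _build_lookup(manifest, max_mismatches)
    guide_ids = [r.guide_id for r in manifest.records]
    spacer_len = manifest.spacer_length
    start = anchor_offset + len(anchor)

    if samples is None:
        samples = [_parse_sample_id(sid) for sid in fastq_by_sample]
    sample_order = [s.sample_id for s in samples]

    counts = pd.DataFrame(0, index=guide_ids, columns=sample_order, dtype=np.int64)
    unassigned: Dict[str, int] = {}
    for sample_id in sample_order:
        paths = fastq_by_sample[sample_id]
        if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
            paths = [paths]
        col = counts[sample_id].to_dict()
        miss = 0
        for path in paths:
            for _, seq in iter_fastq(path):
                if len(seq) < start + spacer_len:
                    raise FastqFormatError(
                        f"{path}: read shorter than anchor + spacer "
                        f"({len(seq)} < {start + spacer_len})"
                    )
                if seq[anchor_offset:start] != anchor:
                    miss += 1
                    continue
                guide = lookup.get(seq[start : start + spacer_len])
                if guide is None:
                    miss += 1
                else:
                    col[guide] += 1
        counts[sample_id] = pd.Series(col)
        unassigned[sample_id] = miss
    return GuideCountTable(counts=counts, samples=list(samples), unassigned=unassigned)


def _parse_sample_id(sample_id: str) -> SampleInfo:
    tp, _, rep = sample_id.partition("_r")
    return SampleInfo(sample_id, tp, int(rep) if rep else 1)


def gini_coefficient(values: np.ndarray) -> float:
    """Gini of a nonnegative vector (0 = uniform, ->1 fully concentrated)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    total = x.sum()
    if n == 0 or total == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * total))


@dataclass
class ScreenQcReport:
    mapping_rate: Dict[str, float]
    zero_fraction: Dict[str, float]
    gini: Dict[str, float]
    total_reads: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mapping_rate": self.mapping_rate,
                "zero_fraction": self.zero_fraction,
                "gini": self.gini,
                "total_reads": self.total_reads,
            }
        ).rename_axis("sample_id")


def write_counts_tsv(table: GuideCountTable, path) -> None:
    """Wide TSV (guide_id + one column per sample); unassigned totals go in
    ``# unassigned`` comment lines so the table round-trips exactly."""
    with open(path, "w") as fh:
        for s in table.samples:
            fh.write(
                f"# sample\t{s.sample_id}\t{s.timepoint}\t{s.replicate}"
                f"\t{table.unassigned.get(s.sample_id, 0)}\n"
            )
        table.counts.rename_axis("guide_id").to_csv(fh, sep="\t")


def read_counts_tsv(path) -> GuideCountTable:
    samples: List[SampleInfo] = []
    unassigned: Dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("# sample\t"):
            break
        _, sid, tp, rep, miss = line.rstrip("\n").split("\t")
        samples.append(SampleInfo(sid, tp, int(rep)))
        unassigned[sid] = int(miss)
        body_start += 1
    from io import StringIO

    counts = pd.read_csv(
        StringIO("".join(lines[body_start:])), sep="\t", index_col="guide_id"
    )
    if not samples:
        samples = [_parse_sample_id(c) for c in counts.columns]
    return GuideCountTable(
        counts=counts.astype(np.int64), samples=samples, unassigned=unassigned
    )


def screen_qc(table: GuideCountTable) -> ScreenQcReport:
    if not table.samples:
        raise ValueError("count table has no samples")
    mapping_rate, zero_fraction, gini, totals = {}, {}, {}, {}
    for s in table.sample_ids():
        col = table.counts[s].to_numpy()
        assigned = int(col.sum())
        total = assigned + table.unassigned.get(s, 0)
        totals[s] = total
        mapping_rate[s] = assigned / total if total else 0.0
        zero_fraction[s] = float((col == 0).mean())
        gini[s] = gini_coefficient(col)
    return ScreenQcReport(mapping_rate, zero_fraction, gini, totals)
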