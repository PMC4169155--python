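"""Population alignment I/O, quality masking and per-site classification.

The pipeline starts from haploid consensus sequences (one record per strain)
aligned to a common coordinate system, plus a single outgroup sequence.  This
module reads those alignments, applies the two quality-control rules used
throughout the analyses — per-base PHRED masking and exclusion of sites with
too much missing data — and exposes coordinate-aware site and window
iteration for the downstream statistics.

Conventions (fixed across the package):

* coordinates are 1-based inclusive; column ``j`` of an alignment starting at
  ``start_coord`` maps to chromosome position ``start_coord + j``;
* gap characters ``-`` are treated as missing (``N``);
* the missing-data exclusion is applied to the pooled analysis sample;
* multiallelic sites are excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
MISSING = "N"


class AlignmentError(ValueError):
    """Raised when records cannot form a rectangular alignment."""


class InputError(ValueError):
    """Raised on empty or malformed input files."""


@dataclass
class AlignedSampleSet:
    """Haploid sequence matrix with population labels and coordinates.

    ``seq_matrix`` holds single characters in {A, C, G, T, N, -} with one row
    per haploid sample.  ``population`` may be a single label applied to all
    rows or one label per row.  ``quality`` is an optional PHRED integer
    matrix congruent with ``seq_matrix``.
    """

    sample_ids: list[str]
    population: list[str]
    seq_matrix: np.ndarray
    start_coord: int = 1
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.seq_matrix = np.asarray(self.seq_matrix, dtype="<U1")
        if self.seq_matrix.ndim != 2:
            raise AlignmentError("seq_matrix must be 2-dimensional")
        if len(self.sample_ids) != self.seq_matrix.shape[0]:
            raise AlignmentError("one sample id required per row")
        if isinstance(self.population, str):
            self.population = [self.population] * len(self.sample_ids)
        if len(self.population) != len(self.sample_ids):
            raise AlignmentError("one population label required per row")
        if self.start_coord < 1:
            raise ValueError("start_coord must be >= 1 (1-based coordinates)")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=int)
            if self.quality.shape != self.seq_matrix.shape:
                raise AlignmentError("quality shape must equal seq_matrix shape")

    @property
    def n_samples(self) -> int:
        return self.seq_matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.seq_matrix.shape[1]

    @property
    def end_coord(self) -> int:
        return self.start_coord + self.n_sites - 1

    def column(self, coord: int) -> np.ndarray:
        j = coord - self.start_coord
        if j < 0 or j >= self.n_sites:
            raise IndexError(f"coordinate {coord} outside alignment span")
        return self.seq_matrix[:, j]

    def concat_rows(self, other: "AlignedSampleSet") -> "AlignedSampleSet":
        """Stack two sample sets sharing the same coordinate span."""
        if other.start_coord != self.start_coord or other.n_sites != self.n_sites:
            raise AlignmentError("sample sets must share the same coordinate span")
        qual = None
        if self.quality is not None and other.quality is not None:
            qual = np.vstack([self.quality, other.quality])
        return AlignedSampleSet(
            sample_ids=self.sample_ids + other.sample_ids,
            population=list(self.population) + list(other.population),
            seq_matrix=np.vstack([self.seq_matrix, other.seq_matrix]),
            start_coord=self.start_coord,
            quality=qual,
        )


@dataclass
class OutgroupSequence:
    """Single outgroup sequence aligned to the same columns."""

    seq: str
    label: str = "outgroup"

    def __post_init__(self) -> None:
        self.seq = _normalize(self.seq)

    def base(self, coord: int, start_coord: int) -> str:
        j = coord - start_coord
        if j < 0 or j >= len(self.seq):
            raise IndexError(f"coordinate {coord} outside outgroup span")
        return self.seq[j]


@dataclass
class SiteFilterConfig:
    """Quality-control thresholds applied before any statistic.

    ``min_phred`` masks individual base calls; ``max_missing_frac`` excludes
    whole sites whose pooled fraction of N calls is strictly above the
    threshold; ``excluded_regions`` are closed 1-based intervals (e.g. the
    low-recombination telomere and centromere) removed from scans.
    """

    min_phred: int = 21
    max_missing_frac: float = 0.10
    excluded_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must lie in [0, 1]")

    def in_excluded_region(self, coord: int) -> bool:
        return any(lo <= coord <= hi for lo, hi in self.excluded_regions)


@dataclass
class SiteRecord:
    """Classified alignment column with per-population allele counts."""

    coord: int
    allele_counts: dict[str, dict[str, int]]
    n_valid: dict[str, int]
    outgroup_base: str
    status: str  # monomorphic | biallelic | multiallelic | excluded

    @property
    def pooled_counts(self) -> dict[str, int]:
        pooled: dict[str, int] = {}
        for counts in self.allele_counts.values():
            for base, c in counts.items():
                pooled[base] = pooled.get(base, 0) + c
        return pooled

    @property
    def alleles(self) -> list[str]:
        """Distinct bases observed in the pooled sample, most common first."""
        pooled = self.pooled_counts
        return sorted(pooled, key=lambda b: (-pooled[b], b))


def _normalize(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in VALID_BASES:
            out.append(ch)
        elif ch == "-":
            out.append("-")
        else:
            out.append(MISSING)
    return "".join(out)


def read_population_fasta(path, population: str, start_coord: int = 1) -> AlignedSampleSet:
    """Read a multi-FASTA of equal-length haploid consensus sequences.

    Headers become sample ids; characters are upper-cased and anything
    outside {A, C, G, T, -} is mapped to N.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal record lengths in {path}: {sorted(lengths)}")
    matrix = np.array([list(_normalize(str(r.seq))) for r in records], dtype="<U1")
    return AlignedSampleSet(
        sample_ids=[r.id for r in records],
        population=[population] * len(records),
        seq_matrix=matrix,
        start_coord=start_coord,
    )


def read_outgroup_fasta(path, label: str | None = None) -> OutgroupSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return OutgroupSequence(seq=str(records[0].seq), label=label or records[0].id)


def read_phred_matrix(path) -> np.ndarray:
    """Read a whitespace-separated integer PHRED matrix (rows = samples)."""
    matrix = np.loadtxt(str(path), dtype=int, ndmin=2)
    return matrix


def read_fastq_quality(path) -> np.ndarray:
    """Per-base PHRED scores from a FASTQ file (rows = records)."""
    records = list(SeqIO.parse(str(path), "fastq"))
    if not records:
        raise InputError(f"no FASTQ records in {path}")
    quals = [r.letter_annotations["phred_quality"] for r in records]
    if len({len(q) for q in quals}) != 1:
        raise AlignmentError("FASTQ records have unequal lengths")
    return np.array(quals, dtype=int)


def write_fasta(aln: AlignedSampleSet, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.sample_ids, aln.seq_matrix):
            fh.write(f">{sid}\n{''.join(row)}\n")


def apply_quality_mask(aln: AlignedSampleSet, cfg: SiteFilterConfig) -> AlignedSampleSet:
    """Set every cell with PHRED below ``cfg.min_phred`` to N (idempotent)."""
    if aln.quality is None:
        raise ValueError("apply_quality_mask requires a quality track")
    masked = aln.seq_matrix.copy()
    masked[aln.quality < cfg.min_phred] = MISSING
    return replace(aln, seq_matrix=masked)


def classify_site(
    aln: AlignedSampleSet,
    outgroup: OutgroupSequence | None,
    coord: int,
    cfg: SiteFilterConfig,
) -> SiteRecord:
    """Classify one alignment column, applying the missing-data exclusion.

    A site is ``excluded`` when the pooled fraction of N calls is strictly
    above ``cfg.max_missing_frac`` or the coordinate falls in an excluded
    region; otherwise the status reflects the number of distinct non-N bases.
    Gap characters count as N.
    """
    column = aln.column(coord)
    pops = np.asarray(aln.population)
    allele_counts: dict[str, dict[str, int]] = {}
    n_valid: dict[str, int] = {}
    n_missing = 0
    for pop in dict.fromkeys(aln.population):
        sub = column[pops == pop]
        counts: dict[str, int] = {}
        valid = 0
        for ch in sub:
            if ch in VALID_BASES:
                counts[ch] = counts.get(ch, 0) + 1
                valid += 1
            else:
                n_missing += 1
        allele_counts[pop] = counts
        n_valid[pop] = valid
    out_base = outgroup.base(coord, aln.start_coord) if outgroup is not None else MISSING
    if out_base == "-":
        out_base = MISSING

    total = aln.n_samples
    if cfg.in_excluded_region(coord) or (total > 0 and n_missing / total > cfg.max_missing_frac):
        status = "excluded"
    else:
        distinct = {b for counts in allele_counts.values() for b in counts}
        if len(distinct) <= 1:
            status = "monomorphic"
        elif len(distinct) == 2:
            status = "biallelic"
        else:
            status = "multiallelic"
    return SiteRecord(
        coord=coord,
        allele_counts=allele_counts,
        n_valid=n_valid,
        outgroup_base=out_base,
        status=status,
    )


def site_table(
    aln: AlignedSampleSet,
    outgroup: OutgroupSequence | None,
    cfg: SiteFilterConfig,
) -> list[SiteRecord]:
    """Classify every column of the alignment (mask -> classify -> filter)."""
    return [
        classify_site(aln, outgroup, coord, cfg)
        for coord in range(aln.start_coord, aln.end_coord + 1)
    ]


@dataclass(frozen=True)
class WindowInterval:
    """Closed 1-based window [start, end]; ``partial`` marks a short tail."""

    start: int
    end: int
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, coord: int) -> bool:
        return self.start <= coord <= self.end


def iter_windows(aln: AlignedSampleSet, window_len: int) -> Iterator[WindowInterval]:
    """Consecutive non-overlapping windows over the alignment span."""
    yield from iter_windows_span(aln.start_coord, aln.end_coord, window_len)


def iter_windows_span(start: int, end: int, window_len: int) -> Iterator[WindowInterval]:
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    pos = start
    while pos <= end:
        w_end = min(pos + window_len - 1, end)
        yield WindowInterval(pos, w_end, partial=(w_end - pos + 1) < window_len)
        pos = w_end + 1


def read_ms_replicates(text: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parse ms-format text into (positions, 0/1 matrix) replicates.

    Positions are returned on the simulator's relative scale (whatever the
    writer used); matrices have one row per haplotype.
    """
    replicates: list[tuple[np.ndarray, np.ndarray]] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() == "//":
            i += 1
            segsites = int(lines[i].split()[1])
            i += 1
            if segsites == 0:
                replicates.append((np.empty(0), np.empty((0, 0), dtype=np.int8)))
                continue
            positions = np.array([float(x) for x in lines[i].split()[1:]])
            i += 1
            haps = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("//"):
                haps.append([int(c) for c in lines[i].strip()])
                i += 1
            replicates.append((positions, np.array(haps, dtype=np.int8)))
        else:
            i += 1
    return replicates


def haplotypes_to_alignment(
    matrix: np.ndarray,
    population: str,
    start_coord: int = 1,
    zero_base: str = "A",
    one_base: str = "G",
    sample_prefix: str = "sim",
) -> AlignedSampleSet:
    """Map a 0/1 haplotype matrix onto two arbitrary bases."""
    matrix = np.asarray(matrix)
    chars = np.where(matrix == 0, zero_base, one_base).astype("<U1")
    ids = [f"{sample_prefix}{k}" for k in range(matrix.shape[0])]
    return AlignedSampleSet(ids, [population] * len(ids), chars, start_coord=start_coord)


def write_site_table(records: Sequence[SiteRecord], path) -> None:
    """Write classified sites as tab-separated text (one row per site)."""
    pops = list(records[0].allele_counts) if records else []
    with open(path, "w") as fh:
        header = ["coord", "status", "outgroup"]
        for pop in pops:
            header += [f"{pop}_counts", f"{pop}_n_valid"]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            row = [str(rec.coord), rec.status, rec.outgroup_base]
            for pop in pops:
                counts = ",".join(f"{b}:{c}" for b, c in sorted(rec.allele_counts[pop].items()))
                row += [counts or ".", str(rec.n_valid[pop])]
            fh.write("\t".join(row) + "\n")
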