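"""Per-position read coverage of junctions and retained introns.

A spliced read supports a junction at the read offset where the split
occurs, so a junction of a sample is summarised as a vector of counts over
the ``L - 1`` possible split positions of a read of nominal length ``L``.
Introns are handled analogously by treating the exon/intron boundary as a
zero-length junction: reads covering the intron start contribute junction
like positions, reads starting inside the intron contribute one raw position
per genomic offset, and the raw vector is then aggregated down to ``L - 1``
near-equal bins (bin value = mean of its raw members) so that junctions and
introns share one coverage model.

Positions with outlier counts (read stacks) are masked with a Poisson
right-tail test; measurement error of the total read rate is modelled by
bootstrap resampling over the unmasked positions, falling back to Poisson
sampling when the positions are underdispersed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 100
DEFAULT_ALPHA = 1e-7
DEFAULT_BOOTSTRAPS = 30

SJ_FORMAT_VERSION = 1


class SJFormatError(ValueError):
    pass


@dataclass
class EdgeCoverage:
    """Read counts per possible position for one junction/intron, one sample."""

    edge_ref: tuple  # ("J"|"I", chrom, strand, start, end)
    position_counts: np.ndarray
    mask: np.ndarray | None = None  # True = excluded

    def __post_init__(self) -> None:
        self.position_counts = np.asarray(self.position_counts, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(len(self.position_counts), dtype=bool)

    @property
    def num_positions(self) -> int:
        return len(self.position_counts)

    @property
    def unmasked_counts(self) -> np.ndarray:
        return self.position_counts[~self.mask]

    @property
    def total_reads(self) -> float:
        """Raw total over all positions (pre-mask), used for build thresholds."""
        return float(self.position_counts.sum())

    @property
    def nonzero_positions(self) -> int:
        return int(np.count_nonzero(self.position_counts))


@dataclass
class BootstrapCoverage:
    edge_ref: tuple
    replicates: np.ndarray
    seed: int

    @property
    def M(self) -> int:
        return len(self.replicates)


# ---------------------------------------------------------------------------
# Alignment parsing (pysam AlignedSegment streams)
# ---------------------------------------------------------------------------

_QUERY_OPS = {0, 1, 4, 7, 8}   # M, I, S, =, X consume query
_REF_OPS = {0, 2, 3, 7, 8}     # M, D, N, =, X consume reference


def read_splits(read) -> list[tuple[int, int, int]]:
    """(genomic_start, genomic_end, query_offset) for each N gap of a read."""
    out = []
    gpos = read.reference_start
    qpos = 0
    for op, length in read.cigartuples or []:
        if op == 3:  # N
            out.append((gpos, gpos + length, qpos))
        if op in _QUERY_OPS:
            qpos += length
        if op in _REF_OPS:
            gpos += length
    return out


def junction_coverage(alignments, junction: tuple[int, int],
                      read_length: int = DEFAULT_READ_LENGTH,
                      chrom: str = "", strand: str = ".") -> EdgeCoverage:
    """Count reads supporting one junction per split position.

    A read whose alignment is split at genomic interval ``junction`` with
    ``p`` query bases before the split contributes to position ``p`` (1-based,
    valid range ``1..L-1``).  Longer reads are clipped to the valid range with
    a warning; ``num_positions`` always comes from the nominal read length.
    """
    counts = np.zeros(read_length - 1)
    start, end = junction
    for read in alignments:
        for gstart, gend, qoff in read_splits(read):
            if gstart == start and gend == end:
                if 1 <= qoff <= read_length - 1:
                    counts[qoff - 1] += 1
                else:
                    warnings.warn(
                        f"split offset {qoff} outside 1..{read_length - 1}; clipped"
                    )
                    counts[min(max(qoff, 1), read_length - 1) - 1] += 1
    return EdgeCoverage(("J", chrom, strand, start, end), counts)


def intron_raw_coverage(alignments, intron: tuple[int, int],
                        read_length: int = DEFAULT_READ_LENGTH,
                        chrom: str = "", strand: str = ".") -> EdgeCoverage:
    """Raw (unaggregated) per-position coverage of one retained intron.

    Raw positions are the ``L - 1`` junction-like placements over the intron
    start followed by one position per genomic offset ``1..intron_length``
    for reads starting inside the intron.  Only reads intersecting the
    intron contiguously (no split within the intron boundaries) count.
    """
    start, end = intron
    ilen = end - start
    raw = np.zeros(read_length - 1 + ilen)
    for read in alignments:
        if any(gs < end and ge > start
               for gs, ge, _ in read_splits(read)):
            continue  # spliced across/inside the intron
        rs, re = read.reference_start, read.reference_end
        if rs is None or re is None or re <= start or rs >= end:
            continue
        if rs < start:
            p = start - rs
            if 1 <= p <= read_length - 1:
                raw[p - 1] += 1
        else:
            off = rs - start + 1  # 1..intron_length
            if off <= ilen:
                raw[read_length - 2 + off] += 1
    return EdgeCoverage(("I", chrom, strand, start, end), raw)


def reduce_intron(raw: EdgeCoverage, read_length: int = DEFAULT_READ_LENGTH) -> EdgeCoverage:
    """Aggregate raw intron positions into ``L - 1`` near-equal bins.

    Adjacent raw positions are partitioned into contiguous bins whose sizes
    differ by at most one; each bin carries the mean of its members, which
    preserves mean coverage.  If fewer raw positions than bins exist the raw
    vector is returned unchanged.
    """
    nbins = read_length - 1
    if len(raw.position_counts) <= nbins:
        return raw
    chunks = np.array_split(raw.position_counts, nbins)
    reduced = np.array([c.mean() for c in chunks])
    return EdgeCoverage(raw.edge_ref, reduced)


# ---------------------------------------------------------------------------
# Outlier masking and bootstrap
# ---------------------------------------------------------------------------

def mask_outliers(cov: EdgeCoverage, alpha: float = DEFAULT_ALPHA) -> EdgeCoverage:
    """Mask zero-coverage positions and Poisson right-tail outliers.

    Per-position read rates are approximately Poisson; for each nonzero
    position the rate is estimated from the *other* nonzero positions and the
    position is masked when ``P(X >= count) < alpha``.  All decisions are
    made simultaneously in one pass over the original counts.
    """
    c = cov.position_counts
    mask = c == 0
    nz = np.flatnonzero(c > 0)
    if len(nz) >= 2 and alpha > 0:
        total_nz = c[nz].sum()
        lam = (total_nz - c[nz]) / (len(nz) - 1)
        # right tail P(X >= c_i), decided simultaneously for all positions
        tail = stats.poisson.sf(c[nz] - 1, lam)
        mask[nz[tail < alpha]] = True
    return EdgeCoverage(cov.edge_ref, c, mask=mask)


def bootstrap_rates(cov: EdgeCoverage, M: int = DEFAULT_BOOTSTRAPS,
                    seed: int = 0) -> BootstrapCoverage:
    """Bootstrap replicates of the total read rate over unmasked positions.

    Nonparametric: each replicate is the sum of ``n`` draws with replacement
    from the unmasked position counts (already on the total-rate scale).
    When the unbiased sample variance falls below the sample mean
    (underdispersed relative to Poisson), replicates are drawn as
    ``Poisson(total rate)`` instead.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    c = cov.unmasked_counts
    n = len(c)
    if n == 0:
        return BootstrapCoverage(cov.edge_ref, np.zeros(M), seed)
    total = c.sum()
    mean = total / n
    var = float(c.var(ddof=1)) if n > 1 else 0.0
    if var < mean:
        reps = rng.poisson(total, size=M).astype(float)
    else:
        draws = rng.choice(c, size=(M, n), replace=True)
        reps = draws.sum(axis=1)
    return BootstrapCoverage(cov.edge_ref, reps, seed)


# ---------------------------------------------------------------------------
# SJ interchange file (versioned text container)
# ---------------------------------------------------------------------------

@dataclass
class SJFile:
    """Raw (pre-mask) junction/intron coverage of one experiment.

    Records are keyed by ``(kind, chrom, strand, start, end)`` with kind
    ``"J"`` (junction; vector length ``L - 1``) or ``"I"`` (intron; raw
    vector length ``L - 1 + intron_length``).  Building a splicegraph from
    an SJ file is bit-identical to building from the alignments it came from.
    """

    experiment: str
    read_length: int = DEFAULT_READ_LENGTH
    records: dict[tuple, np.ndarray] = field(default_factory=dict)

    def add(self, cov: EdgeCoverage) -> None:
        self.records[cov.edge_ref] = cov.position_counts

    def get(self, key: tuple) -> EdgeCoverage | None:
        if key in self.records:
            return EdgeCoverage(key, self.records[key])
        return None


def write_sj(sj: SJFile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#lsvkit-sj\t{SJ_FORMAT_VERSION}\n")
        fh.write(f"#experiment\t{sj.experiment}\n")
        fh.write(f"#read_length\t{sj.read_length}\n")
        keys = sorted(sj.records)
        for kind, chrom, strand, start, end in keys:
            counts = sj.records[(kind, chrom, strand, start, end)]
            txt = ",".join(repr(float(x)) for x in counts)
            fh.write(f"{kind}\t{chrom}\t{strand}\t{start}\t{end}\t{txt}\n")
        fh.write(f"#end\t{len(keys)}\n")


def read_sj(path: str) -> SJFile:
    """Read an SJ container; truncated or version-mismatched files raise."""
    sj = SJFile(experiment="", read_length=DEFAULT_READ_LENGTH)
    n = 0
    terminated = False
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 or header[0] != "#lsvkit-sj":
            raise SJFormatError(f"{path}: not an lsvkit SJ file")
        version = int(header[1])
        if version != SJ_FORMAT_VERSION:
            raise SJFormatError(
                f"{path}: SJ version {version}, expected {SJ_FORMAT_VERSION}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#end"):
                declared = int(line.split("\t")[1])
                if declared != n:
                    raise SJFormatError(
                        f"{path}: record count {n} != declared {declared}"
                    )
                terminated = True
                break
            if line.startswith("#experiment"):
                sj.experiment = line.split("\t", 1)[1]
                continue
            if line.startswith("#read_length"):
                sj.read_length = int(line.split("\t", 1)[1])
                continue
            try:
                kind, chrom, strand, start, end, counts = line.split("\t")
                sj.records[(kind, chrom, strand, int(start), int(end))] = (
                    np.array([float(x) for x in counts.split(",")])
                )
            except ValueError as exc:
                raise SJFormatError(f"{path}: malformed SJ record: {exc}") from exc
            n += 1
    if not terminated:
        raise SJFormatError(f"{path}: truncated SJ file (missing #end)")
    return sj


def sj_from_alignments(sam_path: str, read_length: int = DEFAULT_READ_LENGTH,
                       experiment: str = "",
                       intron_intervals: dict[str, list[tuple[int, int]]] | None = None,
                       ) -> SJFile:
    """Extract an SJ container from a SAM/BAM file in one pass.

    Junctions are discovered from split alignments.  Intron coverage is
    collected for the candidate intervals in ``intron_intervals`` (per
    chromosome), normally the inter-exon gaps of annotated genes plus any
    user-supplied candidates.
    """
    import pysam

    sj = SJFile(experiment=experiment or sam_path, read_length=read_length)
    jc: dict[tuple, np.ndarray] = {}
    ic: dict[tuple, np.ndarray] = {}
    if intron_intervals:
        for chrom, ivals in intron_intervals.items():
            for s, e in ivals:
                ic[("I", chrom, ".", s, e)] = np.zeros(read_length - 1 + (e - s))

    with pysam.AlignmentFile(sam_path, "r") as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                continue
            chrom = read.reference_name
            splits = read_splits(read)
            for gs, ge, qoff in splits:
                key = ("J", chrom, ".", gs, ge)
                if key not in jc:
                    jc[key] = np.zeros(read_length - 1)
                p = min(max(qoff, 1), read_length - 1)
                jc[key][p - 1] += 1
            for key, raw in ic.items():
                _, ichrom, _, s, e = key
                if ichrom != chrom:
                    continue
                if any(gs < e and ge > s for gs, ge, _ in splits):
                    continue
                rs, re = read.reference_start, read.reference_end
                if re <= s or rs >= e:
                    continue
                if rs < s:
                    p = s - rs
                    if 1 <= p <= read_length - 1:
                        raw[p - 1] += 1
                else:
                    off = rs - s + 1
                    if off <= e - s:
                        raw[read_length - 2 + off] += 1
    sj.records.update(jc)
    sj.records.update(ic)
    return sj
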