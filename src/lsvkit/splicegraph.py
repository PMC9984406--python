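"""Gene splicegraphs: exons as vertices, junctions and retained introns as edges.

A splicegraph encodes every splicing decision of a gene that is consistent
with the transcript annotation and the observed RNA-seq evidence.  Exons of a
gene are pairwise non-overlapping, sorted genomic intervals; each junction
connects a donor position inside one exon to an acceptor position inside
another; a retained intron spans the gap between two adjacent exons.

Local splicing variations (LSVs) are splits in this graph: the set of edges
leaving (source) or entering (target) a reference exon.  Only splits with at
least two non-simplified edges are quantified.

Coordinates are 0-based half-open on the forward genomic strand throughout;
GFF3 input (1-based inclusive) is converted at the parsing boundary.  A
junction's ``start`` is the half-open end of its donor exon (first intronic
base) and its ``end`` is the start of its acceptor exon, so the junction
interval is exactly the intron it removes.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: window (bp) used both for tier-2 gene assignment of de novo junctions and
#: as the cap on extension of an annotated exon boundary.
NEARBY_WINDOW = 400


class AnnotationError(ValueError):
    """Malformed annotation hierarchy; the message names the offending record."""


@dataclass
class Exon:
    start: int
    end: int
    annotated: bool = True
    denovo_extended: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance(self, pos: int) -> int:
        """Distance from ``pos`` to this interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass
class Junction:
    start: int
    end: int
    annotated: bool = True
    simplified: bool = False
    passed: bool = False  # met the evidence thresholds in some build group

    @property
    def key(self) -> tuple:
        return ("J", self.start, self.end)

    @property
    def is_intron(self) -> bool:
        return False


@dataclass
class RetainedIntron:
    start: int
    end: int
    annotated: bool = True
    simplified: bool = False
    passed: bool = False
    #: interval of the original (pre-split) intron whose coverage this
    #: fragment inherits; equals (start, end) when never split.
    source: tuple | None = None

    @property
    def key(self) -> tuple:
        return ("I", self.start, self.end)

    @property
    def is_intron(self) -> bool:
        return True


Edge = Junction | RetainedIntron


@dataclass
class BuildGroup:
    """A user-defined group of experiments used for evidence thresholds."""

    name: str
    experiments: list[str]
    min_experiments: int = 0

    def __post_init__(self) -> None:
        if self.min_experiments <= 0:
            self.min_experiments = math.ceil(0.5 * len(self.experiments))
        if self.min_experiments > len(self.experiments):
            raise ValueError(
                f"min_experiments {self.min_experiments} exceeds group size "
                f"{len(self.experiments)} for group {self.name!r}"
            )


@dataclass
class BuildThresholds:
    """Evidence thresholds for incorporating and flagging graph edges.

    De novo elements require stronger evidence than annotated ones: an
    unannotated junction/intron enters the graph only with at least
    ``denovo_min_reads`` total reads over at least ``denovo_min_pos`` distinct
    read positions; annotated edges are merely flagged ``passed`` at the
    looser thresholds.
    """

    denovo_min_reads: int = 5
    denovo_min_pos: int = 3
    annotated_min_reads: int = 3
    annotated_min_pos: int = 2


@dataclass
class SpliceGraph:
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)
    introns: list[RetainedIntron] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0].start if self.exons else 0

    @property
    def end(self) -> int:
        return self.exons[-1].end if self.exons else 0

    # -- exon lookup ------------------------------------------------------

    def exon_index(self, pos: int) -> int | None:
        """Index of the exon containing ``pos``, or None."""
        starts = [e.start for e in self.exons]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and self.exons[i].contains(pos):
            return i
        return None

    def donor_index(self, edge: Edge) -> int | None:
        """Exon whose last base precedes the edge (contains ``start - 1``)."""
        return self.exon_index(edge.start - 1)

    def acceptor_index(self, edge: Edge) -> int | None:
        """Exon containing the edge's ``end`` position."""
        return self.exon_index(edge.end)

    def edges(self) -> list[Edge]:
        return list(self.junctions) + list(self.introns)

    def find_junction(self, start: int, end: int) -> Junction | None:
        for j in self.junctions:
            if j.start == start and j.end == end:
                return j
        return None

    def check_invariants(self) -> None:
        """Raise AssertionError if the graph is internally inconsistent."""
        for a, b in zip(self.exons, self.exons[1:]):
            assert a.end <= b.start, (
                f"{self.gene_id}: exons overlap or unsorted at {a}/{b}"
            )
        for j in self.junctions:
            d, a = self.donor_index(j), self.acceptor_index(j)
            assert d is not None and a is not None and d != a, (
                f"{self.gene_id}: junction {j.start}-{j.end} does not connect "
                f"two distinct exons (donor={d}, acceptor={a})"
            )
        for ri in self.introns:
            d, a = self.donor_index(ri), self.acceptor_index(ri)
            assert d is not None and a is not None and a == d + 1, (
                f"{self.gene_id}: retained intron {ri.start}-{ri.end} is not "
                f"between adjacent exons"
            )


@dataclass
class Lsv:
    """A local splicing variation: a >=2-way split at a reference exon.

    ``direction`` is resolved by strand: a *source* LSV groups the edges a
    transcript can take when leaving the reference exon in the direction of
    transcription, a *target* LSV the edges arriving at it.
    """

    gene_id: str
    reference_exon: Exon
    direction: str  # "source" | "target"
    edges: list[Edge]

    @property
    def lsv_id(self) -> str:
        tag = "s" if self.direction == "source" else "t"
        return f"{self.gene_id}:{tag}:{self.reference_exon.start}-{self.reference_exon.end}"


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[list[int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def graph_from_transcripts(
    gene_id: str,
    chrom: str,
    strand: str,
    transcripts: Sequence[Sequence[tuple[int, int]]],
) -> SpliceGraph:
    """Build the minimal splicegraph for one gene from transcript exon lists.

    Exons of all transcripts are merged into non-overlapping intervals; one
    junction is created per distinct (donor, acceptor) pair.  Wherever a
    merged exon spans the full interval of some junction (i.e. one transcript
    retains what another splices out), the spanning exon is split and an
    annotated retained intron is recorded, so that every junction starts and
    ends in different exons.
    """
    junctions: set[tuple[int, int]] = set()
    for tx in transcripts:
        ex = sorted(tx)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise AnnotationError(
                    f"gene {gene_id}: transcript exons overlap: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
            junctions.add((e1, s2))

    merged = _merge_intervals(iv for tx in transcripts for iv in tx)

    exons: list[Exon] = []
    introns: list[RetainedIntron] = []
    for s, e in merged:
        # junctions fully inside this merged exon imply retained introns
        inner = sorted((a, b) for (a, b) in junctions if s < a and b < e)
        cur = s
        for a, b in inner:
            if a < cur:
                continue  # overlapping retention; keep the first split
            exons.append(Exon(cur, a))
            introns.append(RetainedIntron(a, b, annotated=True, source=(a, b)))
            cur = b
        exons.append(Exon(cur, e))

    sg = SpliceGraph(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=sorted(exons, key=lambda x: x.start),
        junctions=[Junction(a, b) for a, b in sorted(junctions)],
        introns=sorted(introns, key=lambda x: x.start),
    )
    sg.check_invariants()
    return sg


def parse_annotation(gff3_path: str) -> dict[str, SpliceGraph]:
    """Parse a GFF3 gene/transcript/exon hierarchy into splicegraphs.

    Returns one :class:`SpliceGraph` per gene.  Genes without exons are
    skipped with a warning; records that break the hierarchy raise
    :class:`AnnotationError` naming the record.
    """
    genes: dict[str, dict] = {}
    tx_to_gene: dict[str, str] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}

    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{gff3_path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            s, e = int(start) - 1, int(end)  # to 0-based half-open
            adict = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    adict[k.strip()] = v.strip()
            if ftype == "gene":
                gid = adict.get("ID")
                if gid is None:
                    raise AnnotationError(f"{gff3_path}:{lineno}: gene without ID")
                genes[gid] = {"chrom": chrom, "strand": strand}
            elif ftype in ("mRNA", "transcript"):
                tid, parent = adict.get("ID"), adict.get("Parent")
                if tid is None or parent is None:
                    raise AnnotationError(
                        f"{gff3_path}:{lineno}: transcript without ID/Parent"
                    )
                if parent not in genes:
                    raise AnnotationError(
                        f"{gff3_path}:{lineno}: transcript {tid} references "
                        f"unknown gene {parent}"
                    )
                tx_to_gene[tid] = parent
                tx_exons.setdefault(tid, [])
            elif ftype == "exon":
                parent = adict.get("Parent")
                if parent is None or parent not in tx_exons:
                    raise AnnotationError(
                        f"{gff3_path}:{lineno}: exon without known transcript "
                        f"parent ({adict.get('Parent')})"
                    )
                tx_exons[parent].append((s, e))

    out: dict[str, SpliceGraph] = {}
    for gid, meta in genes.items():
        txs = [tx_exons[t] for t, g in tx_to_gene.items() if g == gid and tx_exons[t]]
        if not txs:
            logger.warning("gene %s has no exons; skipped", gid)
            continue
        out[gid] = graph_from_transcripts(gid, meta["chrom"], meta["strand"], txs)
    return out


# ---------------------------------------------------------------------------
# Gene assignment of de novo junctions
# ---------------------------------------------------------------------------

def assign_junction_to_gene(
    junction: tuple[int, int], candidate_genes: Sequence[SpliceGraph]
) -> str | None:
    """Assign a (start, end) junction to the highest-priority candidate gene.

    Priority: (1) genes already containing the junction; (2) genes where both
    junction coordinates lie within 400 bp of an exon; (3) genes whose
    boundaries contain the junction.  Ties within a tier resolve to the gene
    whose boundary midpoint is nearest the junction midpoint, then to the
    lexicographically smallest gene_id.  Returns None when no tier matches.
    """
    start, end = junction

    def tier(sg: SpliceGraph) -> int:
        if sg.find_junction(start, end) is not None:
            return 1
        if (
            min(e.distance(start) for e in sg.exons) <= NEARBY_WINDOW
            and min(e.distance(end) for e in sg.exons) <= NEARBY_WINDOW
        ):
            return 2
        if sg.start <= start and end <= sg.end:
            return 3
        return 4

    jmid = (start + end) / 2
    best = None
    for sg in candidate_genes:
        t = sg and tier(sg)
        if t == 4:
            continue
        key = (t, abs((sg.start + sg.end) / 2 - jmid), sg.gene_id)
        if best is None or key < best[0]:
            best = (key, sg.gene_id)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# De novo update
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    """Evidence for one potential junction or intron in one gene.

    ``counts`` maps experiment name to (total_reads, nonzero_positions),
    raw totals taken before any outlier masking.
    """

    kind: str  # "junction" | "intron"
    start: int
    end: int
    counts: Mapping[str, tuple[float, int]]


def _passes(
    counts: Mapping[str, tuple[float, int]],
    groups: Sequence[BuildGroup],
    min_reads: float,
    min_pos: int,
) -> bool:
    for g in groups:
        n_ok = sum(
            1
            for exp in g.experiments
            if exp in counts
            and counts[exp][0] >= min_reads
            and counts[exp][1] >= min_pos
        )
        if n_ok >= g.min_experiments:
            return True
    return False


def update_splicegraph(
    sg: SpliceGraph,
    candidates: Sequence[Candidate],
    groups: Sequence[BuildGroup],
    thresholds: BuildThresholds = BuildThresholds(),
) -> SpliceGraph:
    """Incorporate de novo junction/intron evidence into a splicegraph.

    A de novo element is added iff, in at least one build group, at least
    ``min_experiments`` experiments each individually reach the de novo
    reads/positions thresholds.  Annotated elements with evidence at the
    (looser) annotated thresholds are flagged ``passed`` but are retained
    either way.  Exons are extended (up to 400 bp past their annotated
    boundary) or created de novo to host accepted junction endpoints, and
    retained introns are re-derived from the adjusted exon inventory so that
    each fragment spans exactly one inter-exon gap, remembering the original
    intron interval whose coverage it inherits.

    Idempotent: re-applying evidence already incorporated changes nothing.
    """
    sg = replace(
        sg,
        exons=[replace(e) for e in sg.exons],
        junctions=[replace(j) for j in sg.junctions],
        introns=[replace(i) for i in sg.introns],
    )

    accepted_j: list[tuple[int, int]] = []
    accepted_i: list[tuple[int, int]] = []
    for cand in candidates:
        if cand.kind == "junction":
            existing = sg.find_junction(cand.start, cand.end)
            if existing is not None:
                if _passes(cand.counts, groups, thresholds.annotated_min_reads,
                           thresholds.annotated_min_pos):
                    existing.passed = True
                continue
            if _passes(cand.counts, groups, thresholds.denovo_min_reads,
                       thresholds.denovo_min_pos):
                accepted_j.append((cand.start, cand.end))
        else:
            hit = [i for i in sg.introns if i.start <= cand.start and cand.end <= i.end]
            if hit:
                if _passes(cand.counts, groups, thresholds.annotated_min_reads,
                           thresholds.annotated_min_pos):
                    for i in hit:
                        i.passed = True
                continue
            if _passes(cand.counts, groups, thresholds.denovo_min_reads,
                       thresholds.denovo_min_pos):
                accepted_i.append((cand.start, cand.end))

    # --- host exons for accepted de novo junction endpoints ---------------
    orphan_acceptors: list[int] = []
    orphan_donors: list[int] = []
    for start, end in accepted_j:
        for pos, side in ((start, "donor"), (end, "acceptor")):
            probe = pos - 1 if side == "donor" else pos
            if sg.exon_index(probe) is not None:
                continue
            if side == "donor":
                # extend the nearest exon on the left rightwards to pos
                cands = [e for e in sg.exons
                         if e.end <= pos and pos - e.end <= NEARBY_WINDOW]
                if cands:
                    host = max(cands, key=lambda e: e.end)
                    nxt = [e.start for e in sg.exons if e.start >= pos]
                    if not nxt or pos <= min(nxt):
                        host.end = pos
                        host.denovo_extended = True
                        continue
                orphan_donors.append(pos)
            else:
                cands = [e for e in sg.exons
                         if e.start >= pos and e.start - pos <= NEARBY_WINDOW]
                if cands:
                    host = min(cands, key=lambda e: e.start)
                    prev = [e.end for e in sg.exons if e.end <= pos]
                    if not prev or pos >= max(prev):
                        host.start = pos
                        host.denovo_extended = True
                        continue
                orphan_acceptors.append(pos)

    # orphan endpoints beyond the extension window become de novo exons;
    # an acceptor followed by a donor with no exon in between pair up.
    new_exons: list[Exon] = []
    orphan_acceptors.sort()
    orphan_donors.sort()
    used_d: set[int] = set()
    for a in orphan_acceptors:
        mate = None
        for d in orphan_donors:
            if d in used_d or d <= a:
                continue
            between = [e for e in sg.exons if e.start >= a and e.end <= d]
            if not between:
                mate = d
            break
        if mate is not None:
            used_d.add(mate)
            new_exons.append(Exon(a, mate, annotated=False))
        else:
            new_exons.append(Exon(a, a + 1, annotated=False))
    for d in orphan_donors:
        if d not in used_d:
            new_exons.append(Exon(d - 1, d, annotated=False))
    sg.exons = sorted(sg.exons + new_exons, key=lambda e: e.start)

    for start, end in accepted_j:
        sg.junctions.append(Junction(start, end, annotated=False, passed=True))
    sg.junctions.sort(key=lambda j: (j.start, j.end))

    # --- re-derive retained introns over the adjusted exons ---------------
    sources: list[tuple[int, int, bool, bool]] = [
        (i.source[0] if i.source else i.start,
         i.source[1] if i.source else i.end,
         i.annotated, i.passed)
        for i in sg.introns
    ]
    sources += [(s, e, False, True) for s, e in accepted_i]
    new_introns: list[RetainedIntron] = []
    for left, right in zip(sg.exons, sg.exons[1:]):
        gap = (left.end, right.start)
        if gap[0] >= gap[1]:
            continue
        covering = [src for src in sources if src[0] <= gap[0] and gap[1] <= src[1]]
        if not covering:            # also accept partial overlap after extension
            covering = [src for src in sources if src[0] < gap[1] and gap[0] < src[1]]
        if covering:
            s0, e0, ann, passed = covering[0]
            new_introns.append(
                RetainedIntron(gap[0], gap[1], annotated=ann, passed=passed,
                               source=(s0, e0))
            )
    sg.introns = new_introns
    sg.check_invariants()
    return sg


# ---------------------------------------------------------------------------
# Simplifier
# ---------------------------------------------------------------------------

def _splits(sg: SpliceGraph) -> list[list[Edge]]:
    """All donor-side and acceptor-side edge groups (ignoring strand)."""
    donor: dict[int, list[Edge]] = {}
    acceptor: dict[int, list[Edge]] = {}
    for e in sg.edges():
        d, a = sg.donor_index(e), sg.acceptor_index(e)
        if d is None or a is None or d == a:
            continue
        donor.setdefault(d, []).append(e)
        acceptor.setdefault(a, []).append(e)
    return list(donor.values()) + list(acceptor.values())


def simplify(
    sg: SpliceGraph,
    group_rates: Mapping[tuple, Mapping[str, float]],
    threshold: float,
) -> SpliceGraph:
    """Flag edges with consistently low relative coverage as simplified.

    For every edge and build group the raw read rate is divided by the summed
    rate of all edges of each of the (up to two) LSV splits containing it.
    The edge is simplified iff this ratio is below ``threshold`` in every
    build group for both splits; a split with zero total rate in a group
    abstains, i.e. counts as low.  Simplified edges are excluded from LSV
    definition but stay in the graph.

    ``group_rates`` maps edge keys (``edge.key``) to per-group aggregate raw
    read rates.  Returns a new graph; ``threshold=0`` is the identity.
    """
    sg = replace(
        sg,
        exons=[replace(e) for e in sg.exons],
        junctions=[replace(j) for j in sg.junctions],
        introns=[replace(i) for i in sg.introns],
    )
    if threshold <= 0:
        return sg
    groups = sorted({g for rates in group_rates.values() for g in rates})

    def rate(e: Edge, g: str) -> float:
        return group_rates.get(e.key, {}).get(g, 0.0)

    low: dict[tuple, bool] = {e.key: True for e in sg.edges()}
    for split in _splits(sg):
        for e in split:
            ok_all_groups = True
            for g in groups:
                total = sum(rate(x, g) for x in split)
                if total > 0 and rate(e, g) / total >= threshold:
                    ok_all_groups = False
                    break
            if not ok_all_groups:
                low[e.key] = False
    if not groups:
        low = {k: False for k in low}

    for e in sg.edges():
        if low.get(e.key, False):
            e.simplified = True
    return sg


# ---------------------------------------------------------------------------
# LSV definition
# ---------------------------------------------------------------------------

def define_lsvs(sg: SpliceGraph, include_introns: bool = True) -> list[Lsv]:
    """Enumerate source and target LSVs with >= 2 non-simplified edges.

    On the forward strand a source LSV collects the edges leaving an exon
    rightwards (donor side); on the reverse strand transcription runs
    right-to-left, so donor-side groups become target LSVs and vice versa.
    Edges are ordered by genomic coordinate.
    """
    donor: dict[int, list[Edge]] = {}
    acceptor: dict[int, list[Edge]] = {}
    for e in sg.edges():
        if e.simplified:
            continue
        if e.is_intron and not include_introns:
            continue
        d, a = sg.donor_index(e), sg.acceptor_index(e)
        if d is None or a is None or d == a:
            continue
        donor.setdefault(d, []).append(e)
        acceptor.setdefault(a, []).append(e)

    fwd = sg.strand != "-"
    lsvs: list[Lsv] = []
    for idx in sorted(set(donor) | set(acceptor)):
        for side, edges in (("donor", donor.get(idx, [])),
                            ("acceptor", acceptor.get(idx, []))):
            if len(edges) < 2:
                continue
            direction = (
                "source" if (side == "donor") == fwd else "target"
            )
            lsvs.append(
                Lsv(
                    gene_id=sg.gene_id,
                    reference_exon=sg.exons[idx],
                    direction=direction,
                    edges=sorted(edges, key=lambda e: (e.start, e.end)),
                )
            )
    lsvs.sort(key=lambda l: (l.reference_exon.start, l.direction))
    return lsvs


# ---------------------------------------------------------------------------
# Dump
# ---------------------------------------------------------------------------

def dump_tsv(graphs: Mapping[str, SpliceGraph], path: str) -> None:
    """Write all graphs as a GFF3-like TSV (one row per exon/junction/intron)."""
    with open(path, "w") as fh:
        fh.write("#lsvkit-splicegraph\t1\n")
        fh.write("gene_id\tchrom\tstrand\tkind\tstart\tend\tannotated\t"
                 "simplified\tdenovo_extended\n")
        for gid in sorted(graphs):
            sg = graphs[gid]
            for e in sg.exons:
                fh.write(f"{gid}\t{sg.chrom}\t{sg.strand}\texon\t{e.start}\t"
                         f"{e.end}\t{int(e.annotated)}\t0\t{int(e.denovo_extended)}\n")
            for j in sg.junctions:
                fh.write(f"{gid}\t{sg.chrom}\t{sg.strand}\tjunction\t{j.start}\t"
                         f"{j.end}\t{int(j.annotated)}\t{int(j.simplified)}\t0\n")
            for i in sg.introns:
                fh.write(f"{gid}\t{sg.chrom}\t{sg.strand}\tintron\t{i.start}\t"
                         f"{i.end}\t{int(i.annotated)}\t{int(i.simplified)}\t0\n")
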