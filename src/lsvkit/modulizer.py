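"""Alternative-splicing modules: single-entry/single-exit splicegraph regions
and the classification of their constituent binary AS events.

A module is a maximal stretch of a gene's splicegraph in which more than one
junction path runs in parallel: it begins where one path diverges into two
or more and ends where all paths have converged back to one.  Within a
module, binary sub-patterns are matched against a fixed taxonomy of event
types:

    CE    cassette exon                  TCE   tandem cassette exons
    MES   multi-exon skipping            MXE   mutually exclusive exons
    A5SS  alternative 5' splice site     A3SS  alternative 3' splice site
    AFE   alternative first exon         ALE   alternative last exon
    pAFE / pALE                          putative variants built on a de
                                         novo terminal exon
    pA5SS / pA3SS                        putative alternative splice sites:
                                         a cassette-like pattern whose
                                         inclusion junction is gone but whose
                                         intron retention is high
    IR    intron retention
    other anything with >= 2 paths that matches no pattern

Before detection, edges whose group-median E[PSI] stays below the
"decomplexify" threshold in every group are removed from consideration
(the splicegraph itself is untouched).  After classification, events can be
flagged *changing* / *non-changing* from HET results using the median
difference, within-group IQR and per-statistic p value thresholds.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .splicegraph import Edge, Exon, SpliceGraph

logger = logging.getLogger(__name__)

EVENT_TYPES = [
    "CE", "TCE", "MES", "MXE", "A3SS", "A5SS", "AFE", "ALE",
    "pAFE", "pALE", "pA3SS", "pA5SS", "IR", "other",
]


@dataclass
class FlagThresholds:
    psi_simplify: float = 0.05      # decomplexify: min group-median E[PSI]
    dpsi_changing: float = 0.20     # min |median difference| for changing
    p_changing: float = 0.05        # max p (all statistics) for changing
    dpsi_nonchanging: float = 0.05  # max |median difference| for non-changing
    iqr_nonchanging: float = 0.10   # max within-group IQR for non-changing
    p_nonchanging: float = 0.05     # min p (all statistics) for non-changing

    def __post_init__(self) -> None:
        for name in ("psi_simplify", "dpsi_changing", "p_changing",
                     "dpsi_nonchanging", "iqr_nonchanging", "p_nonchanging"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dpsi_nonchanging >= self.dpsi_changing:
            raise ValueError("dpsi_nonchanging must be < dpsi_changing")


@dataclass
class AsEvent:
    event_type: str
    inclusion_edges: list[tuple]   # edge keys
    exclusion_edges: list[tuple]
    source_lsv: str | None = None
    target_lsv: str | None = None
    changing: bool = False
    nonchanging: bool = False

    @property
    def edges(self) -> list[tuple]:
        return self.inclusion_edges + self.exclusion_edges


@dataclass
class AsModule:
    gene_id: str
    entry_exon: Exon
    exit_exon: Exon
    exon_indices: list[int]
    edges: list[Edge]
    events: list[AsEvent] = field(default_factory=list)

    @property
    def module_id(self) -> str:
        return f"{self.gene_id}:{self.entry_exon.start}-{self.exit_exon.end}"

    def type_label(self) -> Counter:
        return label_module_types(self.events)


@dataclass
class ModuleView:
    """A decomplexified, read-only view of one splicegraph."""

    sg: SpliceGraph
    edges: list[Edge]


def decomplexify(sg: SpliceGraph,
                 group_medians: Mapping[tuple, Mapping[str, float]],
                 psi_threshold: float = 0.05) -> ModuleView:
    """Drop edges whose group-median E[PSI] is below threshold in every group.

    ``group_medians`` maps edge keys to per-group medians of E[PSI].
    Simplified edges are always dropped.  An edge with no quantification in
    any group is removed (and logged) unless the filter is disabled
    (``psi_threshold == 0``, the identity).  The underlying splicegraph is
    not modified.
    """
    kept: list[Edge] = []
    for e in sg.edges():
        if e.simplified:
            continue
        if psi_threshold <= 0:
            kept.append(e)
            continue
        meds = group_medians.get(e.key)
        if not meds:
            logger.info("%s edge %s lacks quantification; removed",
                        sg.gene_id, e.key)
            continue
        if max(meds.values()) >= psi_threshold:
            kept.append(e)
    return ModuleView(sg, kept)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(view: ModuleView) -> list[AsModule]:
    """Find single-entry/single-exit AS modules in a decomplexified view.

    A boundary between consecutive exons separates two modules iff at most
    one retained edge crosses it and, if exactly one does, that edge links
    the two adjacent exons (a constitutive connection).  Maximal runs of
    non-separating boundaries delimit the modules; regions traversed by a
    single path yield none.  Edges belong to exactly one module; boundary
    exons may be shared between neighbouring modules.
    """
    sg = view.sg
    spans: list[tuple[int, int, Edge]] = []
    for e in view.edges:
        d, a = sg.donor_index(e), sg.acceptor_index(e)
        if d is None or a is None or d == a:
            continue
        spans.append((d, a, e))

    n_bounds = len(sg.exons) - 1
    modules: list[AsModule] = []
    run: list[int] = []

    def close_run() -> None:
        if not run:
            return
        k0, k1 = run[0], run[-1]
        edges = [e for d, a, e in spans if d <= k1 and a >= k0 + 1]
        if len(edges) >= 2:
            idxs = list(range(k0, k1 + 2))
            modules.append(
                AsModule(
                    gene_id=sg.gene_id,
                    entry_exon=sg.exons[k0],
                    exit_exon=sg.exons[k1 + 1],
                    exon_indices=idxs,
                    edges=sorted(edges, key=lambda e: (e.start, e.end)),
                )
            )
        run.clear()

    for k in range(n_bounds):
        crossing = [(d, a) for d, a, _ in spans if d <= k and a >= k + 1]
        separator = (
            len(crossing) == 0
            or (len(crossing) == 1 and crossing[0] == (k, k + 1))
        )
        if separator:
            close_run()
        else:
            if run and run[-1] == k - 1:
                # exon k is a convergence point when nothing spans across it;
                # back-to-back modules then share it as exit/entry exon
                spanned = any(d <= k - 1 and a >= k + 1 for d, a, _ in spans)
                if not spanned:
                    close_run()
            run.append(k)
    close_run()
    return modules


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

def _lsv_id(sg: SpliceGraph, exon_idx: int, side: str) -> str:
    """LSV id for the donor/acceptor split of an exon, direction by strand."""
    fwd = sg.strand != "-"
    direction = "source" if (side == "donor") == fwd else "target"
    tag = "s" if direction == "source" else "t"
    e = sg.exons[exon_idx]
    return f"{sg.gene_id}:{tag}:{e.start}-{e.end}"


def classify_events(module: AsModule, sg: SpliceGraph) -> list[AsEvent]:
    """Match the module's structure against the binary AS event taxonomy.

    Every matched sub-pattern is emitted as one event carrying references to
    the quantifying source- and target-side LSVs (both are reported even
    when they quantify the same structure).  A module with at least two
    distinct paths in which nothing matched yields a single "other" event.
    """
    idxs = module.exon_indices
    fwd = sg.strand != "-"

    junctions: dict[tuple[int, int], list[Edge]] = {}
    introns: dict[tuple[int, int], Edge] = {}
    for e in module.edges:
        d, a = sg.donor_index(e), sg.acceptor_index(e)
        if e.is_intron:
            introns[(d, a)] = e
        else:
            junctions.setdefault((d, a), []).append(e)

    def J(a: int, b: int) -> list[Edge]:
        return junctions.get((a, b), [])

    incoming: dict[int, int] = {i: 0 for i in idxs}
    outgoing: dict[int, int] = {i: 0 for i in idxs}
    for (d, a), js in junctions.items():
        outgoing[d] = outgoing.get(d, 0) + len(js)
        incoming[a] = incoming.get(a, 0) + len(js)
    for (d, a) in introns:
        outgoing[d] = outgoing.get(d, 0) + 1
        incoming[a] = incoming.get(a, 0) + 1

    events: list[AsEvent] = []

    def emit(etype: str, incl: list[Edge], excl: list[Edge],
             left: int, right: int) -> None:
        src = _lsv_id(sg, left if fwd else right, "donor" if fwd else "acceptor")
        tgt = _lsv_id(sg, right if fwd else left, "acceptor" if fwd else "donor")
        events.append(
            AsEvent(
                event_type=etype,
                inclusion_edges=[e.key for e in incl],
                exclusion_edges=[e.key for e in excl],
                source_lsv=src,
                target_lsv=tgt,
            )
        )

    pairs = sorted(junctions)

    # IR: retained intron with any parallel junction path (either directly
    # between the same adjacent exons or spanning across the intron)
    for (d, a), intron in introns.items():
        parallel = J(d, a) or [
            js[0] for (jd, ja), js in junctions.items() if jd <= d and ja >= a
        ]
        if parallel:
            emit("IR", [intron], [parallel[0]], d, a)

    # CE: single middle exon with inclusion path and skipping junction
    for a in idxs:
        for b in idxs:
            if b <= a + 1 or not J(a, b):
                continue
            for c in idxs:
                if a < c < b and J(a, c) and J(c, b):
                    emit("CE", [J(a, c)[0], J(c, b)[0]], [J(a, b)[0]], a, b)

    # TCE / MES: >= 2 middle exons skipped by one junction
    for a in idxs:
        for b in idxs:
            if b <= a + 2 or not J(a, b):
                continue
            middles = [c for c in idxs if a < c < b]
            # TCE: every chain a -> c1 -> ... -> ck -> b (k >= 2)
            def chains(frm: int, path: list[int]) -> None:
                for nxt in middles:
                    if nxt <= frm or not J(frm, nxt):
                        continue
                    seq = path + [nxt]
                    if J(nxt, b):
                        incl = [J(a, seq[0])[0]]
                        for u, v in zip(seq, seq[1:]):
                            incl.append(J(u, v)[0])
                        incl.append(J(seq[-1], b)[0])
                        emit("TCE", incl, [J(a, b)[0]], a, b)
                    chains(nxt, seq)
            for c1 in middles:
                if J(a, c1):
                    chains(c1, [c1])
            # MES: entry junction into the first middle, exit junction from a
            # later middle, regardless of how the middles are joined
            for cf in middles:
                for cl in middles:
                    if cl > cf and J(a, cf) and J(cl, b):
                        emit("MES", [J(a, cf)[0], J(cl, b)[0]], [J(a, b)[0]], a, b)

    # MXE: two middles, each with entry and exit, not connected, no skip
    for a in idxs:
        for b in idxs:
            if b <= a + 2 or J(a, b):
                continue
            mids = [c for c in idxs if a < c < b and J(a, c) and J(c, b)]
            for i, c1 in enumerate(mids):
                for c2 in mids[i + 1:]:
                    if J(c1, c2) or (c1, c2) in introns:
                        continue
                    emit("MXE", [J(a, c1)[0], J(c1, b)[0]],
                         [J(a, c2)[0], J(c2, b)[0]], a, b)

    # A5SS / A3SS: two junctions between the same exon pair sharing one end
    for (d, a) in pairs:
        js = sorted(J(d, a), key=lambda e: (e.start, e.end))
        for i, j1 in enumerate(js):
            for j2 in js[i + 1:]:
                if j1.end == j2.end and j1.start != j2.start:
                    etype = "A5SS" if fwd else "A3SS"
                elif j1.start == j2.start and j1.end != j2.end:
                    etype = "A3SS" if fwd else "A5SS"
                else:
                    continue
                emit(etype, [j1], [j2], d, a)

    # AFE / ALE: alternative terminal exons converging on a common exon
    starts = [i for i in idxs if incoming.get(i, 0) == 0 and outgoing.get(i, 0) > 0]
    for i, s1 in enumerate(starts):
        for s2 in starts[i + 1:]:
            common = [b for b in idxs if J(s1, b) and J(s2, b)]
            if not common:
                continue
            b = min(common)
            putative = not (sg.exons[s1].annotated and sg.exons[s2].annotated)
            etype = ("p" if putative else "") + ("AFE" if fwd else "ALE")
            emit(etype, [J(s2, b)[0]], [J(s1, b)[0]], s1, b)
    ends = [i for i in idxs if outgoing.get(i, 0) == 0 and incoming.get(i, 0) > 0]
    for i, e1 in enumerate(ends):
        for e2 in ends[i + 1:]:
            common = [a for a in idxs if J(a, e1) and J(a, e2)]
            if not common:
                continue
            a = max(common)
            putative = not (sg.exons[e1].annotated and sg.exons[e2].annotated)
            etype = ("p" if putative else "") + ("ALE" if fwd else "AFE")
            emit(etype, [J(a, e1)[0]], [J(a, e2)[0]], a, e2)

    # pA5SS / pA3SS: cassette whose inclusion junction is gone, bridged by IR
    for a in idxs:
        for b in idxs:
            if b <= a + 1 or not J(a, b):
                continue
            for c in idxs:
                if not a < c < b:
                    continue
                # intron joins c..c+1 == c..? toward b side, junction a -> c kept
                if (c, c + 1) in introns and c + 1 <= b and not J(c, b) and J(a, c) \
                        and c + 1 == b:
                    etype = "pA3SS" if fwd else "pA5SS"
                    emit(etype, [J(a, c)[0], introns[(c, b)]], [J(a, b)[0]], a, b)
                if (a, a + 1) in introns and a + 1 == c and not J(a, c) and J(c, b):
                    etype = "pA5SS" if fwd else "pA3SS"
                    emit(etype, [introns[(a, c)], J(c, b)[0]], [J(a, b)[0]], a, b)

    if not events and len(module.edges) >= 2:
        emit("other", [e for e in module.edges], [],
             module.exon_indices[0], module.exon_indices[-1])
    return events


def label_module_types(events: Sequence[AsEvent]) -> Counter:
    """Module label: the multiset of event types after the redundancy rule.

    Every tandem-cassette module necessarily contains a multi-exon-skipping
    pattern, and every putative-splice-site module an intron-retention
    pattern; the partially redundant type (MES, IR) enters the label only
    when its count exceeds the count of the type it overlaps.
    """
    counts = Counter(e.event_type for e in events)
    label = Counter()
    for etype, n in counts.items():
        if etype == "MES" and n <= counts.get("TCE", 0):
            continue
        if etype == "IR" and n <= counts.get("pA3SS", 0) + counts.get("pA5SS", 0):
            continue
        label[etype] = n
    return label


# ---------------------------------------------------------------------------
# Changing / non-changing flags
# ---------------------------------------------------------------------------

@dataclass
class EdgeQuant:
    """Joined quantification for one edge used by the event flags."""

    dmedian: float                  # difference of group medians of E[PSI]
    pvalues: Mapping[str, float]    # per requested statistic
    iqr: Sequence[float] = ()       # within-group IQRs


def flag_events(events: Sequence[AsEvent],
                edge_quant: Mapping[tuple, EdgeQuant],
                thresholds: FlagThresholds = FlagThresholds()) -> list[AsEvent]:
    """Set changing / non-changing flags on events from joined quantifications.

    changing: at least one event edge has |median difference| >=
    ``dpsi_changing`` with every requested statistic's p below
    ``p_changing``.  non-changing: every event edge has |median difference|
    <= ``dpsi_nonchanging``, all within-group IQRs <= ``iqr_nonchanging``
    and every p >= ``p_nonchanging``.  Events with an unquantified edge are
    left unflagged.
    """
    for ev in events:
        quants = [edge_quant.get(k) for k in ev.edges]
        if any(q is None for q in quants) or not quants:
            logger.info("event %s has unquantified edges; unflagged",
                        ev.event_type)
            ev.changing = ev.nonchanging = False
            continue
        ev.changing = any(
            abs(q.dmedian) >= thresholds.dpsi_changing
            and all(p < thresholds.p_changing for p in q.pvalues.values())
            for q in quants
        )
        ev.nonchanging = all(
            abs(q.dmedian) <= thresholds.dpsi_nonchanging
            and all(i <= thresholds.iqr_nonchanging for i in q.iqr)
            and all(p >= thresholds.p_nonchanging for p in q.pvalues.values())
            for q in quants
        )
        assert not (ev.changing and ev.nonchanging)
    return list(events)
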