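"""Method-assessment statistics: reproducibility-ratio curves, intra-to-inter
ratio, and event/gene-level confusion labelling against ground truth.

The reproducibility ratio measures internal consistency of a differential
splicing method: repeat a two-group comparison on disjoint sample splits and
ask what fraction of the top *n* events of the first run appear among the
top *n* of the second.  The intra-to-inter ratio (IIR) is an FDR proxy for
real data without ground truth: significant events from a within-group
comparison divided by those from a between-group comparison.

When simulated ground truth is available, events are labelled TP/TN/FP/FN
from the method's reported |dPSI| and p value against the true |dPSI|
(cases falling between the 5% and 20% bands, or where the method's dPSI and
p value conflict, are Ambiguous), and genes are labelled from their events
with priority FP > FN > TP > TN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

LABELS = ("TP", "TN", "FP", "FN", "Ambiguous")
GENE_PRIORITY = ("FP", "FN", "TP", "TN")


@dataclass
class RankedEventList:
    """Events deemed significant, ordered best-first by the method's score."""

    ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked event identifiers must be unique")

    def __len__(self) -> int:
        return len(self.ids)


def collapse_overlapping(ranked_ids: Sequence[str],
                         event_junctions: Mapping[str, Iterable[tuple]],
                         ) -> RankedEventList:
    """Drop an event when an earlier-ranked one shares a junction with it.

    Source and target LSVs of one classic AS event overlap by construction,
    so keeping both would double-count the event; the first-ranked LSV wins.
    """
    kept: list[str] = []
    seen: set[tuple] = set()
    for eid in ranked_ids:
        juncs = set(event_junctions.get(eid, ()))
        if juncs & seen:
            continue
        kept.append(eid)
        seen |= juncs
    return RankedEventList(kept)


def rr_curve(list1: RankedEventList, list2: RankedEventList) -> np.ndarray:
    """RR(n) = |top_n(list1) & top_n(list2)| / n for n = 1..len(list1).

    ``RR(N_A)`` with ``N_A = len(list1)`` is the reproducibility ratio.
    Returns an empty array when the first list is empty.
    """
    n_a = len(list1)
    if n_a == 0:
        return np.empty(0)
    set1: set[str] = set()
    set2: set[str] = set()
    rr = np.empty(n_a)
    for n in range(n_a):
        set1.add(list1.ids[n])
        if n < len(list2.ids):
            set2.add(list2.ids[n])
        rr[n] = len(set1 & set2) / (n + 1)
    return rr


def iir(n_intra: int, n_inter: int) -> float | None:
    """Intra-to-inter significant-event ratio; None when n_inter == 0."""
    if n_intra < 0 or n_inter < 0:
        raise ValueError("counts must be non-negative")
    if n_inter == 0:
        return None
    return n_intra / n_inter


def label_event(dpsi_tool: float, p_tool: float, dpsi_gt: float,
                thresholds: tuple[float, float, float] = (0.20, 0.05, 0.05),
                ) -> str:
    """Confusion label for one event from tool output vs ground truth.

    ``dpsi_tool`` and ``dpsi_gt`` are the maxima of |dPSI| over the event's
    junctions/introns, taken before this call.  With thresholds
    (high, low, p): TP when tool >= high significant and truth >= high; TN
    when tool < low non-significant and truth < low; FP/FN for the
    significant/non-significant mismatches; anything else (either quantity
    in the [low, high) band, or dPSI and p value conflicting) is Ambiguous.
    """
    high, low, p_thr = thresholds
    dpsi_tool, dpsi_gt = abs(dpsi_tool), abs(dpsi_gt)
    sig = dpsi_tool >= high and p_tool <= p_thr
    nonsig = dpsi_tool < low and p_tool > p_thr
    if sig and dpsi_gt >= high:
        return "TP"
    if sig and dpsi_gt < low:
        return "FP"
    if nonsig and dpsi_gt < low:
        return "TN"
    if nonsig and dpsi_gt >= high:
        return "FN"
    return "Ambiguous"


def gene_label(event_labels: Iterable[str]) -> str | None:
    """Aggregate event labels of one gene with priority FP > FN > TP > TN.

    Wrong hits dominate (they cost follow-up effort), then missed changes.
    A gene whose events are all Ambiguous is excluded (None).
    """
    present = set(event_labels)
    for lab in GENE_PRIORITY:
        if lab in present:
            return lab
    return None


def confusion_summary(gene_labels: Iterable[str]) -> dict:
    """FDR, FNR and Matthews correlation coefficient over labelled genes."""
    counts = {lab: 0 for lab in GENE_PRIORITY}
    for lab in gene_labels:
        if lab in counts:
            counts[lab] += 1
    tp, tn, fp, fn = counts["TP"], counts["TN"], counts["FP"], counts["FN"]
    fdr = fp / (fp + tp) if fp + tp else None
    fnr = fn / (fn + tp) if fn + tp else None
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else None
    return {"FDR": fdr, "FNR": fnr, "MCC": mcc,
            "TP": tp, "TN": tn, "FP": fp, "FN": fn}
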