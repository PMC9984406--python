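"""End-to-end orchestration: annotation + SJ coverage -> splicegraphs ->
LSV coverage -> PSI / dPSI / HET tables -> module classification inputs.

This is the library equivalent of the command-line workflow: build once,
quantify many times.  All SJ coverage is read from
:class:`~lsvkit.coverage.SJFile` containers, which are either computed from
alignments (and cached) or simulated, so a build is reproducible and
incremental by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import het as het_mod
from .coverage import (
    DEFAULT_BOOTSTRAPS,
    EdgeCoverage,
    SJFile,
    bootstrap_rates,
    mask_outliers,
    reduce_intron,
)
from .psi import (
    DpsiPrior,
    ExperimentLsvCoverage,
    PsiPosterior,
    dpsi_for_edge,
    experiment_psi,
    group_psi,
)
from .splicegraph import (
    BuildGroup,
    BuildThresholds,
    Candidate,
    Lsv,
    SpliceGraph,
    assign_junction_to_gene,
    define_lsvs,
    parse_annotation,
    simplify,
    update_splicegraph,
)


@dataclass
class BuildResult:
    graphs: dict[str, SpliceGraph]
    lsvs: dict[str, list[Lsv]]               # gene_id -> LSVs
    sj: Mapping[str, SJFile]                 # experiment -> coverage
    read_length: int
    rejects: list[tuple] = field(default_factory=list)

    def all_lsvs(self) -> list[Lsv]:
        return [l for gid in sorted(self.lsvs) for l in self.lsvs[gid]]


def _aggregate_candidates(sj_by_exp: Mapping[str, SJFile]):
    """Per SJ record key: experiment -> (total reads, nonzero positions)."""
    agg: dict[tuple, dict[str, tuple[float, int]]] = {}
    for exp, sj in sj_by_exp.items():
        for key, counts in sj.records.items():
            agg.setdefault(key, {})[exp] = (
                float(counts.sum()),
                int(np.count_nonzero(counts)),
            )
    return agg


def build(gff3_path: str, sj_by_exp: Mapping[str, SJFile],
          groups: Sequence[BuildGroup],
          thresholds: BuildThresholds = BuildThresholds(),
          read_length: int = 100,
          simplifier_threshold: float = 0.0) -> BuildResult:
    """Build splicegraphs from annotation plus per-experiment SJ coverage.

    De novo junctions are assigned to genes by the containment / 400 bp /
    boundary priority; junctions passing the evidence thresholds but
    matching no gene land in ``rejects``.  When ``simplifier_threshold`` is
    positive the simplifier runs on per-build-group raw read rates before
    LSVs are defined.
    """
    graphs = parse_annotation(gff3_path)
    agg = _aggregate_candidates(sj_by_exp)

    by_chrom: dict[str, list[SpliceGraph]] = {}
    annotated_j: dict[tuple, str] = {}
    for sg in graphs.values():
        by_chrom.setdefault(sg.chrom, []).append(sg)
        for j in sg.junctions:
            annotated_j.setdefault((sg.chrom, j.start, j.end), sg.gene_id)

    per_gene: dict[str, list[Candidate]] = {g: [] for g in graphs}
    rejects: list[tuple] = []
    for key, counts in sorted(agg.items()):
        kind, chrom, _strand, start, end = key
        cands = by_chrom.get(chrom, [])
        if kind == "J":
            # fast path: annotated junctions resolve without the tier scan
            gid = annotated_j.get((chrom, start, end))
            if gid is None:
                gid = assign_junction_to_gene((start, end), cands)
            if gid is None:
                if _supported(counts, groups, thresholds):
                    rejects.append(key)
                continue
            per_gene[gid].append(Candidate("junction", start, end, counts))
        else:
            hosts = [sg for sg in cands if sg.start <= start and end <= sg.end]
            if not hosts:
                continue
            gid = min(hosts, key=lambda sg: sg.gene_id).gene_id
            per_gene[gid].append(Candidate("intron", start, end, counts))

    for gid, cands in per_gene.items():
        graphs[gid] = update_splicegraph(graphs[gid], cands, groups, thresholds)

    if simplifier_threshold > 0:
        for gid, sg in graphs.items():
            rates: dict[tuple, dict[str, float]] = {}
            for e in sg.edges():
                per_group: dict[str, float] = {}
                for g in groups:
                    per_group[g.name] = sum(
                        _edge_raw_total(sj_by_exp[exp], sg, e)
                        for exp in g.experiments if exp in sj_by_exp
                    )
                rates[e.key] = per_group
            graphs[gid] = simplify(sg, rates, simplifier_threshold)

    lsvs = {gid: define_lsvs(sg) for gid, sg in graphs.items()}
    return BuildResult(graphs, lsvs, dict(sj_by_exp), read_length, rejects)


def _supported(counts, groups, thresholds: BuildThresholds) -> bool:
    from .splicegraph import _passes

    return _passes(counts, groups, thresholds.denovo_min_reads,
                   thresholds.denovo_min_pos)


def _edge_record(sj: SJFile, sg: SpliceGraph, edge) -> np.ndarray | None:
    """SJ record for an edge; introns match any record covering the fragment."""
    if not edge.is_intron:
        return sj.records.get(("J", sg.chrom, ".", edge.start, edge.end))
    src = edge.source or (edge.start, edge.end)
    exact = sj.records.get(("I", sg.chrom, ".", src[0], src[1]))
    if exact is not None:
        return exact
    for (kind, chrom, _s, s, e), counts in sj.records.items():
        if kind == "I" and chrom == sg.chrom and s <= edge.start and edge.end <= e:
            return counts
    return None


def _edge_raw_total(sj: SJFile, sg: SpliceGraph, edge) -> float:
    rec = _edge_record(sj, sg, edge)
    return float(rec.sum()) if rec is not None else 0.0


def edge_coverage(sj: SJFile, sg: SpliceGraph, edge,
                  read_length: int) -> EdgeCoverage:
    """Reduced (for introns) raw coverage of one edge in one experiment."""
    rec = _edge_record(sj, sg, edge)
    kind = "I" if edge.is_intron else "J"
    npos = read_length - 1
    if rec is None:
        if edge.is_intron:
            src = edge.source or (edge.start, edge.end)
            rec = np.zeros(npos + (src[1] - src[0]))
        else:
            rec = np.zeros(npos)
    cov = EdgeCoverage((kind, sg.chrom, ".", edge.start, edge.end), rec)
    if edge.is_intron:
        cov = reduce_intron(cov, read_length)
    return cov


def _coverage_seed(base_seed: int, experiment: str, lsv_id: str) -> int:
    return (base_seed * 7_919 + zlib.crc32(f"{experiment}|{lsv_id}".encode())) % (2**31)


def lsv_experiment_coverage(result: BuildResult, sg: SpliceGraph, lsv: Lsv,
                            experiment: str, M: int = DEFAULT_BOOTSTRAPS,
                            seed: int = 0) -> ExperimentLsvCoverage:
    """Masked, bootstrapped coverage of one LSV in one experiment."""
    sj = result.sj[experiment]
    J = len(lsv.edges)
    reads = np.zeros(J)
    positions = np.zeros(J)
    boots = np.zeros((J, M))
    rng_seed = _coverage_seed(seed, experiment, lsv.lsv_id)
    for j, edge in enumerate(lsv.edges):
        cov = edge_coverage(sj, sg, edge, result.read_length)
        reads[j] = cov.total_reads
        positions[j] = cov.nonzero_positions
        masked = mask_outliers(cov)
        boots[j] = bootstrap_rates(masked, M=M, seed=rng_seed + j).replicates
    return ExperimentLsvCoverage(experiment, reads, positions, boots)


# ---------------------------------------------------------------------------
# Quantification drivers
# ---------------------------------------------------------------------------

def quantify_group(result: BuildResult, experiments: Sequence[str],
                   M: int = DEFAULT_BOOTSTRAPS, seed: int = 0,
                   bins: int = 40) -> dict[str, PsiPosterior]:
    """Replicate-group PSI posterior per LSV (the PSI pipeline)."""
    out: dict[str, PsiPosterior] = {}
    for gid, lsvs in result.lsvs.items():
        sg = result.graphs[gid]
        for lsv in lsvs:
            covs = [lsv_experiment_coverage(result, sg, lsv, e, M, seed)
                    for e in experiments]
            post = group_psi(covs, lsv.lsv_id,
                             [e.key for e in lsv.edges], bins=bins)
            if post is not None:
                out[lsv.lsv_id] = post
    return out


def quantify_experiments(result: BuildResult, experiments: Sequence[str],
                         M: int = DEFAULT_BOOTSTRAPS, seed: int = 0,
                         bins: int = 40) -> dict[str, dict[str, PsiPosterior]]:
    """Per-experiment PSI posteriors per LSV (input to HET)."""
    out: dict[str, dict[str, PsiPosterior]] = {}
    for gid, lsvs in result.lsvs.items():
        sg = result.graphs[gid]
        for lsv in lsvs:
            per_exp = {}
            for e in experiments:
                cov = lsv_experiment_coverage(result, sg, lsv, e, M, seed)
                per_exp[e] = experiment_psi(cov, lsv.lsv_id,
                                            [k.key for k in lsv.edges], bins=bins)
            out[lsv.lsv_id] = per_exp
    return out


def het_compare(result: BuildResult, group1: Sequence[str],
                group2: Sequence[str],
                statistics: Sequence[str] = tuple(het_mod.STATISTICS),
                n_rep: int = het_mod.DEFAULT_N_REP,
                M: int = DEFAULT_BOOTSTRAPS, seed: int = 0,
                bins: int = 40) -> dict[str, het_mod.HetResult]:
    """HET comparison of two heterogeneous groups over all LSVs."""
    posts = quantify_experiments(result, list(group1) + list(group2), M, seed, bins)
    out: dict[str, het_mod.HetResult] = {}
    for lsv_id, per_exp in posts.items():
        res = het_mod.het_test(
            [per_exp[e] for e in group1],
            [per_exp[e] for e in group2],
            statistics=statistics, n_rep=n_rep,
            seed=_coverage_seed(seed, "het", lsv_id),
        )
        if res is not None:
            out[lsv_id] = res
    return out


def dpsi_compare(result: BuildResult, group1: Sequence[str],
                 group2: Sequence[str], prior: DpsiPrior | None = None,
                 M: int = DEFAULT_BOOTSTRAPS, seed: int = 0,
                 bins: int = 40) -> dict[str, list[dict]]:
    """dPSI posterior per LSV edge between two replicate groups."""
    p1 = quantify_group(result, group1, M, seed, bins)
    p2 = quantify_group(result, group2, M, seed, bins)
    if prior is None:
        prior = DpsiPrior(bins=bins)
    out: dict[str, list[dict]] = {}
    for lsv_id in sorted(set(p1) & set(p2)):
        rows = []
        for j, key in enumerate(p1[lsv_id].edge_keys):
            post = dpsi_for_edge(p1[lsv_id], p2[lsv_id], j, prior)
            rows.append({
                "edge": key,
                "dpsi_mean": post.mean,
                "psi1": p1[lsv_id].means[j],
                "psi2": p2[lsv_id].means[j],
                "prob_change_0.2": post.prob_change(0.2),
            })
        out[lsv_id] = rows
    return out


# ---------------------------------------------------------------------------
# Bridges into the modulizer
# ---------------------------------------------------------------------------

def group_median_psi(posts_by_exp: Mapping[str, Mapping[str, PsiPosterior]],
                     ) -> dict[tuple, float]:
    """Per-edge median over experiments of posterior-mean PSI.

    When an edge is quantified in both its source and target LSV the larger
    median is kept (an edge is 'used' if either view says so).
    """
    acc: dict[tuple, list[float]] = {}
    for lsv_id, per_exp in posts_by_exp.items():
        quantified = [p for p in per_exp.values() if p is not None]
        if not quantified:
            continue
        keys = quantified[0].edge_keys
        med = np.median([p.means for p in quantified], axis=0)
        for key, m in zip(keys, med):
            acc.setdefault(key, []).append(float(m))
    return {k: max(v) for k, v in acc.items()}


def het_edge_quant(het_results: Mapping[str, het_mod.HetResult]):
    """Join HET output per edge for event flagging.

    Each edge can be quantified by up to two LSVs; the entry with the larger
    |median difference| represents the edge.
    """
    from .modulizer import EdgeQuant

    best: dict[tuple, EdgeQuant] = {}
    for res in het_results.values():
        stats = list(res.p_quantile)
        for j, key in enumerate(res.edge_keys):
            q = EdgeQuant(
                dmedian=float(res.dmedian[j]),
                pvalues={s: float(res.p_quantile[s][j]) for s in stats},
                iqr=[float(res.iqr[0][j]), float(res.iqr[1][j])],
            )
            if key not in best or abs(q.dmedian) > abs(best[key].dmedian):
                best[key] = q
    return best
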