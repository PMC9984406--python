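"""Self-contained simulation studies used to validate the method end to end.

Each function sets up a synthetic study with the generator, runs the real
pipeline on it, and returns summary numbers: type-I error of the HET tests
under a null with between-sample heterogeneity, power to flag planted
changes, PSI estimation error versus depth, and exact agreement of the
module classifier with planted event compositions.  The same entry points
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import os
import tempfile
from collections import Counter

import numpy as np

from . import pipeline
from .het import het_test
from .modulizer import classify_events, decomplexify, detect_modules, label_module_types
from .psi import experiment_psi, group_psi
from .simulate import (
    SampleSpec,
    make_annotation,
    make_gene,
    make_panel,
    simulate_sample,
)
from .splicegraph import BuildGroup, Candidate, parse_annotation, update_splicegraph


def _build_cassette_study(n_genes: int, p_by_group: dict[str, float],
                          n_per_group: int, depth: float, dispersion: float,
                          seed: int, p_jitter: float = 0.0):
    """Cassette-gene panel with group-specific inclusion levels.

    Returns (build result, per-gene true inclusion by group, experiment
    names by group).  All genes share a structure; inclusion levels may be
    jittered per gene around the group value (same jitter in both groups).
    """
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-p_jitter, p_jitter, size=n_genes)
    specs_by_group = {}
    truth: dict[str, dict[str, float]] = {}
    for g, p in p_by_group.items():
        specs = []
        for i in range(n_genes):
            pi = float(np.clip(p + jitter[i], 0.05, 0.95))
            specs.append(make_gene("cassette", f"g{i:04d}", offset=i * 3000, p=pi))
            truth.setdefault(f"g{i:04d}", {})[g] = pi
        specs_by_group[g] = specs

    with tempfile.TemporaryDirectory() as tmp:
        gff3 = os.path.join(tmp, "genes.gff3")
        make_annotation(next(iter(specs_by_group.values())), gff3)
        sj_by_exp = {}
        exps_by_group: dict[str, list[str]] = {}
        k = 0
        for g, specs in specs_by_group.items():
            exps_by_group[g] = []
            for _ in range(n_per_group):
                name = f"{g}_{k}"
                sj_by_exp[name] = simulate_sample(
                    specs, SampleSpec(name=name, depth=depth,
                                      heterogeneity=dispersion,
                                      seed=(seed * 131 + k) % (2**31)))
                exps_by_group[g].append(name)
                k += 1
        groups = [BuildGroup(g, exps, max(1, len(exps) // 2))
                  for g, exps in exps_by_group.items()]
        result = pipeline.build(gff3, sj_by_exp, groups)
    return result, truth, exps_by_group


def _source_lsvs(result: pipeline.BuildResult):
    for gid in sorted(result.lsvs):
        for lsv in result.lsvs[gid]:
            if lsv.direction == "source":
                yield result.graphs[gid], lsv


def null_type1_rates(n_lsvs: int = 500, n_per_group: int = 10,
                     depth: float = 100.0, dispersion: float = 0.05,
                     seed: int = 0) -> dict[str, float]:
    """Fraction of null LSVs with posterior-mean p < 0.05 per statistic.

    Both groups draw per-sample PSI from the same heterogeneous
    distribution, so a calibrated test should reject ~5% of LSVs.
    """
    result, _truth, exps = _build_cassette_study(
        n_lsvs, {"a": 0.5, "b": 0.5}, n_per_group, depth, dispersion, seed,
        p_jitter=0.25)
    g1, g2 = exps["a"], exps["b"]
    stats = ("welch", "mannwhitney")
    hits = {s: 0 for s in stats}
    n_tested = 0
    for sg, lsv in _source_lsvs(result):
        posts1 = [experiment_psi(
            pipeline.lsv_experiment_coverage(result, sg, lsv, e, seed=seed),
            lsv.lsv_id, [k.key for k in lsv.edges]) for e in g1]
        posts2 = [experiment_psi(
            pipeline.lsv_experiment_coverage(result, sg, lsv, e, seed=seed),
            lsv.lsv_id, [k.key for k in lsv.edges]) for e in g2]
        res = het_test(posts1, posts2, statistics=stats, n_rep=0, seed=seed)
        if res is None:
            continue
        n_tested += 1
        for s in stats:
            if res.p_mean[s][0] < 0.05:
                hits[s] += 1
    return {s: hits[s] / n_tested for s in stats} | {"n": n_tested}


def power_and_null_flagging(n_changing: int = 40, n_null: int = 20,
                            dpsi: float = 0.4, n_per_group: int = 10,
                            depth: float = 100.0, dispersion: float = 0.05,
                            seed: int = 0) -> dict[str, float]:
    """Fraction of planted changing / null events flagged as changing.

    The changing flag is the conservative one: |median difference| >= 0.2
    and every HET statistic's 95th-percentile p value < 0.05.
    """
    p_lo, p_hi = 0.5 - dpsi / 2, 0.5 + dpsi / 2
    n_genes = n_changing + n_null

    rng = np.random.default_rng(seed)
    specs_by_group = {"a": [], "b": []}
    for i in range(n_genes):
        if i < n_changing:
            pa, pb = p_lo, p_hi
        else:
            pa = pb = float(rng.uniform(0.3, 0.7))
        specs_by_group["a"].append(
            make_gene("cassette", f"g{i:04d}", offset=i * 3000, p=pa))
        specs_by_group["b"].append(
            make_gene("cassette", f"g{i:04d}", offset=i * 3000, p=pb))

    with tempfile.TemporaryDirectory() as tmp:
        gff3 = os.path.join(tmp, "genes.gff3")
        make_annotation(specs_by_group["a"], gff3)
        sj_by_exp = {}
        exps = {"a": [], "b": []}
        k = 0
        for g in ("a", "b"):
            for _ in range(n_per_group):
                name = f"{g}_{k}"
                sj_by_exp[name] = simulate_sample(
                    specs_by_group[g],
                    SampleSpec(name=name, depth=depth,
                               heterogeneity=dispersion,
                               seed=(seed * 977 + k) % (2**31)))
                exps[g].append(name)
                k += 1
        groups = [BuildGroup(g, e, max(1, len(e) // 2))
                  for g, e in exps.items()]
        result = pipeline.build(gff3, sj_by_exp, groups)

    flagged_changing = flagged_null = 0
    for sg, lsv in _source_lsvs(result):
        posts = {
            e: experiment_psi(
                pipeline.lsv_experiment_coverage(result, sg, lsv, e, seed=seed),
                lsv.lsv_id, [k.key for k in lsv.edges])
            for e in exps["a"] + exps["b"]
        }
        res = het_test([posts[e] for e in exps["a"]],
                       [posts[e] for e in exps["b"]],
                       n_rep=30, seed=seed + 17)
        if res is None:
            continue
        changing = any(
            abs(res.dmedian[j]) >= 0.20
            and all(res.p_quantile[s][j] < 0.05 for s in res.p_quantile)
            for j in range(len(res.edge_keys))
        )
        idx = int(sg.gene_id[1:5])
        if idx < n_changing:
            flagged_changing += changing
        else:
            flagged_null += changing
    return {
        "power": flagged_changing / n_changing,
        "null_flag_rate": flagged_null / n_null,
        "n_changing": n_changing,
        "n_null": n_null,
    }


def psi_recovery_mae(n_lsvs: int = 50, depth: float = 200.0,
                     n_samples: int = 3, seed: int = 0) -> dict[str, float]:
    """Mean absolute error of E[PSI] against planted truth."""
    result, truth, exps = _build_cassette_study(
        n_lsvs, {"a": 0.5}, n_samples, depth, 0.0, seed, p_jitter=0.4)
    errs = []
    for sg, lsv in _source_lsvs(result):
        covs = [pipeline.lsv_experiment_coverage(result, sg, lsv, e, seed=seed)
                for e in exps["a"]]
        post = group_psi(covs, lsv.lsv_id, [k.key for k in lsv.edges])
        if post is None:
            continue
        p_true = truth[sg.gene_id]["a"]
        by_key = dict(zip(post.edge_keys, post.means))
        inclusion = [k for k in by_key if k[1] == lsv.reference_exon.end][0]
        errs.append(abs(by_key[inclusion] - p_true))
    return {"mae": float(np.mean(errs)), "n": len(errs)}


def panel_classification(seed: int = 0) -> dict[str, float]:
    """Module/event exactness on the 20-gene mixed panel.

    Builds the panel annotation, incorporates the planted de novo junctions,
    decomplexifies with the ground-truth PSI at the 5% threshold, and
    compares detected modules and per-type event counts (and the TCE/MES
    redundancy label rule) with the hand-derived plants.
    """
    specs = make_panel(20)
    with tempfile.TemporaryDirectory() as tmp:
        gff3 = os.path.join(tmp, "genes.gff3")
        make_annotation(specs, gff3)
        graphs = parse_annotation(gff3)
    groups = [BuildGroup("g", ["s0", "s1"], 2)]
    module_match = event_match = 0
    redundancy_ok = True
    total_modules = 0
    for spec in specs:
        sg = graphs[spec.gene_id]
        cands = [Candidate("junction", s, e, {"s0": (20.0, 5), "s1": (20.0, 5)})
                 for s, e, _ in spec.denovo_junctions]
        if cands:
            sg = update_splicegraph(sg, cands, groups)
        meds = {k: {"g": v} for k, v in spec.true_psi().items()}
        view = decomplexify(sg, meds, 0.05)
        mods = detect_modules(view)
        total_modules += len(mods)
        counts: Counter = Counter()
        labels: Counter = Counter()
        for m in mods:
            m.events = classify_events(m, sg)
            counts += Counter(e.event_type for e in m.events)
            labels += label_module_types(m.events)
        module_match += len(mods) == spec.expected_modules
        event_match += dict(counts) == spec.expected_events
        if spec.template in ("tce", "tce2") and labels.get("MES", 0) > 0:
            redundancy_ok = False  # MES must be suppressed when TCE >= MES
    return {
        "module_count_match": module_match / len(specs),
        "event_count_match": event_match / len(specs),
        "redundancy_rule_ok": float(redundancy_ok),
        "total_modules": total_modules,
    }
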