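"""Synthetic annotation and coverage generator with known ground truth.

Toy genes are built from a library of templates, one per alternative
splicing pattern (cassette exon, intron retention, mutually exclusive
exons, alternative splice sites / first / last exons, tandem cassettes,
putative variants, and an intentionally unclassifiable structure).  Each
template hand-codes its expected splicegraph inventory (exon / junction /
intron counts), the AS events it plants and the per-edge true PSI as a
function of the isoform abundances, so every downstream module can be
tested against known truth without any external data.

Read simulation works at the coverage level: for each splicegraph edge the
per-position read counts are drawn as independent Poisson variables with
rate ``depth * rel / (L - 1)`` where ``rel`` is the fraction of transcripts
using the edge, so edge totals are Poisson(depth * rel) and the positions
are uniform.  Between-sample heterogeneity draws each sample's isoform
abundances from a Dirichlet centered on the spec's abundances with
concentration ``1 / dispersion**2`` (dispersion 0 means exact replicates).
The same simulated placements can be emitted both as an SJ coverage file
and as a minimal SAM file, which therefore agree read-for-read.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .coverage import SJFile

GENE_SPACING = 10_000


@dataclass
class ToyGeneSpec:
    gene_id: str
    chrom: str
    strand: str
    isoforms: list[list[tuple[int, int]]]
    abundances: list[float]
    template: str = ""
    # hand-derived bookkeeping (after de novo update where applicable)
    expected_exons: int = 0
    expected_junctions: int = 0
    expected_introns: int = 0
    expected_modules: int = 0
    expected_events: dict = field(default_factory=dict)
    #: de novo junctions absent from the annotation but supported by reads,
    #: as (start, end, relative_abundance)
    denovo_junctions: list[tuple[int, int, float]] = field(default_factory=list)
    #: hand-coded per-edge true PSI given abundances
    psi_fn: Callable | None = None

    def __post_init__(self) -> None:
        total = sum(self.abundances)
        if not np.isclose(total, 1.0):
            raise ValueError(f"{self.gene_id}: abundances sum to {total}, not 1")
        if len(self.abundances) != len(self.isoforms):
            raise ValueError(f"{self.gene_id}: one abundance per isoform required")

    # -- ground truth -----------------------------------------------------

    def edge_abundance(self, abundances: Sequence[float] | None = None) -> dict:
        """Fraction of transcripts using each edge: ("J"|"I", start, end) -> rel.

        A junction is used by an isoform when two consecutive exons splice at
        its coordinates; a retained intron when some isoform exon covers it
        with flanking sequence on both sides.
        """
        ab = list(self.abundances if abundances is None else abundances)
        rel: dict[tuple, float] = {}
        intron_keys = self._intron_keys()
        for iso, a in zip(self.isoforms, ab):
            ex = sorted(iso)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                key = ("J", e1, s2)
                rel[key] = rel.get(key, 0.0) + a
            for (js, je) in intron_keys:
                if any(u < js and v > je for u, v in ex):
                    key = ("I", js, je)
                    rel[key] = rel.get(key, 0.0) + a
        remaining = 1.0 - sum(r for *_k, r in self.denovo_junctions)
        rel = {k: v * remaining for k, v in rel.items()}
        for s, e, r in self.denovo_junctions:
            rel[("J", s, e)] = rel.get(("J", s, e), 0.0) + r
        return rel

    def _intron_keys(self) -> list[tuple[int, int]]:
        """Junction intervals retained by some isoform's spanning exon."""
        juncs = set()
        for iso in self.isoforms:
            ex = sorted(iso)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                juncs.add((e1, s2))
        out = []
        for (js, je) in juncs:
            for iso in self.isoforms:
                if any(u < js and v > je for u, v in iso):
                    out.append((js, je))
                    break
        return out

    def true_psi(self, abundances: Sequence[float] | None = None) -> dict:
        """Hand-coded per-edge true PSI (max over the edge's two splits)."""
        if self.psi_fn is None:
            raise ValueError(f"{self.gene_id}: template has no psi function")
        ab = list(self.abundances if abundances is None else abundances)
        return self.psi_fn(ab)

    @property
    def span(self) -> tuple[int, int]:
        lo = min(s for iso in self.isoforms for s, _ in iso)
        hi = max(e for iso in self.isoforms for _, e in iso)
        for s, e, _ in self.denovo_junctions:
            lo, hi = min(lo, s - 200), max(hi, e + 200)
        return lo, hi


@dataclass
class SampleSpec:
    name: str
    depth: float = 100.0
    read_length: int = 100
    heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")


# ---------------------------------------------------------------------------
# Template library
# ---------------------------------------------------------------------------

def _shift(isoforms, off):
    return [[(s + off, e + off) for s, e in iso] for iso in isoforms]


def _psi_shift(fn, off):
    def shifted(ab):
        return {(k[0], k[1] + off, k[2] + off): v for k, v in fn(ab).items()}
    return shifted


TEMPLATES: dict[str, Callable] = {}


def template(name):
    def deco(fn):
        TEMPLATES[name] = fn
        return fn
    return deco


@template("cassette")
def _cassette(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (400, 500), (800, 900)], [(0, 100), (800, 900)]],
        abundances=[p, 1 - p],
        expected_exons=3, expected_junctions=3, expected_introns=0,
        expected_modules=1, expected_events={"CE": 1},
        psi_fn=lambda ab: {("J", 100, 400): ab[0], ("J", 500, 800): ab[0],
                           ("J", 100, 800): ab[1]},
    )


@template("ir")
def _ir(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (400, 500)], [(0, 500)]],
        abundances=[p, 1 - p],
        expected_exons=2, expected_junctions=1, expected_introns=1,
        expected_modules=1, expected_events={"IR": 1},
        psi_fn=lambda ab: {("J", 100, 400): ab[0], ("I", 100, 400): ab[1]},
    )


@template("mxe")
def _mxe(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (300, 400), (900, 1000)],
                  [(0, 100), (600, 700), (900, 1000)]],
        abundances=[p, 1 - p],
        expected_exons=4, expected_junctions=4, expected_introns=0,
        expected_modules=1, expected_events={"MXE": 1},
        psi_fn=lambda ab: {("J", 100, 300): ab[0], ("J", 400, 900): ab[0],
                           ("J", 100, 600): ab[1], ("J", 700, 900): ab[1]},
    )


@template("a5ss")
def _a5ss(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (400, 500)], [(0, 150), (400, 500)]],
        abundances=[p, 1 - p],
        expected_exons=2, expected_junctions=2, expected_introns=0,
        expected_modules=1, expected_events={"A5SS": 1},
        psi_fn=lambda ab: {("J", 100, 400): ab[0], ("J", 150, 400): ab[1]},
    )


@template("a3ss")
def _a3ss(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (400, 500)], [(0, 100), (350, 500)]],
        abundances=[p, 1 - p],
        expected_exons=2, expected_junctions=2, expected_introns=0,
        expected_modules=1, expected_events={"A3SS": 1},
        psi_fn=lambda ab: {("J", 100, 400): ab[0], ("J", 100, 350): ab[1]},
    )


@template("afe")
def _afe(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (700, 800)], [(300, 400), (700, 800)]],
        abundances=[p, 1 - p],
        expected_exons=3, expected_junctions=2, expected_introns=0,
        expected_modules=1, expected_events={"AFE": 1},
        psi_fn=lambda ab: {("J", 100, 700): ab[0], ("J", 400, 700): ab[1]},
    )


@template("ale")
def _ale(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (400, 500)], [(0, 100), (700, 800)]],
        abundances=[p, 1 - p],
        expected_exons=3, expected_junctions=2, expected_introns=0,
        expected_modules=1, expected_events={"ALE": 1},
        psi_fn=lambda ab: {("J", 100, 400): ab[0], ("J", 100, 700): ab[1]},
    )


@template("tce")
def _tce(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (300, 400), (600, 700), (900, 1000)],
                  [(0, 100), (900, 1000)]],
        abundances=[p, 1 - p],
        expected_exons=4, expected_junctions=4, expected_introns=0,
        expected_modules=1, expected_events={"TCE": 1, "MES": 1},
        psi_fn=lambda ab: {("J", 100, 300): ab[0], ("J", 400, 600): ab[0],
                           ("J", 700, 900): ab[0], ("J", 100, 900): ab[1]},
    )


@template("tce2")
def _tce2(p1: float = 0.3, p2: float = 0.3) -> dict:
    p3 = 1 - p1 - p2
    return dict(
        isoforms=[[(0, 100), (300, 400), (500, 600), (700, 800), (900, 1000)],
                  [(0, 100), (300, 400), (700, 800), (900, 1000)],
                  [(0, 100), (900, 1000)]],
        abundances=[p1, p2, p3],
        expected_exons=5, expected_junctions=6, expected_introns=0,
        expected_modules=1, expected_events={"TCE": 2, "MES": 1, "CE": 1},
        psi_fn=lambda ab: {("J", 100, 300): ab[0] + ab[1],
                           ("J", 400, 500): ab[0] / (ab[0] + ab[1]),
                           ("J", 600, 700): ab[0],
                           ("J", 400, 700): ab[1] / (ab[0] + ab[1]),
                           ("J", 800, 900): ab[0] + ab[1],
                           ("J", 100, 900): ab[2]},
    )


@template("pa3ss")
def _pa3ss(minor: float = 0.02) -> dict:
    q = (1 - minor) / 2
    return dict(
        isoforms=[[(0, 100), (400, 500), (700, 800)],
                  [(0, 100), (700, 800)],
                  [(0, 100), (400, 800)]],
        abundances=[minor, q, q],
        expected_exons=3, expected_junctions=3, expected_introns=1,
        expected_modules=1, expected_events={"pA3SS": 1, "IR": 1},
        psi_fn=lambda ab: {("J", 100, 400): ab[0] + ab[2],
                           ("J", 500, 700): ab[0] / (ab[0] + ab[2]),
                           ("J", 100, 700): ab[1],
                           ("I", 500, 700): ab[2]},
    )


@template("pa5ss")
def _pa5ss(minor: float = 0.02) -> dict:
    q = (1 - minor) / 2
    return dict(
        isoforms=[[(0, 100), (300, 400), (700, 800)],
                  [(0, 100), (700, 800)],
                  [(0, 400), (700, 800)]],
        abundances=[minor, q, q],
        expected_exons=3, expected_junctions=3, expected_introns=1,
        expected_modules=1, expected_events={"pA5SS": 1, "IR": 1},
        psi_fn=lambda ab: {("J", 100, 300): ab[0] / (ab[0] + ab[2]),
                           ("J", 400, 700): ab[0] + ab[2],
                           ("J", 100, 700): ab[1],
                           ("I", 100, 300): ab[2]},
    )


@template("other")
def _other(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (400, 500)], [(0, 150), (450, 500)]],
        abundances=[p, 1 - p],
        expected_exons=2, expected_junctions=2, expected_introns=0,
        expected_modules=1, expected_events={"other": 1},
        psi_fn=lambda ab: {("J", 100, 400): ab[0], ("J", 150, 450): ab[1]},
    )


@template("double_ce")
def _double_ce(p: float = 0.5) -> dict:
    return dict(
        isoforms=[[(0, 100), (300, 400), (600, 700), (900, 1000), (1200, 1300)],
                  [(0, 100), (600, 700), (1200, 1300)]],
        abundances=[p, 1 - p],
        expected_exons=5, expected_junctions=6, expected_introns=0,
        expected_modules=2, expected_events={"CE": 2},
        psi_fn=lambda ab: {("J", 100, 300): ab[0], ("J", 400, 600): ab[0],
                           ("J", 100, 600): ab[1], ("J", 700, 900): ab[0],
                           ("J", 1000, 1200): ab[0], ("J", 700, 1200): ab[1]},
    )


@template("pafe")
def _pafe(minor: float = 0.4) -> dict:
    return dict(
        isoforms=[[(0, 100), (1200, 1300)]],
        abundances=[1.0],
        denovo_junctions=[(700, 1200, minor)],
        expected_exons=3, expected_junctions=2, expected_introns=0,
        expected_modules=1, expected_events={"pAFE": 1},
        psi_fn=lambda ab: {("J", 100, 1200): 1 - 0.4, ("J", 700, 1200): 0.4},
    )


@template("pale")
def _pale(minor: float = 0.4) -> dict:
    return dict(
        isoforms=[[(0, 100), (1200, 1300)]],
        abundances=[1.0],
        denovo_junctions=[(100, 700, minor)],
        expected_exons=3, expected_junctions=2, expected_introns=0,
        expected_modules=1, expected_events={"pALE": 1},
        psi_fn=lambda ab: {("J", 100, 1200): 1 - 0.4, ("J", 100, 700): 0.4},
    )


def make_gene(template_name: str, gene_id: str, chrom: str = "chr1",
              offset: int = 0, strand: str = "+", **params) -> ToyGeneSpec:
    """Instantiate a template at a genomic offset."""
    cfg = TEMPLATES[template_name](**params)
    spec = ToyGeneSpec(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        isoforms=_shift(cfg["isoforms"], offset),
        abundances=cfg["abundances"],
        template=template_name,
        expected_exons=cfg["expected_exons"],
        expected_junctions=cfg["expected_junctions"],
        expected_introns=cfg["expected_introns"],
        expected_modules=cfg["expected_modules"],
        expected_events=cfg["expected_events"],
        denovo_junctions=[(s + offset, e + offset, r)
                          for s, e, r in cfg.get("denovo_junctions", [])],
        psi_fn=_psi_shift(cfg["psi_fn"], offset),
    )
    return spec


PANEL_TEMPLATES = [
    "cassette", "ir", "mxe", "a5ss", "a3ss", "afe", "ale", "tce", "tce2",
    "pa3ss", "pa5ss", "other", "double_ce", "pafe", "pale",
    "cassette", "ir", "mxe", "a5ss", "afe",
]


def make_panel(n_genes: int = 20, chrom: str = "chr1") -> list[ToyGeneSpec]:
    """A mixed panel cycling through all templates, one gene per slot."""
    specs = []
    for i in range(n_genes):
        t = PANEL_TEMPLATES[i % len(PANEL_TEMPLATES)]
        specs.append(make_gene(t, f"g{i:03d}_{t}", chrom, offset=i * GENE_SPACING))
    return specs


# ---------------------------------------------------------------------------
# GFF3 emission
# ---------------------------------------------------------------------------

def make_annotation(specs: Sequence[ToyGeneSpec], path: str) -> None:
    """Write the specs as a well-formed GFF3 annotation (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for spec in specs:
            lo, hi = spec.span
            fh.write(f"{spec.chrom}\tlsvkit\tgene\t{lo + 1}\t{hi}\t.\t"
                     f"{spec.strand}\t.\tID={spec.gene_id}\n")
            for t, iso in enumerate(spec.isoforms):
                ts = min(s for s, _ in iso) + 1
                te = max(e for _, e in iso)
                tid = f"{spec.gene_id}.t{t}"
                fh.write(f"{spec.chrom}\tlsvkit\tmRNA\t{ts}\t{te}\t.\t"
                         f"{spec.strand}\t.\tID={tid};Parent={spec.gene_id}\n")
                for s, e in sorted(iso):
                    fh.write(f"{spec.chrom}\tlsvkit\texon\t{s + 1}\t{e}\t.\t"
                             f"{spec.strand}\t.\tParent={tid}\n")


def write_truth_tsv(specs: Sequence[ToyGeneSpec], path: str) -> None:
    """Ground-truth per-edge true PSI table."""
    with open(path, "w") as fh:
        fh.write("gene_id\tkind\tstart\tend\tpsi_true\n")
        for spec in specs:
            for (kind, s, e), psi in sorted(spec.true_psi().items()):
                fh.write(f"{spec.gene_id}\t{kind}\t{s}\t{e}\t{psi:.6g}\n")


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

def _spec_seed(base_seed: int, gene_id: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(gene_id.encode())) % (2**31)


def simulate_positions(specs: Sequence[ToyGeneSpec], sample: SampleSpec,
                       ) -> dict[tuple, np.ndarray]:
    """Per-edge raw position counts for one sample; deterministic by seed.

    Returns SJ-style records keyed ``(kind, chrom, ".", start, end)``;
    junction vectors have length ``L - 1``, intron vectors length
    ``L - 1 + intron_length`` (raw positions).
    """
    L = sample.read_length
    out: dict[tuple, np.ndarray] = {}
    for spec in specs:
        rng = np.random.default_rng(_spec_seed(sample.seed, spec.gene_id))
        ab = np.asarray(spec.abundances, dtype=float)
        if sample.heterogeneity > 0:
            conc = ab * (1.0 / sample.heterogeneity**2)
            ab = rng.dirichlet(np.maximum(conc, 1e-6))
        rel = spec.edge_abundance(ab)
        for (kind, s, e), r in sorted(rel.items()):
            npos = (L - 1) if kind == "J" else (L - 1 + (e - s))
            rate = sample.depth * r / (L - 1)
            out[(kind, spec.chrom, ".", s, e)] = rng.poisson(
                rate, size=npos
            ).astype(float)
    return out


def simulate_sample(specs: Sequence[ToyGeneSpec], sample: SampleSpec) -> SJFile:
    """Simulate one experiment's SJ coverage container."""
    sj = SJFile(experiment=sample.name, read_length=sample.read_length)
    sj.records = simulate_positions(specs, sample)
    return sj


def write_sample_sam(specs: Sequence[ToyGeneSpec], sample: SampleSpec,
                     path: str) -> None:
    """Emit the same simulated reads as a minimal SAM file.

    Junction reads are split reads with CIGAR ``{p}M{gap}N{L-p}M`` placed so
    the split occurs at read offset ``p``; intron reads are contiguous
    ``{L}M`` reads.  Coverage extracted from this SAM is identical to the SJ
    container from :func:`simulate_sample` for the same seed.
    """
    L = sample.read_length
    records = simulate_positions(specs, sample)
    chrom_len: dict[str, int] = {}
    for spec in specs:
        _, hi = spec.span
        chrom_len[spec.chrom] = max(chrom_len.get(spec.chrom, 0), hi + L + 1000)

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(chrom_len):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}\n")
        rid = 0
        seq = "A" * L
        for (kind, chrom, _strand, s, e), counts in sorted(records.items()):
            for i, c in enumerate(counts):
                c = int(c)
                if c == 0:
                    continue
                if kind == "J":
                    p = i + 1
                    pos = s - p  # 0-based leftmost
                    cigar = f"{p}M{e - s}N{L - p}M"
                else:
                    if i <= L - 2:
                        pos = s - (i + 1)
                    else:
                        pos = s + (i - (L - 2)) - 1
                    cigar = f"{L}M"
                for _ in range(c):
                    fh.write(f"r{rid}\t0\t{chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0"
                             f"\t{seq}\t*\n")
                    rid += 1
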