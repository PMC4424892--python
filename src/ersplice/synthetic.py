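"""Synthetic study generator with machine-readable planted ground truth.

Emulates the data layout of an estrogen-stimulation RNA-seq study in three
MCF-7-derived cell lines — the parental wt line (ERalpha only) and two
ERbeta-expressing clones (Ct-ERbeta, Nt-ERbeta) — each profiled with and
without a 2 h estradiol (E2) challenge across replicates:

* a transcript annotation with multi-isoform, multi-promoter genes whose
  isoform structures plant enumerable splicing events of all five types;
* negative-binomial gene counts (log-normal library sizes) with planted
  differentially expressed genes following cross-line patterns (lost in
  ERbeta+, gained in ERbeta+, common, opposite direction);
* multinomial isoform counts with planted isoform-ratio switches that run
  in opposite directions in wt versus both ERbeta+ lines, and planted
  promoter switches that flip the dominant TSS group;
* binomial inclusion/skipping junction counts around planted PSI values;
* ERalpha/ERbeta peak BED files placed inside (or outside) the +/-10 kb
  windows of differentially spliced genes.

Every planted effect is recorded in a :class:`GroundTruth` manifest so each
downstream stage can be scored without external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import annotation as ann_io
from .models import BindingSiteSet, GeneModel, TranscriptAnnotation, TranscriptModel
from .splice_events import EFFECTIVE_LENGTHS, SpliceEvent, enumerate_events

LINES = ("wt", "ct_erb", "nt_erb")
CONDITIONS = ("vehicle", "E2")

# cross-line planting patterns and their sampling weights: which lines carry
# the effect and whether the ERbeta+ lines reverse its sign relative to wt
PATTERNS = {
    "lost": (("wt",), False),
    "erb_specific": (("ct_erb", "nt_erb"), False),
    "common": (("wt", "ct_erb", "nt_erb"), False),
    "opposite": (("wt", "ct_erb", "nt_erb"), True),
}
PATTERN_WEIGHTS = {"lost": 0.25, "erb_specific": 0.35, "common": 0.30,
                   "opposite": 0.10}


class ConfigurationError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-shape and effect-size settings for one synthetic run."""

    n_genes: int = 200
    isoforms_per_gene: Tuple[int, int] = (1, 4)  # inclusive uniform range
    n_replicates: int = 3
    depth: float = 500.0            # mean gene-level fragment count
    dispersion: float = 0.05        # NB: var = mu + dispersion * mu^2
    de_fraction: float = 0.3
    de_fold_change: float = 2.0
    ds_fraction: float = 0.3        # fraction of enumerable events planted
    delta_psi_effect: float = 0.3
    junction_depth: float = 300.0   # mean junction reads per event+condition
    switch_fraction: float = 0.2    # of multi-isoform single-TSS genes
    multi_tss_fraction: float = 0.3  # of multi-isoform genes
    promoter_switch_fraction: float = 0.5  # of multi-TSS genes
    event_mix: Dict[str, float] = field(default_factory=lambda: {
        "SE": 0.5, "MXE": 0.1, "A5SS": 0.1, "A3SS": 0.1, "RI": 0.2,
    })
    peak_placement: Dict[str, float] = field(default_factory=lambda: {
        "both": 0.6, "era_only": 0.2, "erb_only": 0.2,
    })
    library_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.isoforms_per_gene
        if not (1 <= lo <= hi <= 9):
            raise ConfigurationError(
                "isoforms_per_gene must satisfy 1 <= min <= max <= 9"
            )
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        for name in ("de_fraction", "ds_fraction", "switch_fraction",
                     "multi_tss_fraction", "promoter_switch_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if set(self.event_mix) - set(EFFECTIVE_LENGTHS):
            raise ConfigurationError("event_mix has unknown event types")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("event_mix must sum to 1")
        if any(v < 0 for v in self.event_mix.values()):
            raise ConfigurationError("event_mix proportions must be >= 0")
        if abs(sum(self.peak_placement.values()) - 1.0) > 1e-9:
            raise ConfigurationError("peak_placement must sum to 1")
        if not (0.0 <= self.delta_psi_effect < 0.5):
            raise ConfigurationError("delta_psi_effect must lie in [0, 0.5)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted effects, keyed by annotation identifiers."""

    de_genes: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {ln: {} for ln in LINES})
    ds_events: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {ln: {} for ln in LINES})
    switch_genes: Dict[str, Dict] = field(default_factory=dict)
    promoter_switch_genes: Dict[str, List[str]] = field(default_factory=dict)
    peak_groups: Dict[str, str] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return (not any(self.de_genes.values())
                and not any(self.ds_events.values())
                and not self.switch_genes
                and not self.promoter_switch_genes
                and not self.peak_groups)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# annotation generation

_CHROMS = ("chr1", "chr2", "chr3")
_GENE_GAP = 30_000          # keeps +/-10 kb windows of neighbours disjoint
_ALT_TSS_OFFSET = 3_000     # alternative first exon this far upstream


def _build_backbone(rng: np.random.Generator, origin: int) -> List[Tuple[int, int]]:
    n_exons = int(rng.integers(5, 9))
    exons = []
    pos = origin
    for _ in range(n_exons):
        length = int(rng.integers(100, 301))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(500, 2001))
    return exons


def _variant_exons(
    backbone: List[Tuple[int, int]],
    etype: str,
    slot: int,
    strand: str,
) -> List[Tuple[int, int]]:
    """Backbone copy carrying one planted splicing event at exon ``slot``."""
    ex = [list(e) for e in backbone]
    if etype == "SE":
        del ex[slot]
    elif etype == "RI":
        ex[slot][1] = ex[slot + 1][1]
        del ex[slot + 1]
    elif etype in ("A5SS", "A3SS"):
        # shift the donor (A5SS) or acceptor (A3SS) side of a splice site;
        # on the minus strand donor/acceptor swap genomic sides
        move_end = (etype == "A5SS") == (strand == "+")
        if move_end:
            ex[slot][1] -= 60
        else:
            ex[slot + 1][0] += 60
    elif etype == "MXE":
        s, e = backbone[slot]
        nxt = backbone[slot + 1][0]
        alt_start = e + 150
        alt_end = min(alt_start + (e - s), nxt - 50)
        ex[slot] = [alt_start, alt_end]
    else:  # pragma: no cover - guarded by config validation
        raise ConfigurationError(f"unknown event type {etype}")
    return [tuple(x) for x in ex]


def generate_annotation(config: SimulationConfig) -> TranscriptAnnotation:
    """Deterministic multi-chromosome annotation with planted events.

    Genes are laid out without overlap on both strands of several
    chromosomes. Isoform 1 is the full exon backbone; each further isoform
    introduces one splicing event (type drawn from ``event_mix``), and in
    multi-TSS genes the last variant additionally starts from an
    alternative upstream first exon (plus a cassette skip so the gene stays
    event-bearing even with two isoforms).
    """
    rng = config.rng(1)
    genes: Dict[str, GeneModel] = {}
    cursors = {c: 20_000 for c in _CHROMS}
    lo, hi = config.isoforms_per_gene
    etypes = sorted(config.event_mix)
    eprobs = np.array([config.event_mix[t] for t in etypes])

    for i in range(config.n_genes):
        gid = f"G{i + 1:05d}"
        chrom = _CHROMS[i % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        origin = cursors[chrom]
        backbone = _build_backbone(rng, origin)
        n_iso = int(rng.integers(lo, hi + 1))
        multi_tss = n_iso >= 2 and rng.random() < config.multi_tss_fraction

        gene = GeneModel(gid, chrom, strand)
        gene.add_transcript(
            TranscriptModel(f"{gid}.t01", gid, chrom, strand, backbone)
        )
        used_slots: List[int] = []
        for k in range(2, n_iso + 1):
            tid = f"{gid}.t{k:02d}"
            is_tss_variant = multi_tss and k == n_iso
            if is_tss_variant:
                # alternative promoter + cassette skip away from the 5' end
                slot = int(rng.integers(2, len(backbone) - 1))
                exons = [list(e) for e in backbone]
                del exons[slot]
                first_len = int(rng.integers(100, 201))
                if strand == "+":
                    alt_start = backbone[0][0] - _ALT_TSS_OFFSET - first_len
                    exons[0] = [alt_start, alt_start + first_len]
                else:
                    alt_end = backbone[-1][1] + _ALT_TSS_OFFSET + first_len
                    exons[-1] = [alt_end - first_len, alt_end]
                exons = [tuple(x) for x in exons]
            else:
                etype = str(rng.choice(etypes, p=eprobs))
                free = [s for s in range(1, len(backbone) - 1)
                        if s not in used_slots]
                if not free:
                    continue
                slot = int(rng.choice(free))
                used_slots.append(slot)
                exons = _variant_exons(backbone, etype, slot, strand)
            gene.add_transcript(
                TranscriptModel(tid, gid, chrom, strand, exons)
            )
        genes[gid] = gene
        span = gene.span
        cursors[chrom] = span[1] + _GENE_GAP

    annotation = TranscriptAnnotation(genes=genes)
    ann_io.group_by_tss(annotation)
    return annotation


# ---------------------------------------------------------------------------
# truth planting

def plant_truth(annotation: TranscriptAnnotation, config: SimulationConfig) -> GroundTruth:
    """Assign planted effects to genes/events of an existing annotation."""
    rng = config.rng(2)
    truth = GroundTruth()
    gids = sorted(annotation.genes)
    events = enumerate_events(annotation)

    multi_iso = [g for g in gids if len(annotation.genes[g].transcripts) >= 2]
    multi_tss = [
        g for g in multi_iso
        if len(annotation.genes[g].tss_groups()) >= 2
    ]
    single_tss_multi_iso = [g for g in multi_iso if g not in set(multi_tss)]

    pat_names = sorted(PATTERN_WEIGHTS)
    pat_probs = np.array([PATTERN_WEIGHTS[p] for p in pat_names])

    def draw_pattern() -> Tuple[Tuple[str, ...], bool]:
        return PATTERNS[str(rng.choice(pat_names, p=pat_probs))]

    # isoform-ratio switch genes (always affect wt one way, ERbeta+ the other)
    n_switch = int(round(config.switch_fraction * len(single_tss_multi_iso)))
    switch_genes = list(rng.choice(single_tss_multi_iso, size=n_switch,
                                   replace=False)) if n_switch else []
    for g in sorted(switch_genes):
        txs = sorted(annotation.genes[g].transcripts)
        focal = txs[1]
        wt_sign = 1 if rng.random() < 0.5 else -1
        truth.switch_genes[g] = {
            "focal_isoform": focal,
            "signs": {"wt": wt_sign, "ct_erb": -wt_sign, "nt_erb": -wt_sign},
        }

    # promoter-switch genes: flip dominant TSS group in the pattern's lines
    n_prom = int(round(config.promoter_switch_fraction * len(multi_tss)))
    prom_genes = list(rng.choice(multi_tss, size=n_prom,
                                 replace=False)) if n_prom else []
    for g in sorted(prom_genes):
        lines, _ = draw_pattern()
        truth.promoter_switch_genes[g] = list(lines)

    # DE genes, excluding switch-planted genes to keep effects orthogonal
    reserved = set(switch_genes) | set(prom_genes)
    de_pool = [g for g in gids if g not in reserved]
    n_de = int(round(config.de_fraction * len(de_pool)))
    de_genes = list(rng.choice(de_pool, size=n_de, replace=False)) if n_de else []
    for g in sorted(de_genes):
        lines, flip = draw_pattern()
        sign = 1 if rng.random() < 0.5 else -1
        for ln in lines:
            s = -sign if (flip and ln != "wt") else sign
            truth.de_genes[ln][g] = s

    # differentially spliced events; events in switch genes are always
    # planted (criterion iv requires a significant event there) with signs
    # matching the ratio switch
    if config.delta_psi_effect > 0:
        switch_set = set(switch_genes)
        keys = sorted(str(ev.key) for ev in events.values())
        ev_by_key = {str(ev.key): ev for ev in events.values()}
        free_keys = [k for k in keys if ev_by_key[k].gene_id not in switch_set]
        n_ds = int(round(config.ds_fraction * len(free_keys)))
        ds_keys = list(rng.choice(free_keys, size=n_ds,
                                  replace=False)) if n_ds else []
        for k in sorted(ds_keys):
            lines, flip = draw_pattern()
            sign = 1 if rng.random() < 0.5 else -1
            for ln in lines:
                s = -sign if (flip and ln != "wt") else sign
                truth.ds_events[ln][k] = s * config.delta_psi_effect
        covered = set()
        for k in keys:
            g = ev_by_key[k].gene_id
            if g in switch_set and g not in covered:
                covered.add(g)
                for ln, s in truth.switch_genes[g]["signs"].items():
                    truth.ds_events[ln][k] = s * config.delta_psi_effect

    # peak groups for every gene with a planted splicing change
    by_key = {str(ev.key): ev for ev in events.values()}
    dsg_genes = sorted(
        {by_key[k].gene_id for ln in LINES for k in truth.ds_events[ln]}
    )
    cats = sorted(config.peak_placement)
    cat_probs = np.array([config.peak_placement[c] for c in cats])
    for g in dsg_genes:
        truth.peak_groups[g] = str(rng.choice(cats, p=cat_probs))
    return truth


# ---------------------------------------------------------------------------
# count simulation

@dataclass
class SimulatedDataset:
    annotation: TranscriptAnnotation
    truth: GroundTruth
    config: SimulationConfig
    gene_counts: pd.DataFrame
    isoform_counts: pd.DataFrame
    junction_counts: pd.DataFrame
    library_sizes: pd.DataFrame
    era_peaks: BindingSiteSet
    erb_peaks: BindingSiteSet


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def _base_weights(rng: np.random.Generator, n_iso: int) -> np.ndarray:
    w = rng.dirichlet(np.full(n_iso, 5.0))
    return np.sort(w)[::-1]  # dominant isoform first (transcript .t01)


def _isoform_fractions(
    gene: GeneModel,
    line: str,
    condition: str,
    base: np.ndarray,
    truth: GroundTruth,
) -> np.ndarray:
    txs = sorted(gene.transcripts)
    frac = base.copy()
    g = gene.gene_id

    sw = truth.switch_genes.get(g)
    if sw is not None:
        focal_idx = txs.index(sw["focal_isoform"])
        sign = sw["signs"][line]
        lo_share, hi_share = 0.20, 0.45
        if condition == "vehicle":
            share = lo_share if sign > 0 else hi_share
        else:
            share = hi_share if sign > 0 else lo_share
        others = np.delete(np.arange(len(txs)), focal_idx)
        rest = base[others] / base[others].sum() * (1.0 - share)
        frac = np.empty_like(base)
        frac[focal_idx] = share
        frac[others] = rest
        return frac

    lines_affected = truth.promoter_switch_genes.get(g)
    if lines_affected and line in lines_affected:
        groups = gene.tss_groups()
        labels = sorted(groups)
        alt_label = labels[-1]  # the alternative-promoter group
        alt_idx = np.array([
            txs.index(t.transcript_id) for t in groups[alt_label]
        ])
        main_idx = np.array([i for i in range(len(txs)) if i not in set(alt_idx)])
        alt_share = 0.8 if condition == "vehicle" else 0.2
        frac = np.empty_like(base)
        frac[alt_idx] = base[alt_idx] / base[alt_idx].sum() * alt_share
        frac[main_idx] = base[main_idx] / base[main_idx].sum() * (1 - alt_share)
        return frac
    return frac


def simulate_counts(
    annotation: TranscriptAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> SimulatedDataset:
    """Draw replicate count tables and junction counts under the truth."""
    _check_truth(annotation, truth)
    rng = config.rng(3)
    gids = sorted(annotation.genes)
    events = enumerate_events(annotation)
    ev_keys = sorted(str(ev.key) for ev in events.values())
    ev_by_key = {str(ev.key): ev for ev in events.values()}

    gene_mu = {
        g: config.depth * float(np.exp(rng.normal(0.0, 0.5))) for g in gids
    }
    base_w = {
        g: _base_weights(rng, len(annotation.genes[g].transcripts))
        for g in gids
    }
    base_psi = {
        k: float(rng.uniform(0.35, 0.65)) if _planted_anywhere(k, truth)
        else float(rng.uniform(0.2, 0.8))
        for k in ev_keys
    }

    gene_rows, iso_rows, junc_rows, lib_rows = [], [], [], []
    for line in LINES:
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                lib_factor = float(np.exp(rng.normal(0.0, config.library_sigma)))
                total = 0
                for g in gids:
                    gene = annotation.genes[g]
                    mu = gene_mu[g] * lib_factor
                    sign = truth.de_genes[line].get(g)
                    if sign is not None and cond == "E2":
                        mu *= config.de_fold_change ** sign
                    count = _nb_draw(rng, mu, config.dispersion)
                    frac = _isoform_fractions(
                        gene, line, cond, base_w[g], truth
                    )
                    iso_counts = rng.multinomial(count, frac)
                    count = int(iso_counts.sum())
                    total += count
                    gene_rows.append((g, line, cond, rep, count))
                    for tid, c in zip(sorted(gene.transcripts), iso_counts):
                        iso_rows.append((tid, line, cond, rep, int(c)))
                lib_rows.append((line, cond, rep, total))
                for k in ev_keys:
                    ev = ev_by_key[k]
                    psi_val = base_psi[k]
                    if cond == "E2":
                        psi_val += truth.ds_events[line].get(k, 0.0)
                    psi_val = min(max(psi_val, 0.01), 0.99)
                    li, ls = EFFECTIVE_LENGTHS[ev.event_type]
                    theta = psi_val * li / (psi_val * li + (1 - psi_val) * ls)
                    n = int(rng.poisson(config.junction_depth
                                        / config.n_replicates))
                    ijc = int(rng.binomial(n, theta)) if n else 0
                    junc_rows.append(
                        (k, ev.event_type, ev.gene_id, line, cond, rep,
                         ijc, n - ijc)
                    )

    era, erb = _place_peaks(annotation, truth)
    cols = ["feature_id", "cell_line", "condition", "replicate", "count"]
    return SimulatedDataset(
        annotation=annotation, truth=truth, config=config,
        gene_counts=pd.DataFrame(gene_rows, columns=cols),
        isoform_counts=pd.DataFrame(iso_rows, columns=cols),
        junction_counts=pd.DataFrame(
            junc_rows,
            columns=["event_key", "event_type", "gene_id", "cell_line",
                     "condition", "replicate", "ijc", "sjc"],
        ),
        library_sizes=pd.DataFrame(
            lib_rows,
            columns=["cell_line", "condition", "replicate", "library_size"],
        ),
        era_peaks=era, erb_peaks=erb,
    )


def _planted_anywhere(key: str, truth: GroundTruth) -> bool:
    return any(key in truth.ds_events[ln] for ln in LINES)


def _check_truth(annotation: TranscriptAnnotation, truth: GroundTruth) -> None:
    events = {str(ev.key) for ev in enumerate_events(annotation).values()}
    for ln in LINES:
        for g in truth.de_genes.get(ln, {}):
            if g not in annotation.genes:
                raise ConsistencyError(f"truth DE gene {g} not in annotation")
        for k in truth.ds_events.get(ln, {}):
            if k not in events:
                raise ConsistencyError(f"truth event {k} not enumerable")
    for g, info in truth.switch_genes.items():
        gene = annotation.genes.get(g)
        if gene is None:
            raise ConsistencyError(f"truth switch gene {g} not in annotation")
        if len(gene.transcripts) < 2:
            raise ConsistencyError(f"switch gene {g} has < 2 isoforms")
        if info["focal_isoform"] not in gene.transcripts:
            raise ConsistencyError(
                f"switch gene {g}: unknown focal isoform "
                f"{info['focal_isoform']}"
            )
    for g in truth.promoter_switch_genes:
        if g not in annotation.genes:
            raise ConsistencyError(f"truth promoter gene {g} not in annotation")
    for g in truth.peak_groups:
        if g not in annotation.genes:
            raise ConsistencyError(f"truth peak gene {g} not in annotation")


# ---------------------------------------------------------------------------
# peaks

_PEAK_WIDTH = 200
_PEAK_OFFSET = 5_000   # inside the +/-10 kb window


def _place_peaks(
    annotation: TranscriptAnnotation, truth: GroundTruth
) -> Tuple[BindingSiteSet, BindingSiteSet]:
    era: Dict[str, List[Tuple[int, int]]] = {}
    erb: Dict[str, List[Tuple[int, int]]] = {}
    for g, cat in sorted(truth.peak_groups.items()):
        gene = annotation.genes[g]
        s, e = gene.span
        up = (max(0, s - _PEAK_OFFSET - _PEAK_WIDTH), max(1, s - _PEAK_OFFSET))
        dn = (e + _PEAK_OFFSET, e + _PEAK_OFFSET + _PEAK_WIDTH)
        if cat in ("both", "era_only"):
            era.setdefault(gene.chrom, []).append(up)
        if cat in ("both", "erb_only"):
            erb.setdefault(gene.chrom, []).append(dn)
    # background peaks in inter-gene gaps, outside every +/-10 kb window
    spans = sorted(
        (g.chrom, *g.span) for g in annotation.genes.values()
    )
    for (c1, _, e1), (c2, s2, _) in zip(spans, spans[1:]):
        if c1 != c2 or s2 - e1 < 2 * 10_000 + 2 * _PEAK_WIDTH + 2000:
            continue
        mid = (e1 + 10_000 + s2 - 10_000) // 2
        era.setdefault(c1, []).append((mid - _PEAK_WIDTH, mid))
        erb.setdefault(c1, []).append((mid + 500, mid + 500 + _PEAK_WIDTH))
    return (BindingSiteSet("era", era), BindingSiteSet("erb", erb))


# ---------------------------------------------------------------------------
# fixture writing and the one-call convenience front end

def simulate(config: SimulationConfig) -> SimulatedDataset:
    """generate_annotation -> plant_truth -> simulate_counts in one call."""
    annotation = generate_annotation(config)
    truth = plant_truth(annotation, config)
    return simulate_counts(annotation, truth, config)


def write_fixture(dataset: SimulatedDataset, outdir) -> Dict[str, Path]:
    """Write GTF + count TSVs + two BEDs + truth JSON; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "gene_counts": out / "gene_counts.tsv",
        "isoform_counts": out / "isoform_counts.tsv",
        "junction_counts": out / "junction_counts.tsv",
        "era_peaks": out / "peaks_era.bed",
        "erb_peaks": out / "peaks_erb.bed",
        "truth": out / "truth.json",
    }
    ann_io.write_annotation(dataset.annotation, paths["gtf"])
    dataset.gene_counts.to_csv(paths["gene_counts"], sep="\t", index=False)
    dataset.isoform_counts.to_csv(paths["isoform_counts"], sep="\t", index=False)
    dataset.junction_counts.to_csv(paths["junction_counts"], sep="\t",
                                   index=False)
    ann_io.write_peaks(dataset.era_peaks, paths["era_peaks"])
    ann_io.write_peaks(dataset.erb_peaks, paths["erb_peaks"])
    paths["truth"].write_text(dataset.truth.to_json())
    return paths
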