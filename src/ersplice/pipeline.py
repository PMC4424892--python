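"""End-to-end orchestration: files in, per-stage tables and a summary out.

Stages: FPKM normalization and regulation calls per cell line (genes and
isoforms) -> three-way regulon comparison -> splice-event enumeration and
per-line differential-inclusion calls -> isoform-ratio switch classification
-> promoter-switch and within-promoter (DSG) divergence tests with set logic
-> ER-binding window annotation of the DSGs shared by both ERbeta+ lines.

All thresholds default to the study's printed values (FPKM >= 0.5,
q <= 0.05, |FC| >= 1.3, PSI cutoff c = 0.1, event FDR <= 0.05, 10
ratio percentage points, +/-10 kb binding windows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_io
from . import binding, cross_line, quantify, splice_events, switches
from .models import TranscriptAnnotation

log = logging.getLogger("ersplice")

LINES = ("wt", "ct_erb", "nt_erb")
CONDITIONS = ("vehicle", "E2")


@dataclass
class PipelineConfig:
    gtf: str = ""
    gene_counts: str = ""
    isoform_counts: str = ""
    junction_counts: str = ""
    era_peaks: str = ""
    erb_peaks: str = ""
    outdir: str = "ersplice_run"
    fpkm_min: float = 0.5
    q_max: float = 0.05
    fc_min: float = 1.3
    psi_c: float = 0.1
    event_fdr: float = 0.05
    ratio_points: float = 10.0
    switch_use_q: bool = False  # criterion (ii): p <= 0.05 as printed, or q
    window_bp: int = 10_000
    tss_tolerance_bp: int = 50
    n_perm: int = 999
    seed: int = 0
    cell_lines: Tuple[str, str, str] = LINES
    conditions: Tuple[str, str] = CONDITIONS

    def __post_init__(self) -> None:
        if len(self.cell_lines) != 3:
            raise ValueError("exactly three cell lines are required")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        for name in ("fpkm_min", "q_max", "fc_min", "event_fdr",
                     "ratio_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.psi_c < 1):
            raise ValueError("psi_c must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("cell_lines", "conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # output location is not analysis identity
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_inputs(config: PipelineConfig) -> List[Dict[str, str]]:
    """Machine-readable issue list; empty means the inputs look consistent."""
    issues: List[Dict[str, str]] = []
    paths = {
        "gtf": config.gtf, "gene_counts": config.gene_counts,
        "isoform_counts": config.isoform_counts,
        "junction_counts": config.junction_counts,
        "era_peaks": config.era_peaks, "erb_peaks": config.erb_peaks,
    }
    for name, p in paths.items():
        if not p or not Path(p).exists():
            issues.append({"kind": "missing_file", "input": name,
                           "detail": str(p)})
    if issues:
        return issues

    annotation = ann_io.load_annotation(config.gtf)
    gtf_chroms = set(annotation.chroms())
    for name in ("era_peaks", "erb_peaks"):
        peaks = ann_io.load_peaks(paths[name], name)
        bad = set(peaks.intervals) - gtf_chroms
        if bad:
            issues.append({
                "kind": "chromosome_mismatch", "input": name,
                "detail": f"BED chroms {sorted(bad)} absent from GTF "
                          f"chroms {sorted(gtf_chroms)}",
            })
    expected = ["feature_id", "cell_line", "condition", "replicate", "count"]
    for name in ("gene_counts", "isoform_counts"):
        df = pd.read_csv(paths[name], sep="\t", nrows=5)
        missing = [c for c in expected if c not in df.columns]
        if missing:
            issues.append({"kind": "schema", "input": name,
                           "detail": f"missing columns {missing}"})
    jdf = pd.read_csv(paths["junction_counts"], sep="\t", nrows=5)
    missing = [c for c in ("event_key", "cell_line", "condition",
                           "replicate", "ijc", "sjc") if c not in jdf.columns]
    if missing:
        issues.append({"kind": "schema", "input": "junction_counts",
                       "detail": f"missing columns {missing}"})
    if not issues:
        counts = pd.read_csv(paths["gene_counts"], sep="\t")
        got_lines = set(counts["cell_line"])
        for line in config.cell_lines:
            if line not in got_lines:
                issues.append({"kind": "missing_cell_line",
                               "input": "gene_counts", "detail": line})
        reps = counts.groupby(["cell_line", "condition"])["replicate"].nunique()
        if reps.nunique() > 1:
            issues.append({"kind": "unbalanced_replicates",
                           "input": "gene_counts",
                           "detail": reps.to_dict().__repr__()})
    return issues


# ---------------------------------------------------------------------------
# stage helpers (usable directly from library code)

def fpkm_table(
    counts: pd.DataFrame,
    lengths: Dict[str, int],
    library_sizes: pd.DataFrame,
) -> pd.DataFrame:
    """Long-form FPKM from a long-form count table.

    ``library_sizes`` has columns cell_line, condition, replicate,
    library_size; ``lengths`` maps feature id -> effective length in bp.
    """
    df = counts.merge(library_sizes, on=["cell_line", "condition", "replicate"])
    missing = set(df["feature_id"]) - set(lengths)
    if missing:
        raise KeyError(
            f"no effective length for features {sorted(missing)[:5]}"
        )
    lens = df["feature_id"].map(lengths).astype(float)
    df["fpkm"] = 1e9 * df["count"] / (df["library_size"] * lens)
    return df


def library_sizes_from(gene_counts: pd.DataFrame) -> pd.DataFrame:
    sizes = (gene_counts.groupby(["cell_line", "condition", "replicate"])
             ["count"].sum().reset_index(name="library_size"))
    return sizes


def regulation_calls_per_line(
    fpkm_df: pd.DataFrame, config: PipelineConfig
) -> Dict[str, pd.DataFrame]:
    calls = {}
    veh, e2 = config.conditions
    for line in config.cell_lines:
        sub = fpkm_df[fpkm_df["cell_line"] == line]
        calls[line] = quantify.call_regulation(
            sub, fpkm_min=config.fpkm_min, q_max=config.q_max,
            fc_min=config.fc_min, vehicle_label=veh, e2_label=e2,
        )
    return calls


def _gene_matrices(
    iso_fpkm: pd.DataFrame, annotation: TranscriptAnnotation, line: str,
    conditions: Tuple[str, str],
) -> Dict[str, Dict]:
    """Per-gene isoform count/abundance matrices for the divergence tests."""
    sub = iso_fpkm[iso_fpkm["cell_line"] == line]
    piv = sub.pivot_table(index="feature_id", columns=["condition", "replicate"],
                          values="count", aggfunc="first")
    out = {}
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        tids = sorted(gene.transcripts)
        if len(tids) < 2 or any(t not in piv.index for t in tids):
            continue
        mats = {}
        for cond in conditions:
            mats[cond] = piv.loc[tids, cond].to_numpy(dtype=float)
        weights = np.array([
            1.0 / gene.transcripts[t].length for t in tids
        ])
        groups = [gene.transcripts[t].tss_group for t in tids]
        out[gid] = dict(tids=tids, mats=mats, weights=weights, groups=groups)
    return out


def tss_group_count_matrices(
    iso_counts: pd.DataFrame,
    annotation: TranscriptAnnotation,
    line: str,
    conditions: Tuple[str, str] = CONDITIONS,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-gene (vehicle, E2) TSS-group count matrices for one cell line.

    Only genes with >= 2 promoter groups are returned; rows are TSS groups
    in label order, columns replicates.
    """
    per_gene = _gene_matrices(iso_counts, annotation, line, conditions)
    out = {}
    for gid, info in per_gene.items():
        labels = sorted(set(info["groups"]))
        if len(labels) < 2:
            continue
        groups = np.asarray(info["groups"])
        mats = []
        for cond in conditions:
            m = info["mats"][cond]
            mats.append(np.vstack([
                m[groups == lab].sum(axis=0) for lab in labels
            ]))
        out[gid] = (mats[0], mats[1])
    return out


def promoter_and_dsg_tests(
    iso_counts: pd.DataFrame,
    annotation: TranscriptAnnotation,
    config: PipelineConfig,
) -> Tuple[Dict[str, pd.DataFrame], Dict[str, pd.DataFrame]]:
    """Per-line promoter-switch and DSG call tables."""
    veh, e2 = config.conditions
    prom, dsg = {}, {}
    for li_idx, line in enumerate(config.cell_lines):
        per_gene = _gene_matrices(iso_counts, annotation, line,
                                  config.conditions)
        prom_res, dsg_res = {}, {}
        for gid, info in per_gene.items():
            rng = np.random.default_rng(
                [config.seed, 7, li_idx, _gene_stream(gid)]
            )
            groups = np.asarray(info["groups"])
            cv, ce = info["mats"][veh], info["mats"][e2]
            if len(set(info["groups"])) >= 2:
                g_labels = sorted(set(info["groups"]))
                gv = np.vstack([
                    cv[groups == g].sum(axis=0) for g in g_labels
                ])
                ge = np.vstack([
                    ce[groups == g].sum(axis=0) for g in g_labels
                ])
                prom_res[gid] = switches.promoter_switch_test(
                    gv, ge, n_perm=config.n_perm, rng=rng,
                )
            dsg_res[gid] = switches.dsg_test(
                cv, ce, info["groups"], weights=info["weights"],
                n_perm=config.n_perm, rng=rng,
            )
        prom[line] = switches.divergence_table(prom_res, alpha=config.q_max)
        dsg[line] = switches.divergence_table(dsg_res, alpha=config.q_max,
                                              strict=True)
    return prom, dsg


def _gene_stream(gid: str) -> int:
    return int(hashlib.sha256(gid.encode()).hexdigest()[:8], 16)


def classify_switches(
    iso_fpkm: pd.DataFrame,
    annotation: TranscriptAnnotation,
    iso_calls: Dict[str, pd.DataFrame],
    event_calls: Dict[str, pd.DataFrame],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Four-criterion switch classification for every multi-isoform gene."""
    veh, e2 = config.conditions
    tx_index = annotation.transcript_index()
    gene_of = {t: tx_index[t].gene_id for t in tx_index}

    mean_fpkm = (iso_fpkm.groupby(["feature_id", "cell_line", "condition"])
                 ["fpkm"].mean().reset_index())
    mean_fpkm["gene_id"] = mean_fpkm["feature_id"].map(gene_of)
    gene_fpkm = (mean_fpkm.groupby(["gene_id", "cell_line", "condition"])
                 ["fpkm"].sum().rename("gene_fpkm").reset_index())
    merged = mean_fpkm.merge(gene_fpkm, on=["gene_id", "cell_line",
                                            "condition"])
    merged["ratio"] = np.where(
        merged["gene_fpkm"] > 0,
        100.0 * merged["fpkm"] / merged["gene_fpkm"], np.nan,
    )
    piv = merged.pivot_table(
        index=["gene_id", "feature_id", "cell_line"], columns="condition",
        values="ratio", aggfunc="first",
    ).reset_index()
    piv["dratio"] = piv[e2] - piv[veh]
    ratios = piv.rename(columns={"feature_id": "isoform_id"})

    # criterion (ii) gate: per the figure legend, p <= 0.05 with |FC| >= 1.3
    # on an expressed isoform (switch_use_q swaps in the BH q gate instead)
    iso_sig = {}
    for line, df in iso_calls.items():
        stat = df["q"] if config.switch_use_q else df["p"]
        ok = df["expressed"] & (stat <= 0.05) & (df["fc"] >= config.fc_min)
        iso_sig[line] = dict(zip(df["feature_id"], ok.fillna(False)))
    genes_with_event = {
        line: set(df.loc[df["significant"], "gene_id"])
        for line, df in event_calls.items()
    }
    rows = []
    for gid, sub in ratios.groupby("gene_id"):
        if sub["isoform_id"].nunique() < 2 or sub["dratio"].isna().any():
            continue
        call = switches.classify_switch(
            gid, sub, iso_sig,
            {line: gid in genes_with_event[line] for line in config.cell_lines},
            ratio_points=config.ratio_points, lines=config.cell_lines,
        )
        rows.append(dict(
            gene_id=gid, criterion_i=call.criterion_i,
            criterion_ii=call.criterion_ii, criterion_iii=call.criterion_iii,
            criterion_iv=call.criterion_iv, passes=call.passes,
        ))
    cols = ["gene_id", "criterion_i", "criterion_ii", "criterion_iii",
            "criterion_iv", "passes"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# the runner

def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage, write stage outputs + summary JSON, return summary."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    issues = validate_inputs(config)
    if issues:
        raise ValueError(f"input validation failed: {issues}")

    log.info("config %s seed %d", config.digest(), config.seed)
    annotation = ann_io.load_annotation(config.gtf)
    ann_io.group_by_tss(annotation, tolerance_bp=config.tss_tolerance_bp)

    gene_counts = pd.read_csv(config.gene_counts, sep="\t")
    iso_counts = pd.read_csv(config.isoform_counts, sep="\t")
    junctions = pd.read_csv(config.junction_counts, sep="\t")
    lib = library_sizes_from(gene_counts)

    gene_lengths = {g: annotation.genes[g].length for g in annotation.genes}
    iso_lengths = {t.transcript_id: t.length for t in annotation.transcripts()}
    gene_fpkm = fpkm_table(gene_counts, gene_lengths, lib)
    iso_fpkm = fpkm_table(iso_counts, iso_lengths, lib)

    gene_calls = regulation_calls_per_line(gene_fpkm, config)
    iso_calls = regulation_calls_per_line(iso_fpkm, config)
    for line in config.cell_lines:
        gene_calls[line].to_csv(outdir / f"regulation_genes_{line}.tsv",
                                sep="\t", index=False)
        iso_calls[line].to_csv(outdir / f"regulation_isoforms_{line}.tsv",
                               sep="\t", index=False)

    wt, ct, nt = config.cell_lines
    comparison = cross_line.compare_regulons(
        gene_calls[wt], gene_calls[ct], gene_calls[nt]
    )

    events = splice_events.enumerate_events(annotation)
    event_calls = {}
    for line in config.cell_lines:
        sub = junctions[junctions["cell_line"] == line]
        event_calls[line] = splice_events.call_events(
            sub, events, c=config.psi_c, alpha=config.event_fdr,
            vehicle_label=config.conditions[0], e2_label=config.conditions[1],
        )
        event_calls[line].to_csv(outdir / f"splice_events_{line}.tsv",
                                 sep="\t", index=False)
    common_events, opposite_events = splice_events.compare_events_across_lines(
        event_calls[wt], event_calls[ct], event_calls[nt]
    )

    switch_table = classify_switches(iso_fpkm, annotation, iso_calls,
                                     event_calls, config)
    switch_table.to_csv(outdir / "switch_calls.tsv", sep="\t", index=False)

    iso_counts_fpkm = iso_counts.merge(
        iso_fpkm[["feature_id", "cell_line", "condition", "replicate",
                  "fpkm"]],
        on=["feature_id", "cell_line", "condition", "replicate"],
    )
    prom, dsg = promoter_and_dsg_tests(iso_counts_fpkm, annotation, config)
    for line in config.cell_lines:
        prom[line].to_csv(outdir / f"promoter_switch_{line}.tsv", sep="\t",
                          index=False)
        dsg[line].to_csv(outdir / f"dsg_{line}.tsv", sep="\t", index=False)
    prom_sets = switches.switch_set_logic(prom, lines=config.cell_lines)
    dsg_sets = switches.switch_set_logic(dsg, lines=config.cell_lines)

    # DSGs found in both ERbeta+ lines, annotated with ER binding windows
    dsg_both_erb = sorted(
        set(dsg[ct].loc[dsg[ct]["significant"], "gene_id"])
        & set(dsg[nt].loc[dsg[nt]["significant"], "gene_id"])
    )
    era = ann_io.load_peaks(config.era_peaks, "era")
    erb = ann_io.load_peaks(config.erb_peaks, "erb")
    dsg_binding = binding.annotate_dsg_binding(
        [annotation.genes[g] for g in dsg_both_erb], era, erb,
        flank_bp=config.window_bp,
    )
    dsg_binding.to_csv(outdir / "dsg_binding.tsv", sep="\t", index=False)

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_genes": len(annotation.genes),
        "n_events_enumerated": len(events),
        "regulated_genes": {
            line: int(gene_calls[line]["significant"].sum())
            for line in config.cell_lines
        },
        "regulon_sets": comparison.counts(),
        "significant_events": {
            line: int(event_calls[line]["significant"].sum())
            for line in config.cell_lines
        },
        "events_by_type": {
            line: event_calls[line]
            .loc[event_calls[line]["significant"], "event_type"]
            .value_counts().to_dict()
            for line in config.cell_lines
        },
        "common_events": len(common_events),
        "opposite_events": len(opposite_events),
        "switch_genes": int(switch_table["passes"].sum()),
        "promoter_switch_genes": {
            line: int(prom[line]["significant"].sum())
            for line in config.cell_lines
        },
        "promoter_switch_sets": {k: len(v) for k, v in prom_sets.items()},
        "dsg": {
            line: int(dsg[line]["significant"].sum())
            for line in config.cell_lines
        },
        "dsg_sets": {k: len(v) for k, v in dsg_sets.items()},
        "dsg_binding_groups": binding.group_counts(dsg_binding),
        "wall_time_s": round(time.time() - t0, 2),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    return summary
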