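"""Alternative-splicing event enumeration and differential inclusion tests.

Events are enumerated from pairwise comparison of a gene's transcript
structures and typed as SE (skipped/cassette exon), MXE (mutually exclusive
exons), A5SS / A3SS (alternative donor / acceptor) or RI (retained intron).
Inclusion levels (PSI, the fraction of transcripts including the alternative
region) are estimated from length-normalized inclusion/skipping junction
counts, and each event is tested per cell line with a binomial
likelihood-ratio test against the interval null |delta PSI| <= c, mirroring
the MATS-style cutoff c = 0.1 with FDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import GeneModel, TranscriptAnnotation, TranscriptModel
from .quantify import bh_fdr

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

# junction-position counts contributing to inclusion vs skipping per type:
# SE has two inclusion junctions and one skipping junction, etc.
EFFECTIVE_LENGTHS: Dict[str, Tuple[int, int]] = {
    "SE": (2, 1),
    "MXE": (2, 2),
    "A5SS": (1, 1),
    "A3SS": (1, 1),
    "RI": (2, 1),
}


@dataclass(frozen=True)
class SpliceEvent:
    """One typed splicing event keyed by its genomic coordinates."""

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coords: Tuple[int, ...]

    @property
    def key(self) -> Tuple:
        # cell-line independent identity: same coordinates -> same event
        return (self.chrom, self.strand, self.event_type, self.coords)

    @property
    def inclusion_length(self) -> int:
        return EFFECTIVE_LENGTHS[self.event_type][0]

    @property
    def skipping_length(self) -> int:
        return EFFECTIVE_LENGTHS[self.event_type][1]


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _pairwise_events(t1: TranscriptModel, t2: TranscriptModel) -> List[SpliceEvent]:
    """All events distinguishable between two isoforms of one gene."""
    out: List[SpliceEvent] = []
    gene, chrom, strand = t1.gene_id, t1.chrom, t1.strand
    e1, e2 = t1.exons, t2.exons
    set1, set2 = set(e1), set(e2)
    introns1, introns2 = set(t1.introns()), set(t2.introns())

    def emit(etype: str, coords: Tuple[int, ...]) -> None:
        out.append(SpliceEvent(etype, gene, chrom, strand, coords))

    # SE: internal exon of one isoform absent from the other, whose flanking
    # intron pair collapses to a single intron in the skipping isoform
    for inc, skp, inc_introns, skp_introns in (
        (e1, set2, t1.introns(), introns2),
        (e2, set1, t2.introns(), introns1),
    ):
        for i in range(1, len(inc) - 1):
            ex = inc[i]
            if ex in skp:
                continue
            up_intron = (inc[i - 1][1], ex[0])
            dn_intron = (ex[1], inc[i + 1][0])
            if (up_intron[0], dn_intron[1]) in skp_introns:
                emit("SE", (up_intron[0], ex[0], ex[1], dn_intron[1]))

    # RI: an intron of one isoform lies strictly inside a single exon of the
    # other (the retaining isoform fuses the two flanking exons)
    for retained_exons, spliced in ((set2, t1), (set1, t2)):
        for intron in spliced.introns():
            for ex in retained_exons:
                if ex[0] < intron[0] and intron[1] < ex[1]:
                    emit("RI", (ex[0], intron[0], intron[1], ex[1]))

    # A5SS / A3SS: introns sharing one boundary while the exons at the
    # differing boundary still overlap (a donor/acceptor shift, not a skip)
    for i1 in introns1:
        for i2 in introns2:
            if i1 == i2:
                continue
            if i1[1] == i2[1] and i1[0] != i2[0]:
                up1 = next(ex for ex in e1 if ex[1] == i1[0])
                up2 = next(ex for ex in e2 if ex[1] == i2[0])
                if _overlap(up1, up2):
                    lo, hi = sorted((i1[0], i2[0]))
                    etype = "A5SS" if strand == "+" else "A3SS"
                    emit(etype, (lo, hi, i1[1]))
            elif i1[0] == i2[0] and i1[1] != i2[1]:
                dn1 = next(ex for ex in e1 if ex[0] == i1[1])
                dn2 = next(ex for ex in e2 if ex[0] == i2[1])
                if _overlap(dn1, dn2):
                    lo, hi = sorted((i1[1], i2[1]))
                    etype = "A3SS" if strand == "+" else "A5SS"
                    emit(etype, (i1[0], lo, hi))

    # MXE: distinct non-overlapping internal exons sharing both flanking
    # splice boundaries across the two isoforms
    for i in range(1, len(e1) - 1):
        ex_a = e1[i]
        if ex_a in set2:
            continue
        up_a, dn_a = e1[i - 1][1], e1[i + 1][0]
        for j in range(1, len(e2) - 1):
            ex_b = e2[j]
            if ex_b in set1 or _overlap(ex_a, ex_b):
                continue
            up_b, dn_b = e2[j - 1][1], e2[j + 1][0]
            if up_a == up_b and dn_a == dn_b:
                first, second = sorted((ex_a, ex_b))
                emit("MXE", (up_a, *first, *second, dn_a))
    return out


def enumerate_events(annotation: TranscriptAnnotation) -> Dict[Tuple, SpliceEvent]:
    """Deduplicated events from all transcript pairs of every gene."""
    events: Dict[Tuple, SpliceEvent] = {}
    for gene in annotation.genes.values():
        txs = sorted(gene.transcripts.values(), key=lambda t: t.transcript_id)
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                for ev in _pairwise_events(txs[i], txs[j]):
                    events.setdefault(ev.key, ev)
    return events


def psi(ijc: float, sjc: float, li: int = 1, ls: int = 1) -> float:
    """Inclusion level from junction counts, length-normalized.

    psi = (IJC/lI) / (IJC/lI + SJC/lS)
    """
    if ijc < 0 or sjc < 0:
        raise ValueError("junction counts must be non-negative")
    if li < 1 or ls < 1:
        raise ValueError("effective lengths must be >= 1")
    if ijc == 0 and sjc == 0:
        raise ValueError("PSI undefined when both junction counts are zero")
    inc, skp = ijc / li, sjc / ls
    return inc / (inc + skp)


def _theta(psi_val: float, li: int, ls: int) -> float:
    """Probability that a junction read is an inclusion read, given PSI."""
    num = psi_val * li
    return num / (num + (1.0 - psi_val) * ls)


def _binom_ll(i: float, s: float, psi_val: float, li: int, ls: int) -> float:
    th = min(max(_theta(psi_val, li, ls), 1e-12), 1 - 1e-12)
    return i * np.log(th) + s * np.log1p(-th)


def test_event(
    ijc_vehicle: Sequence[float],
    sjc_vehicle: Sequence[float],
    ijc_e2: Sequence[float],
    sjc_e2: Sequence[float],
    li: int = 1,
    ls: int = 1,
    c: float = 0.1,
) -> Optional[Dict[str, float]]:
    """Interval-null likelihood-ratio test of differential inclusion.

    Replicate junction counts are pooled per condition. The null hypothesis
    is |psi_E2 - psi_vehicle| <= c; the alternative is a larger change. When
    the observed change already lies inside the null interval the LR is 0 and
    p = 1; otherwise the constrained maximum sits on the interval boundary
    and p is taken from chi-square with 1 df. With c = 0 this reduces to the
    usual equal-inclusion LRT.

    Returns None when a condition has zero total junction reads (PSI
    undefined; the event is excluded from testing).
    """
    if not (0.0 <= c < 1.0):
        raise ValueError("cutoff c must lie in [0, 1)")
    i1, s1 = float(np.sum(ijc_vehicle)), float(np.sum(sjc_vehicle))
    i2, s2 = float(np.sum(ijc_e2)), float(np.sum(sjc_e2))
    if (i1 + s1) == 0 or (i2 + s2) == 0:
        return None
    psi1, psi2 = psi(i1, s1, li, ls), psi(i2, s2, li, ls)
    dpsi = psi2 - psi1
    ll_free = _binom_ll(i1, s1, psi1, li, ls) + _binom_ll(i2, s2, psi2, li, ls)

    if abs(dpsi) <= c:
        lr, p = 0.0, 1.0
    else:
        # constrained optimum on the boundary psi2 = psi1 + sign(dpsi) * c
        delta = c if dpsi > 0 else -c
        lo, hi = max(0.0, -delta), min(1.0, 1.0 - delta)

        def nll(x: float) -> float:
            return -(_binom_ll(i1, s1, x, li, ls)
                     + _binom_ll(i2, s2, x + delta, li, ls))

        if c == 0.0:
            # shared theta MLE is the pooled inclusion fraction
            th = (i1 + i2) / (i1 + s1 + i2 + s2)
            x0 = (th / li) / (th / li + (1 - th) / ls)
            ll_null = -nll(x0)
        else:
            res = optimize.minimize_scalar(
                nll, bounds=(lo + 1e-9, hi - 1e-9), method="bounded",
                options={"xatol": 1e-10},
            )
            ll_null = -res.fun
        lr = max(0.0, 2.0 * (ll_free - ll_null))
        p = float(stats.chi2.sf(lr, df=1))
    return dict(psi_vehicle=psi1, psi_e2=psi2, dpsi=dpsi, lr=lr, p=p)


def call_events(
    junction_table: pd.DataFrame,
    events: Dict[Tuple, SpliceEvent],
    *,
    c: float = 0.1,
    alpha: float = 0.05,
    vehicle_label: str = "vehicle",
    e2_label: str = "E2",
) -> pd.DataFrame:
    """Per-event differential-splicing calls for one cell line.

    ``junction_table`` is long-form with columns ``event_key`` (stringified
    event key), ``condition``, ``replicate``, ``ijc``, ``sjc``. BH correction
    runs separately per event type; an event is significant when q <= alpha
    and |delta PSI| >= c (for c = 0 the effect gate is vacuous).
    """
    by_key = {str(ev.key): ev for ev in events.values()}
    rows = []
    for key, sub in junction_table.groupby("event_key", sort=True):
        ev = by_key.get(key)
        if ev is None:
            raise KeyError(f"junction counts for unknown event {key}")
        veh = sub[sub["condition"] == vehicle_label]
        e2 = sub[sub["condition"] == e2_label]
        res = test_event(
            veh["ijc"].to_numpy(), veh["sjc"].to_numpy(),
            e2["ijc"].to_numpy(), e2["sjc"].to_numpy(),
            li=ev.inclusion_length, ls=ev.skipping_length, c=c,
        )
        if res is None:
            continue
        rows.append(
            dict(event_key=key, event_type=ev.event_type, gene_id=ev.gene_id,
                 **res)
        )
    if not rows:
        return pd.DataFrame(
            columns=["event_key", "event_type", "gene_id", "psi_vehicle",
                     "psi_e2", "dpsi", "lr", "p", "q", "significant",
                     "direction"]
        )
    calls = pd.DataFrame(rows)
    calls["q"] = np.nan
    for _, idx in calls.groupby("event_type").groups.items():
        calls.loc[idx, "q"] = bh_fdr(calls.loc[idx, "p"].to_numpy())
    calls["significant"] = (calls["q"] <= alpha) & (calls["dpsi"].abs() >= c)
    calls["direction"] = np.where(calls["dpsi"] > 0, "inclusion", "exclusion")
    return calls


def compare_events_across_lines(
    calls_wt: pd.DataFrame,
    calls_ct: pd.DataFrame,
    calls_nt: pd.DataFrame,
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """(common, opposite) event sets across the three cell lines.

    common: significant in all three lines. opposite: significant in all
    three with the sign of delta PSI in wt reversed relative to both
    ERbeta+ lines.
    """
    def sig_map(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["significant"]].set_index("event_key")

    wt, ct, nt = sig_map(calls_wt), sig_map(calls_ct), sig_map(calls_nt)
    common = frozenset(wt.index) & frozenset(ct.index) & frozenset(nt.index)
    opposite = frozenset(
        k for k in common
        if np.sign(wt.loc[k, "dpsi"]) == -np.sign(ct.loc[k, "dpsi"])
        and np.sign(wt.loc[k, "dpsi"]) == -np.sign(nt.loc[k, "dpsi"])
    )
    return frozenset(common), opposite


def events_per_gene(calls: pd.DataFrame) -> pd.Series:
    """Number of significant events per gene (genes with >=1 only)."""
    sig = calls[calls["significant"]]
    return sig.groupby("gene_id").size()
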