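"""Isoform-ratio switch classification and sqrt-JSD divergence tests.

Three related analyses live here:

* the four-criterion isoform-switch classifier: a gene "switches" when (i)
  some isoform's share of gene expression (FPKM_isoform/FPKM_gene, in %)
  changes by >= 10 percentage points upon estradiol, (ii) some isoform is
  itself significantly regulated, (iii) the ratio change runs in opposite
  directions in wt versus both ERbeta+ lines for the same isoform, and (iv)
  the gene carries at least one significant splicing event;
* a promoter-switch test: sqrt Jensen-Shannon divergence (base-2 entropy)
  between the vehicle and E2 relative-abundance vectors over a gene's
  promoter (TSS) groups, with a seeded Monte-Carlo null;
* a differential-splicing (DSG) test: the same divergence computed within
  each TSS group over that group's isoforms, maximized over groups.

Both divergence tests draw their null by resampling replicate counts from
the condition-pooled relative abundances (a reads-level permutation null),
which stays informative at small replicate numbers where relabeling the
replicates themselves would bound p away from the FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .quantify import bh_fdr

RATIO_POINTS_MIN = 10.0


def isoform_ratio(fpkm_isoform: float, fpkm_gene: float,
                  tolerance: float = 1e-6) -> Optional[float]:
    """Isoform share of gene expression in percent; None when gene FPKM = 0."""
    if fpkm_isoform < 0 or fpkm_gene < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_gene == 0:
        return None
    if fpkm_isoform > fpkm_gene * (1.0 + tolerance):
        raise ValueError(
            f"isoform FPKM {fpkm_isoform} exceeds gene FPKM {fpkm_gene}"
        )
    return 100.0 * min(fpkm_isoform, fpkm_gene) / fpkm_gene


def jsd_sqrt(p_dist: Sequence[float], q_dist: Sequence[float]) -> float:
    """Square root of the Jensen-Shannon divergence, base-2 entropy.

    JS(p,q) = H(m) - (H(p) + H(q))/2 with m = (p+q)/2; the square root is a
    metric bounded by [0, 1] and equals 0 iff p == q.
    """
    p = np.asarray(p_dist, dtype=float)
    q = np.asarray(q_dist, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("distributions must be 1-D, equal length >= 2")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("distributions must each sum to 1")
    m = 0.5 * (p + q)
    js = entropy(m, base=2) - 0.5 * (entropy(p, base=2) + entropy(q, base=2))
    return float(np.sqrt(max(js, 0.0)))


def _condition_profile(counts: np.ndarray, weights: Optional[np.ndarray]) -> Optional[np.ndarray]:
    """Mean per-replicate relative-abundance vector; None if no usable rep."""
    if weights is not None:
        counts = counts * weights[:, None]
    totals = counts.sum(axis=0)
    usable = totals > 0
    if not usable.any():
        return None
    props = counts[:, usable] / totals[usable]
    prof = props.mean(axis=1)
    return prof / prof.sum()


@dataclass
class DivergenceResult:
    statistic: float
    p: float


def _mc_pvalue(obs: float, null_stats: np.ndarray, rng: np.random.Generator,
               randomized: bool) -> float:
    if randomized:
        # uniform tie-breaking keeps the p-value exactly uniform under the
        # null despite the finite Monte-Carlo grid (calibration diagnostics)
        greater = int(np.sum(null_stats > obs + 1e-12))
        ties = int(np.sum(np.abs(null_stats - obs) <= 1e-12))
        u = rng.random()
        return (greater + u * (1 + ties)) / (null_stats.size + 1)
    return (1 + int(np.sum(null_stats >= obs - 1e-12))) / (null_stats.size + 1)


def promoter_switch_test(
    counts_vehicle: np.ndarray,
    counts_e2: np.ndarray,
    *,
    weights: Optional[Sequence[float]] = None,
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
    randomized: bool = False,
) -> Optional[DivergenceResult]:
    """sqrt-JSD shift of promoter-group usage between conditions.

    ``counts_vehicle`` / ``counts_e2`` are (n_groups, n_replicates) count
    matrices of per-TSS-group abundance. ``weights`` (e.g. reciprocal
    lengths) convert counts to abundances before normalizing. Returns None
    when the gene has fewer than two groups or a condition has no reads.
    """
    cv = np.asarray(counts_vehicle, dtype=float)
    ce = np.asarray(counts_e2, dtype=float)
    if cv.shape[0] != ce.shape[0]:
        raise ValueError("group dimension differs between conditions")
    if cv.shape[0] < 2:
        return None
    w = None if weights is None else np.asarray(weights, dtype=float)
    prof_v = _condition_profile(cv, w)
    prof_e = _condition_profile(ce, w)
    if prof_v is None or prof_e is None:
        return None
    obs = jsd_sqrt(prof_v, prof_e)

    rng = np.random.default_rng() if rng is None else rng
    pooled = cv.sum(axis=1) + ce.sum(axis=1)
    if pooled.sum() == 0:
        return None
    pi = pooled / pooled.sum()
    null_stats = _resample_null(cv, ce, pi, w, n_perm, rng)
    return DivergenceResult(obs, _mc_pvalue(obs, null_stats, rng, randomized))


def _resample_null(
    cv: np.ndarray, ce: np.ndarray, pi: np.ndarray,
    w: Optional[np.ndarray], n_perm: int, rng: np.random.Generator,
) -> np.ndarray:
    """Null sqrt-JSD statistics: replicate totals fixed, counts ~ Mult(pi)."""
    k = pi.size
    sims_v = np.zeros((n_perm, k, cv.shape[1]))
    sims_e = np.zeros((n_perm, k, ce.shape[1]))
    for r in range(cv.shape[1]):
        sims_v[:, :, r] = rng.multinomial(int(cv[:, r].sum()), pi, size=n_perm)
    for r in range(ce.shape[1]):
        sims_e[:, :, r] = rng.multinomial(int(ce[:, r].sum()), pi, size=n_perm)
    stats_out = np.empty(n_perm)
    for b in range(n_perm):
        pv = _condition_profile(sims_v[b], w)
        pe = _condition_profile(sims_e[b], w)
        stats_out[b] = 0.0 if pv is None or pe is None else jsd_sqrt(pv, pe)
    return stats_out


def dsg_test(
    counts_vehicle: np.ndarray,
    counts_e2: np.ndarray,
    group_of_isoform: Sequence[str],
    *,
    weights: Optional[Sequence[float]] = None,
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
    randomized: bool = False,
) -> Optional[DivergenceResult]:
    """Within-promoter-group isoform divergence; gene statistic = max group.

    Rows of the count matrices are isoforms; ``group_of_isoform`` maps each
    row to its TSS group. Groups with a single isoform are not testable;
    returns None when no group has >= 2 isoforms. Ties in the max are
    resolved by group label order.
    """
    cv = np.asarray(counts_vehicle, dtype=float)
    ce = np.asarray(counts_e2, dtype=float)
    labels = np.asarray(group_of_isoform)
    if not (cv.shape[0] == ce.shape[0] == labels.size):
        raise ValueError("isoform dimension mismatch")
    w = None if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng() if rng is None else rng

    testable = []
    for g in sorted(set(labels)):
        idx = np.flatnonzero(labels == g)
        if idx.size >= 2:
            testable.append(idx)
    if not testable:
        return None

    def max_stat(mv: np.ndarray, me: np.ndarray) -> Optional[float]:
        best = None
        for idx in testable:
            pv = _condition_profile(mv[idx], None if w is None else w[idx])
            pe = _condition_profile(me[idx], None if w is None else w[idx])
            if pv is None or pe is None:
                continue
            s = jsd_sqrt(pv, pe)
            if best is None or s > best:
                best = s
        return best

    obs = max_stat(cv, ce)
    if obs is None:
        return None

    # null resampling per group, preserving per-replicate group totals
    null_stats = np.zeros(n_perm)
    sims_v = np.tile(cv[:, :, None], (1, 1, n_perm)).astype(float)
    sims_e = np.tile(ce[:, :, None], (1, 1, n_perm)).astype(float)
    for idx in testable:
        pooled = cv[idx].sum(axis=1) + ce[idx].sum(axis=1)
        if pooled.sum() == 0:
            continue
        pi = pooled / pooled.sum()
        for r in range(cv.shape[1]):
            sims_v[idx, r, :] = rng.multinomial(
                int(cv[idx, r].sum()), pi, size=n_perm
            ).T
        for r in range(ce.shape[1]):
            sims_e[idx, r, :] = rng.multinomial(
                int(ce[idx, r].sum()), pi, size=n_perm
            ).T
    for b in range(n_perm):
        s = max_stat(sims_v[:, :, b], sims_e[:, :, b])
        null_stats[b] = 0.0 if s is None else s
    return DivergenceResult(obs, _mc_pvalue(obs, null_stats, rng, randomized))


def divergence_table(
    per_gene: Mapping[str, Optional[DivergenceResult]],
    alpha: float = 0.05,
    strict: bool = False,
) -> pd.DataFrame:
    """BH-correct a mapping gene -> DivergenceResult into a call table.

    ``strict`` selects q < alpha (the DSG convention) instead of q <= alpha
    (the promoter-switch convention).
    """
    rows = [
        dict(gene_id=g, statistic=r.statistic, p=r.p)
        for g, r in sorted(per_gene.items()) if r is not None
    ]
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "statistic", "p", "q", "significant"]
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha if strict else df["q"] <= alpha
    return df


@dataclass
class SwitchCall:
    gene_id: str
    criterion_i: bool
    criterion_ii: bool
    criterion_iii: bool
    criterion_iv: bool

    @property
    def passes(self) -> bool:
        return (self.criterion_i and self.criterion_ii
                and self.criterion_iii and self.criterion_iv)


def classify_switch(
    gene_id: str,
    ratios: pd.DataFrame,
    isoform_significant: Mapping[str, Mapping[str, bool]],
    gene_has_event: Mapping[str, bool],
    *,
    ratio_points: float = RATIO_POINTS_MIN,
    lines: Tuple[str, str, str] = ("wt", "ct_erb", "nt_erb"),
) -> SwitchCall:
    """Evaluate the four switch criteria for one gene.

    ``ratios``: columns ``isoform_id``, ``cell_line``, ``dratio`` (E2 minus
    vehicle isoform ratio, percentage points). ``isoform_significant``:
    per line, isoform id -> regulation significance. ``gene_has_event``:
    per line, does the gene carry >= 1 significant splicing event.
    Criteria i and ii accept evidence from wt alone or from both ERbeta+
    lines; criterion iii needs one isoform whose >= ratio_points change
    runs one way in wt and the other way in both ERbeta+ lines; criterion
    iv accepts any line.
    """
    wt, ct, nt = lines
    piv = ratios.pivot_table(index="isoform_id", columns="cell_line",
                             values="dratio", aggfunc="first")
    for line in lines:
        if line not in piv.columns:
            raise ValueError(f"missing ratio data for cell line {line}")
    d = piv[list(lines)].to_numpy(dtype=float)

    big = np.abs(d) >= ratio_points
    crit_i = bool(np.any(big[:, 0] | (big[:, 1] & big[:, 2])))

    def any_sig(line: str) -> bool:
        return any(
            isoform_significant.get(line, {}).get(iso, False)
            for iso in piv.index
        )

    crit_ii = any_sig(wt) or (any_sig(ct) and any_sig(nt))
    # a direction call is only meaningful where the ratio actually changed:
    # the same isoform must move >= ratio_points in every line, wt against
    # both ERbeta+ lines
    sign = np.sign(d)
    crit_iii = bool(np.any(
        big.all(axis=1)
        & (sign[:, 1] == -sign[:, 0])
        & (sign[:, 2] == -sign[:, 0])
    ))
    crit_iv = any(gene_has_event.get(line, False) for line in lines)
    return SwitchCall(gene_id, crit_i, crit_ii, crit_iii, crit_iv)


def switch_set_logic(
    results: Mapping[str, pd.DataFrame],
    *,
    lines: Tuple[str, str, str] = ("wt", "ct_erb", "nt_erb"),
) -> Dict[str, FrozenSet[str]]:
    """Lost and ERbeta-specific significant-gene sets across the 3 lines.

    lost: significant in wt and in neither ERbeta+ line. erb_specific:
    not significant in wt, significant in both ERbeta+ lines.
    """
    wt, ct, nt = lines
    sig = {}
    universes = {}
    for line in lines:
        df = results[line]
        universes[line] = frozenset(df["gene_id"])
        sig[line] = frozenset(df.loc[df["significant"], "gene_id"])
    if not (universes[wt] == universes[ct] == universes[nt]):
        raise ValueError("per-line result tables must share a gene universe")
    return {
        "lost": sig[wt] - sig[ct] - sig[nt],
        "erb_specific": (sig[ct] & sig[nt]) - sig[wt],
    }
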