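"""FPKM normalization and per-feature estrogen-regulation calls.

A feature (gene or isoform) is called significantly regulated in a cell
line when all three gates hold: mean FPKM >= 0.5 in at least one condition,
BH-adjusted q <= 0.05, and |fold change| >= 1.3. The differential test is a
Welch t-test on log2(FPKM + 0.1) across replicates; BH correction is applied
per cell line over expressed features only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FPKM_MIN = 0.5
Q_MAX = 0.05
FC_MIN = 1.3
LOG_PSEUDO = 0.1


def fpkm(count: float, length_bp: float, library_size: float) -> float:
    """Fragments per kilobase of exon per million mapped reads.

    fpkm = 1e9 * count / (library_size * length_bp)
    """
    if length_bp <= 0 or library_size <= 0:
        raise ValueError("length and library size must be positive")
    return 1e9 * count / (library_size * length_bp)


def is_expressed(mean_fpkms: Sequence[float], threshold: float = FPKM_MIN) -> bool:
    """True iff mean FPKM reaches the threshold in at least one condition."""
    if len(mean_fpkms) == 0:
        raise ValueError("need at least one condition")
    return any(x >= threshold for x in mean_fpkms)


def fold_change(mean_e2: float, mean_vehicle: float, pseudocount: float = 0.0):
    """(|FC|, direction) with |FC| = max(r, 1/r), r = (e2+pc)/(veh+pc).

    direction is 'induced' when r > 1, 'repressed' when r < 1, 'undefined'
    when both means are zero (|FC| reported as 1.0).
    """
    if mean_e2 < 0 or mean_vehicle < 0:
        raise ValueError("FPKM means must be non-negative")
    num, den = mean_e2 + pseudocount, mean_vehicle + pseudocount
    if num == 0 and den == 0:
        return 1.0, "undefined"
    if den == 0:
        return np.inf, "induced"
    if num == 0:
        return np.inf, "repressed"
    r = num / den
    if r > 1:
        return r, "induced"
    if r < 1:
        return 1.0 / r, "repressed"
    return 1.0, "undefined"


def test_regulation(fpkm_vehicle: Sequence[float], fpkm_e2: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value on log2(FPKM + 0.1) replicate values."""
    a = np.log2(np.asarray(fpkm_vehicle, dtype=float) + LOG_PSEUDO)
    b = np.log2(np.asarray(fpkm_e2, dtype=float) + LOG_PSEUDO)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 replicates per condition")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance; equal means are a perfect null
        return 1.0 if a[0] == b[0] else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(min(max(p, 0.0), 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-independent)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_regulation(
    fpkm_table: pd.DataFrame,
    *,
    fpkm_min: float = FPKM_MIN,
    q_max: float = Q_MAX,
    fc_min: float = FC_MIN,
    vehicle_label: str = "vehicle",
    e2_label: str = "E2",
) -> pd.DataFrame:
    """Regulation calls for one cell line.

    ``fpkm_table`` is long-form with columns ``feature_id``, ``condition``,
    ``replicate``, ``fpkm``. Returns one row per feature with mean FPKMs,
    fold change, p, BH q (over expressed features only), and the boolean
    ``expressed`` / ``significant`` gates plus ``direction``.
    """
    required = {"feature_id", "condition", "replicate", "fpkm"}
    missing = required - set(fpkm_table.columns)
    if missing:
        raise ValueError(f"fpkm_table missing columns: {sorted(missing)}")

    rows = []
    for fid, sub in fpkm_table.groupby("feature_id", sort=True):
        veh = sub.loc[sub["condition"] == vehicle_label, "fpkm"].to_numpy()
        e2 = sub.loc[sub["condition"] == e2_label, "fpkm"].to_numpy()
        mean_veh, mean_e2 = float(np.mean(veh)), float(np.mean(e2))
        fc, direction = fold_change(mean_e2, mean_veh)
        expressed = is_expressed([mean_veh, mean_e2], threshold=fpkm_min)
        p = test_regulation(veh, e2)
        rows.append(
            dict(feature_id=fid, mean_fpkm_vehicle=mean_veh,
                 mean_fpkm_e2=mean_e2, fc=fc, direction=direction,
                 expressed=expressed, p=p)
        )
    calls = pd.DataFrame(rows).set_index("feature_id")

    calls["q"] = np.nan
    mask = calls["expressed"].to_numpy()
    if mask.any():
        calls.loc[mask, "q"] = bh_fdr(calls.loc[mask, "p"].to_numpy())
    finite_fc = np.isfinite(calls["fc"].to_numpy())
    calls["significant"] = (
        mask
        & (calls["q"].to_numpy() <= q_max)
        & ((calls["fc"].to_numpy() >= fc_min) | ~finite_fc)
        & (calls["direction"] != "undefined")
    )
    return calls.reset_index()
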