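"""Three-way set logic over per-line regulation calls.

Compares the estradiol regulon of the parental (wt, ERalpha-only) line with
the two ERbeta-expressing lines (Ct-ERbeta, Nt-ERbeta): which regulation is
lost when ERbeta is present, which is gained in both ERbeta+ lines, which is
shared by all three, and which genes flip their direction of regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Tuple

import pandas as pd

WT, CT, NT = "wt", "ct_erb", "nt_erb"


@dataclass
class RegulonComparison:
    regulated_wt: FrozenSet[str]
    regulated_ct: FrozenSet[str]
    regulated_nt: FrozenSet[str]
    lost_in_both_erb: FrozenSet[str]
    gained_in_both_erb: FrozenSet[str]
    common_all: FrozenSet[str]
    opposite_direction: FrozenSet[str]
    composition: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def counts(self) -> Dict[str, int]:
        return {
            "regulated_wt": len(self.regulated_wt),
            "regulated_ct": len(self.regulated_ct),
            "regulated_nt": len(self.regulated_nt),
            "lost_in_both_erb": len(self.lost_in_both_erb),
            "gained_in_both_erb": len(self.gained_in_both_erb),
            "common_all": len(self.common_all),
            "opposite_direction": len(self.opposite_direction),
        }


class UniverseMismatchError(ValueError):
    pass


def _check_universe(calls: Dict[str, pd.DataFrame]) -> None:
    universes = {line: set(df["feature_id"]) for line, df in calls.items()}
    ref_line, ref = next(iter(universes.items()))
    for line, uni in universes.items():
        if uni != ref:
            missing = sorted((ref - uni) | (uni - ref))[:10]
            raise UniverseMismatchError(
                f"feature universes differ between {ref_line} and {line}; "
                f"first differing ids: {missing}"
            )


def compare_regulons(
    calls_wt: pd.DataFrame,
    calls_ct: pd.DataFrame,
    calls_nt: pd.DataFrame,
) -> RegulonComparison:
    """Lost / gained / common / opposite-direction sets across the 3 lines.

    lost: significant in wt, in neither ERbeta+ line. gained: not significant
    in wt, significant in both ERbeta+ lines with consistent direction.
    opposite: significant in all three lines with both ERbeta+ lines agreeing
    against wt.
    """
    calls = {WT: calls_wt, CT: calls_ct, NT: calls_nt}
    _check_universe(calls)
    sig = {
        line: df.set_index("feature_id")["significant"].astype(bool)
        for line, df in calls.items()
    }
    direc = {
        line: df.set_index("feature_id")["direction"] for line, df in calls.items()
    }
    s_wt = frozenset(sig[WT][sig[WT]].index)
    s_ct = frozenset(sig[CT][sig[CT]].index)
    s_nt = frozenset(sig[NT][sig[NT]].index)

    lost = s_wt - s_ct - s_nt
    gained = frozenset(
        g for g in (s_ct & s_nt) - s_wt if direc[CT][g] == direc[NT][g]
    )
    common = s_wt & s_ct & s_nt
    opposite = frozenset(
        g for g in common
        if direc[CT][g] == direc[NT][g] and direc[CT][g] != direc[WT][g]
    )
    comp = RegulonComparison(
        regulated_wt=s_wt, regulated_ct=s_ct, regulated_nt=s_nt,
        lost_in_both_erb=frozenset(lost), gained_in_both_erb=gained,
        common_all=frozenset(common), opposite_direction=opposite,
    )
    comp.composition = {
        "lost_in_both_erb": direction_composition(lost, calls_wt),
        "gained_in_both_erb": direction_composition(gained, calls_ct),
    }
    return comp


def direction_composition(
    features: Iterable[str], calls: pd.DataFrame
) -> Tuple[float, float]:
    """(fraction induced, fraction repressed) of a feature set.

    Empty input returns (0.0, 0.0); otherwise the fractions sum to 1.
    """
    features = list(features)
    if not features:
        return (0.0, 0.0)
    direc = calls.set_index("feature_id")["direction"]
    n_ind = n_rep = 0
    for f in features:
        d = direc.get(f)
        if d == "induced":
            n_ind += 1
        elif d == "repressed":
            n_rep += 1
        else:
            raise ValueError(f"feature {f} has no regulation direction")
    n = n_ind + n_rep
    return (n_ind / n, n_rep / n)
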