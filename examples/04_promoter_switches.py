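"""Detect estradiol-induced promoter switching with the sqrt-JSD test.

Transcripts are grouped by promoter (TSS groups); the test statistic is the
square root of the Jensen-Shannon divergence between the vehicle and E2
relative TSS-group abundance vectors, with a seeded Monte-Carlo null and
BH correction across genes.
"""

from ersplice import SimulationConfig, simulate
from ersplice.pipeline import PipelineConfig, promoter_and_dsg_tests
from ersplice.switches import switch_set_logic

dataset = simulate(SimulationConfig(n_genes=120, seed=4))
prom, dsg = promoter_and_dsg_tests(
    dataset.isoform_counts, dataset.annotation,
    PipelineConfig(n_perm=499, seed=4),
)

for line in ("wt", "ct_erb", "nt_erb"):
    called = prom[line][prom[line]["significant"]]
    print(f"{line}: {len(called)} promoter-switching genes "
          f"(max sqrt-JSD {prom[line]['statistic'].max():.3f})")

sets = switch_set_logic(prom)
print(f"lost in both ERbeta+ lines: {len(sets['lost'])}")
print(f"ERbeta-specific (absent in wt): {len(sets['erb_specific'])}")
# A planted switch flips the dominant promoter's share 0.8 -> 0.2 upon E2,
# giving sqrt-JSD ~ 0.53 against a sampling-noise null near 0.
truth_pairs = {(g, ln) for g, lines in
               dataset.truth.promoter_switch_genes.items() for ln in lines}
print(f"planted (gene, line) switches: {len(truth_pairs)}")
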