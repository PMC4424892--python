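# ersplice

Estrogen-receptor-dependent transcription and splicing analysis for
three-cell-line stimulation studies.

## The problem

When breast-cancer cells that normally express only estrogen receptor α
(ERα) are engineered to co-express ERβ, a short 17β-estradiol (E2) stimulus
no longer produces the same transcriptome response: some genes lose their
hormonal regulation, others acquire it, and — less visibly — the *composition*
of transcripts per gene changes through alternative splicing and alternative
promoter usage. Quantifying those effects requires a pipeline that compares
three cell lines (wt, Ct-ERβ, Nt-ERβ) × two conditions (vehicle, E2) ×
replicates at four levels: gene expression, splicing events, isoform ratios
and promoter usage, and then asks which changes sit near ERα/ERβ binding
sites.

`ersplice` implements that pipeline as a library with a thin CLI, driven by
a synthetic-data generator that plants known effects — so every stage can be
validated against machine-readable ground truth without any sequencing data.

## The statistics at its core

- **Regulation calls**: FPKM = 10⁹·c/(N·L); a feature is regulated when
  FPKM ≥ 0.5 in ≥ 1 condition, BH q ≤ 0.05 (Welch t on log₂(FPKM+0.1)
  across replicates) and |FC| ≥ 1.3 with FC = max(r, 1/r).
- **Splicing**: events (SE/MXE/A5SS/A3SS/RI) enumerated from transcript
  structure; inclusion ψ = (I/l_I)/(I/l_I + S/l_S) from junction counts; a
  binomial likelihood-ratio test against the interval null |Δψ| ≤ c = 0.1,
  gated at FDR ≤ 0.05.
- **Switching**: isoform ratio = FPKM_isoform/FPKM_gene (%), a
  four-criterion opposite-direction switch classifier, and √JSD (base-2
  Jensen–Shannon divergence) between condition abundance vectors over
  promoter (TSS) groups and within them, with a seeded Monte-Carlo null.
- **Binding**: ERα/ERβ peaks intersected with ±10 kb gene windows; genes
  labeled Group 1 (both), 2 (ERα only), 3 (ERβ only); ±1.5 kb binned tag
  density matrices.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
python examples/03_splice_events.py
```

```
enumerated events: 203
wt: 48 significant events {'SE': 22, 'A3SS': 9, 'RI': 9, 'MXE': 6, 'A5SS': 2}
ct_erb: 51 significant events {'SE': 23, 'A3SS': 10, 'MXE': 9, 'RI': 5, 'A5SS': 4}
nt_erb: 52 significant events {'SE': 24, 'A3SS': 10, 'MXE': 9, 'RI': 5, 'A5SS': 4}
common to all three lines: 32
opposite inclusion direction (wt vs both ERbeta+): 18
planted events in wt truth: 49
```

A 120-gene synthetic study is simulated, splicing events are enumerated
from the annotation, and each event is tested per cell line at the
c = 0.1 / FDR ≤ 0.05 gate. Exon skipping dominates (as the generator's
event mix plants), 32 events respond to E2 identically in all three lines,
and 18 flip their inclusion direction when ERβ is present — the signature
of receptor-dependent splicing. The other examples
(`examples/01…05_*.py`) walk through fixture generation, differential
expression with cross-line set logic, promoter switching and binding
integration the same way.

The same stages run from the shell:

```bash
ersplice simulate --seed 1 --outdir fixture/
ersplice validate --config pipeline.yaml
ersplice run --config pipeline.yaml      # writes per-stage TSVs + summary.json
```

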