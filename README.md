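# lncstage

Biotype-resolved temporal transcriptome analysis of neuronal
differentiation, as a tested, reusable pipeline.

Long noncoding RNA (lncRNA) genes are classified by their genomic
position relative to protein-coding genes: genic lncRNAs (within 5 kb of
a coding gene) split into divergent head-to-head (**XH**), convergent
tail-to-tail (**XT**), antisense containing (**XO**), antisense contained
(**XI**), sense-downstream (**SD**) and sense-upstream (**SU**) biotypes,
with the remainder intergenic (**IG**). During in vitro corticogenesis
(an 8-timepoint RPKM series, days 0–77), the coding genes *associated*
with each biotype behave differently: this package implements the
analyses that expose those differences and identify candidate regulator
genes.

The pipeline stages, each an importable module under `src/lncstage/`:

| stage | module | method |
|---|---|---|
| biotype classification | `annotation` | strand/overlap/distance rule table on gene bodies (GTF/BED12 in) |
| expression prep | `expression` | ≥1 RPKM filter, per-biotype expressed fractions, time-based z-scoring of log₂(x+1) |
| stage clustering | `fuzzy` | fuzzy c-means (fuzzifier m = 1.25, min.acore = 0.5) with marker-gene stage calls: POU5F1/NANOG/NODAL/TDGF1 (pluripotency, D0), PAX6/SOX1 (neuronal commitment, D7), EMX2/TBR1/BCL11B/CACNA1E/PRSS12/CARTPT (later development) |
| co-expression modules | `wgcna` | unsigned adjacency \|r\|^β, topological overlap matrix TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), average-linkage static-cut modules, per-biotype counts |
| network change & hubs | `aracne` | plug-in mutual information on equal-frequency bins, permutation-null edge threshold, data-processing-inequality (DPI) pruning, degree-ranked hubs, multiedge-partner counts |
| coding potential | `fickett` | Fickett TESTCODE statistic (published lookup tables) + longest-ORF coverage, coding/noncoding verdicts |
| synthetic data | `simulate` | generators with planted ground truth for every stage |
| orchestration | `pipeline`, `cli` | one-config run, TSV intermediates, deterministic report |

Because the original study's inputs (the public corticogenesis RNA-seq
series, GO annotations, an interactive network session) are not desk-
scale reproducible, the `simulate` module generates a synthetic bundle
that emulates the study conditions with known planted truth; all tests
and the acceptance script run against it.

## Worked example

The numbered scripts under `analysis/` run the full study on the
synthetic bundle:

```bash
python analysis/01_simulate_bundle.py          # writes scratch/bundle
python analysis/02_classify_biotypes.py
python analysis/03_expression_and_stages.py
python analysis/04_coexpression_modules.py
python analysis/05_mi_networks.py
python analysis/06_coding_potential.py
```

`02` prints `classified 252 lncRNAs; truth agreement 100.0%` — every
planted geometry gets its intended label. `03` reports that 73–95% of
biotype-associated coding genes pass the 1-RPKM filter and prints the
stage table:

```
              XH  XT  XO  XI  SD  SU  IG
commitment    30   0   0   0   0   3   0
later          0  30   0   0   0   1   0
pluripotency   0   0   0  15   0   1  30
```

i.e. the commitment (D7) stage is dominated by XH-associated genes
(~30), pluripotency by IG and XI. `04` counts co-expression modules per
biotype stratum — `XH: 4, IG: 3, XI: 2, SD: 2, SU: 0, XO: 0` — and `05`
prints the multiedge-partner change from the D0 to the D7 analogue
(`XH 5→7, IG 9→2, XI 6→4`: the divergent biotype's network grows while
the others shrink) and the hub gene:

```
top hub: CG_XH000 (degree 12; planted: CG_XH000)
```

`CG_XH000` is the coding partner of a divergent lncRNA whose 5′ end
overlaps it by 599 bp — the geometry of the pipeline's candidate-gene
readout. `06` scores the 25+25 transcript set: planted-ORF transcripts
average a Fickett score of 1.32 with ORF coverage 0.82, random
transcripts 0.50 and 0.15, and all 50 verdicts match the planted labels.

The same run is available as a single command:

```bash
lncstage simulate --outdir scratch/bundle --seed 0
lncstage run-all --bundle scratch/bundle/bundle.json --outdir scratch/run
```

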