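# cadep — Ca²⁺-dependency analysis of H₂O₂-responsive transcriptomes

Hydrogen peroxide triggers a transient rise in cytosolic Ca²⁺, and part of
the H₂O₂ transcriptional response travels through that Ca²⁺ signal.  When
the Ca²⁺ channel blocker LaCl₃ suppresses the transient, genes whose
regulation needs Ca²⁺ change their behaviour — and comparing the two
treatments gene by gene reveals which ones they are.  `cadep` implements
that comparative analysis as a tested, reusable pipeline for anyone working
with paired differential-expression contrasts of this design (treatment,
treatment + blocker, blocker alone), together with the downstream profile
clustering and knowledge-network path analysis, and a synthetic-data
generator with planted ground truth standing in for RNA-seq and network
resources.

## The classification rule

For each gene, let `log2FC_H` be its response to H₂O₂ alone and `log2FC_HL`
its response to H₂O₂ + LaCl₃ (both versus water control).  A gene is a DEG
when FDR < 0.01 and |log₂FC| ≥ 0.5; otherwise it is UC (unchanged).
Combined-treatment DEGs that are also DEGs under LaCl₃ alone are removed
first — their change cannot be attributed to the blocked Ca²⁺ transient.
Each remaining H₂O₂-DEG is then classified with Δlog₂FC = log2FC_H −
log2FC_HL:

| class | rule | meaning |
|---|---|---|
| strict | combined response UC | Ca²⁺ signal required for any change |
| partial/additive | both DEG, same sign, \|Δlog₂FC\| ≥ 1, attenuated | Ca²⁺ carries part of the response |
| enhanced | both DEG, same sign, \|Δlog₂FC\| ≥ 1, amplified | response stronger without Ca²⁺ |
| antagonistic | both DEG, opposite sign, \|Δlog₂FC\| ≥ 1 | direction flips without Ca²⁺ |
| independent | none of the above | response does not need Ca²⁺ |

The first four classes are collectively **Ca²⁺-dependent**.  Dependent
genes' (log2FC_H, log2FC_HL) profiles are grouped by k-means with the
cluster number fixed by the gap statistic (Tibshirani's one-standard-error
rule, B = 100 uniform reference datasets).  Finally, regulatory routes from
annotated Ca²⁺-signaling genes to the dependent targets are extracted from
a ranked, typed interaction network under the constraints: path length ≤ 3,
edges of reliability rank ≤ 2, exactly one transcription-regulation edge
per path and it must be the final edge, closest source(s) per target only.
Merged paths are scored for hub nodes by (distinct targets, path
occurrences).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (2,000 genes, four conditions × three replicates, planted dependency
classes) and write tables under `results/`:

```
$ python analysis/01_simulate_data.py
$ python analysis/02_call_degs.py
H2O2_vs_ctrl: 521 up, 352 down, 1127 unchanged
H2O2LaCl3_vs_ctrl: 372 up, 189 down, 1439 unchanged
LaCl3_vs_ctrl: 64 up, 0 down, 1936 unchanged
combined-treatment DEGs: 561; unique after omitting LaCl3-shared: 497 (64 removed)
$ python analysis/03_classify_dependency.py
dependency classes:
              STRICT: 312
    PARTIAL_ADDITIVE: 137
            ENHANCED: 51
        ANTAGONISTIC: 124
         INDEPENDENT: 185
  total dependent: 624 (= 312 strict + 312 partial/antagonistic)
  excluded as LaCl3-shared: 64
agreement with planted classes: 99.9% over 807 classifiable genes
```

At the published study's scale the same tabulation reproduces the
component arithmetic exactly: 295 strict + 36 partial/antagonistic = 331
dependent genes in leaves (33.1% of the 1001 H₂O₂-DEGs), 799 + 522 = 1321
in roots (70.2% of 1883), 1652 across both tissues.

`analysis/04_cluster_profiles.py` selects k by the gap statistic and
recovers the planted response patterns (strict-up, strict-down,
partial-up, partial-down, enhanced-down, antagonistic) as near-pure
clusters; `analysis/05_network_paths.py` extracts exactly the planted
regulatory paths (10/10 targets, decoy near-paths rejected) and ranks
hubs; `analysis/06_qpcr_validation.py` quantifies a 10-gene panel by
2^–ΔΔCt against two reference genes and regresses qPCR on planted log₂FC
(r = 0.993, slope = 1.018 at Ct noise 0.2).

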