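# introscan

Toolkit for characterizing archaic-introgressed haplotypes and genotyping a
mobile-element (Alu) insertion from short ancient-DNA fragments, exercised
end-to-end on synthetic data with recorded ground truth.

Components:

- **`introscan.synthetic`** — simulators for every pipeline input: a phased
  haplotype panel with a planted archaic segment (two archaic
  sub-haplotypes, one carrying the insertion), archaic diploid genotypes,
  a reference pair with/without the insertion, and short ancient-DNA
  fragment sets (truncated-normal lengths, optional terminal deamination),
  plus exact-match ungapped fragment placement.
- **`introscan.genotyper`** — insertion genotyping from fragment evidence:
  per-base depth profiles, the symmetric coverage-drop statistic around the
  insertion point, junction-fragment counting via a unique 22-mer spanning
  the 5' junction, spanning-fragment counting with minimum anchors, and the
  genotype decision rule (hom_present / het / hom_absent / no_call with an
  exact binomial heterozygosity check).
- **`introscan.haplotypes`** — per-population allele frequencies, r²/D from
  phased gamete counts (any site can be a presence/absence pseudo-SNP),
  lineage-private SNPs versus an outgroup, the r²-defined segment extent
  around a focal site, and a per-site archaic-match table for
  carrier/non-carrier haplotype classes.
- **`introscan.ils`** — incomplete-lineage-sorting probability for an
  observed shared-haplotype length: expected tract length L = 1/(r·t) and
  the survival function (1 + m/L)·exp(−m/L) of the sum of two exponential
  extents.
- **`introscan.assoc`** — Wald log-scale odds-ratio confidence intervals
  from 2×2 counts and family-wise error-rate adjustment (Bonferroni /
  Holm) across phenotype families.
- **`introscan.pipeline`** — orchestration of the full synthetic study with
  a structured, schema-versioned JSON report.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form
reference values, genotype-recovery accuracy over seeded simulations,
brute-force LD oracle, Monte-Carlo ILS oracle, ground-truth recovery, depth
conservation).

## CLI

```bash
# full fixed-seed synthetic study (simulate -> genotype -> haplotype -> ILS -> assoc)
introscan demo --seed 0 --out demo_out/

# individual stages
introscan simulate --seed 0 --out sim/
introscan genotype-insertion --ref-without ref.fa --insertion alu.fa \
    --point 2000 --fragments fragments.fa
introscan haplotype --vcf panel.vcf --pops populations.tsv \
    --archaic archaic.tsv --focal 41523 --outgroup YRI-like --out hap/
introscan ils --length-bp 56200 --rec-rate 0.87 --gen-time 25 \
    --branch-modern 200000 --branch-archaic 100000
introscan assoc --table associations.tsv --family-column group
introscan run --config study.yaml --out run_out/
```

All coordinates are 0-based half-open. Panels travel as minimal phased VCF
plus a sample→population TSV; fragments as FASTA plus a placement TSV;
archaic genotypes as a dosage TSV; ground truth as JSON.

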