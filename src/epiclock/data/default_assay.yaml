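# Default targeted-assay definition: 6 PCR amplicons, 7 Infinium CpG probes,
# 70 assessable CpG units. Coordinates are 1-based inclusive on GRCh37/hg19.
name: targeted-biological-age-clock
version: "1.0"
assembly: GRCh37/hg19
regions:
  - gene_label: ELOVL2
    chrom: chr6
    start: 11044680
    end: 11045053
    n_cpg_units: 15
    probes:
      - {id: cg16867657, chrom: chr6, pos: 11044877}
  - gene_label: NHLRC1
    chrom: chr6
    start: 18122552
    end: 18123149
    n_cpg_units: 21
    probes:
      - {id: cg22736354, chrom: chr6, pos: 18122719}
  - gene_label: SIRT7/MAFG
    chrom: chr17
    start: 79877158
    end: 79877497
    n_cpg_units: 6
    probes:
      - {id: cg07855221, chrom: chr17, pos: 79877314}
      - {id: cg09253473, chrom: chr17, pos: 79877390}
  - gene_label: AIM2
    chrom: chr1
    start: 159046884
    end: 159047270
    n_cpg_units: 7
    probes:
      - {id: cg10636246, chrom: chr1, pos: 159046973}
  - gene_label: EDARADD
    chrom: chr1
    start: 236557384
    end: 236557805
    n_cpg_units: 5
    probes:
      - {id: cg09809672, chrom: chr1, pos: 236557683}
  - gene_label: TFAP2E
    chrom: chr1
    start: 36038876
    end: 36039325
    n_cpg_units: 16
    probes:
      - {id: cg26372517, chrom: chr1, pos: 36039159}
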