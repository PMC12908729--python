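# endosift

Conservative small-variant calling and validation for endosymbiont
populations resequenced from host tissues.

## The problem

Intracellular symbionts such as *Wolbachia* are sequenced as total DNA
extracted from host tissue, so the read pool mixes symbiont DNA with
host DNA — including fragments of symbiont DNA that have integrated
into the host nuclear genome over evolutionary time.  Reads from these
nuclear inserts misalign to the symbiont reference and masquerade as
low-frequency within-host variants.  For anyone asking whether symbiont
sub-populations in different tissues differ genetically, these
artifacts vastly outnumber real polymorphism: in a typical experiment,
well over 99% of raw candidate variants must be discarded before the
remainder can be believed.

`endosift` implements that filtering cascade as a tested, reusable
pipeline, together with a synthetic-data generator that plants known
variants, contamination, and recombination events so that every stage
can be verified against ground truth at desk scale.

## The method

Candidates are produced by a frequency caller (every non-reference base
with observation fraction **F ≥ 0.03** in some sample) or ingested from
an external caller's VCF, then pass through:

1. **Support filter** — keep sites with total depth **> 200** and
   **≥ 10** alternative-allele reads within at least one tissue.
2. **Uninfected-line window screen** — define a 300-bp window starting
   150 bp before the site; exclude the candidate if reads from
   symbiont-free host individuals (aligned to the symbiont reference)
   appear in the window **≥ 2** times.  Such reads evidence a
   host-genomic (nuclear-insert) origin.
3. **Wet-lab exclusion list** — optional ingestion of PCR results:
   candidates whose region amplifies in uninfected hosts are removed.
4. **Alignment-anomaly battery** — reads covering each candidate SNP
   are partitioned by the allele they carry; Fisher exact tests compare
   the clipped-read proportion, the proper-pair proportion, and the
   mismatch load (excluding the focal site) between the
   reference-allele and alternative-allele groups.  After
   Benjamini–Hochberg FDR correction across all candidates × features,
   any adjusted *p* < 0.05 excludes the candidate.
5. **Depth review** — survivors get a 100-bp-window coverage profile
   around the site, flagging collapsed repeats.

A separate detector identifies **gene conversion** between homologous
region pairs: a converted acceptor locus shows a sharp coverage drop,
its donor an equal-sized rise, and the reads still anchored at the
acceptor carry the donor's alleles at every diagnostic site.  A
single-end re-scoring check (`unpaired_remap_check`) reproduces the
behaviour of realigning without the paired-end constraint, under which
the anchored reads migrate to the donor.

Relative symbiont load from qPCR is computed as
RQ = 2^−(CP(*wsp*) − CP(TLeu)).

## Worked example

Simulate the default desk-scale dataset (100-kb circular symbiont
genome; three tissues at 534–770× with one planted SNP at
tissue-specific frequencies 0.466/0.584/0.239; three 2-kb nuclear
inserts at 3% divergence contaminating the tissue libraries and covered
by two uninfected lines; two clip-biased artifact variants), then run
the full cascade:

```python
from endosift import pipeline
from endosift.synthetic_data import SimulationDesign, simulate
from endosift.reporting import variant_frequency_table

res = simulate(SimulationDesign(seed=1))
result = pipeline.run(res.tissues, res.genome, res.uninfected)
print(result.funnel.summary())
print(variant_frequency_table(result.survivors).to_string(index=False))
```

```
candidates called: 204
  support_filter: 204 entering, 0 excluded, 204 surviving
  insert_screen: 204 entering, 201 excluded, 3 surviving
  wet_lab_exclusion: 3 entering, 0 excluded, 3 surviving
  anomaly: 3 entering, 2 excluded, 1 surviving
final survivors: 1 / 204 (0.49% rounded, 0.49% truncated)

reference  position ref alt      tissue  depth  alt_count  frequency
 symbiont     64327   C   T  haemolymph    557        267   0.479354
 symbiont     64327   C   T nerve_chain    738        433   0.586721
 symbiont     64327   C   T     ovaries    714        157   0.219888
```

The 201 candidates inside nuclear-insert intervals are removed by the
window screen, the two clip-biased artifacts by the anomaly battery,
and the single survivor is the planted SNP, recovered at its planted
per-tissue frequencies (binomial sampling noise aside).

The same stages are available from the shell:

```bash
endosift simulate --out data/
endosift run --bam data/haemolymph.sam --bam data/nerve_chain.sam \
    --bam data/ovaries.sam --uninfected data/uninfected_1.sam \
    --uninfected data/uninfected_2.sam --ref data/reference.fa --out out/
endosift conversion --bam data/nerve_chain.sam --ref data/reference.fa \
    --pairs data/homolog_pairs.tsv --out calls.tsv
```

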