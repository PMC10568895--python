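# ypanel

Tools for large multiplexed Y-chromosome SNP/Indel genotyping panels:
haplogroup-tree modelling from hierarchical lineage names,
depth-thresholded allele calling, terminal-haplogroup inference under
drop-out, population and pedigree statistics, and a simulator of the
developmental-validation experiments used to qualify such panels
(dilution series, male–female mixtures, PCR inhibition, degraded DNA,
female negative controls, male pedigrees).

It is written for forensic and population geneticists who run
short-amplicon massively parallel sequencing panels of lineage-defining
Y-SNPs and Y-Indels — panels of several hundred markers resolving
hundreds of terminal haplogroups, with clade composition weighted
toward the lineages of the study population (e.g. haplogroup O for
Chinese populations).

## What it computes

**Haplogroup tree from the name grammar.** ISOGG-style names are a
single uppercase clade letter followed by alternating digit and
lowercase-letter runs (`O2a2b1a1a1a1a1`). Every component-boundary
prefix names an ancestor, so a panel's label set induces a rooted tree
with no external phylogeny file; major clades join at a virtual root
`Y`. Missing intermediate labels are bridged to the nearest present
prefix.

**Calling.** A locus with depth of coverage *d* is filtered out below
the detection threshold (default 18 reads), called but marked REVIEW in
the window up to the analysis threshold (default 54 reads), and PASS
above it. Loci are hemizygous: the majority of the two legitimate
alleles gives the state; a majority fraction below 0.9 or an excess of
off-target reads flags the locus as mixed. Profiles can be compared
across runs/platforms and against genotypes lifted from a GRCh38 chrY
VCF (orientation resolved against the panel's ancestral/derived
alleles, not REF/ALT order).

**Inference.** The terminal haplogroup is the deepest node with a
derived marker whose whole root path is supported — every path node
derived, or fully dropped out under the default imputation policy. An
ancestral call vetoes a node and its subtree; stranded derived calls
and imputed gaps downgrade confidence; disjoint-clade candidates give a
CONFLICTED call with a deterministic tie-break.

**Population statistics.** Multiplicity spectra and unbiased haplogroup
diversity

&nbsp;&nbsp;&nbsp;&nbsp;*H* = *N*(1 − Σ *x*ᵢ²)/(*N* − 1),

haplogroup frequency spectra (HFS) at any name-truncation level,
pairwise Fst (two-population Nei G_ST on haploid haplogroup
frequencies), PCA of population frequency matrices, and
genotype/haplogroup concordance across male pedigrees with a
relationship census by degree.

## Worked example

Simulate a cohort on a synthetic 120-marker panel, call it, infer
terminals, and summarise:

```python
from ypanel import (
    generate_panel_fixture, simulate_population, simulate_readcounts,
    call_sample, infer_haplogroup, multiplicity_summary, diversity_report,
    clade_composition, hfs,
)
from ypanel.popstats import render_percentages

fixture = generate_panel_fixture(n_markers=120, seed=42)
tree = fixture.tree
leaves = sorted(n.text for n in tree.nodes() if not n.children)
truth = simulate_population(tree, {lab: 1.0 for lab in leaves}, n=50, seed=1)
counts = simulate_readcounts(truth, fixture.markers, seed=2)

assignments = []
for rec in truth:
    profile = call_sample(counts[rec.sample_id], fixture.markers, sample_id=rec.sample_id)
    assignments.append(infer_haplogroup(profile, tree))

correct = sum(a.terminal == t.haplogroup for a, t in zip(assignments, truth))
print(f"recovered {correct}/{len(truth)} terminal haplogroups")
report = diversity_report(multiplicity_summary(assignments))
print(f"lineages: {report['n_lineages']}, N: {report['N']}, H: {report['H_rounded']}")
print("clades (%):", render_percentages(clade_composition(assignments)))
```

prints

```
recovered 50/50 terminal haplogroups
lineages: 32, N: 50, H: 0.9796
clades (%): {'C': 8.0, 'D': 8.0, 'G': 2.0, 'J': 4.0, 'N': 10.0, 'O': 56.0, 'Q': 8.0, 'R': 4.0}
```

At full input mass every locus clears the analysis threshold, so every
terminal is recovered exactly; the 50 samples span 32 distinct lineages
and the unbiased diversity of the cohort is 0.9796.

The same steps are available from the shell:

```sh
ypanel simulate --scenario dilution --mass 0.5 --out sim/
ypanel panel summarize sim/panel.tsv
ypanel call  --panel sim/panel.tsv --counts sim/counts.tsv --out profiles.json
ypanel infer --panel sim/panel.tsv --profiles profiles.json --out assignments.tsv
ypanel popstats --assignments assignments.tsv --pops pops.tsv --level 4 --out stats/
```

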