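# clonephy

Multi-sample tumour subclonal deconvolution: cancer cell fraction (CCF)
estimation from sequencing read counts, multidimensional Dirichlet-process
clustering of SNVs across samples, and rule-based clone-tree reconstruction,
with a read-count simulator for validating cluster and tree recovery against
a known clonal phylogeny.

## Who this is for

Cancer-genomics analysts with somatic SNV calls from several samples of the
same patient (multi-region biopsies, autopsy metastases, a matched primary)
who want to resolve the clonal architecture: which mutations are truncal
(carried by every tumour cell in every sample), which define subclonal
lineages, and how those lineages relate on a phylogenetic tree. The inputs
are per-sample SNV read counts (TSV or VCF), allele-specific copy-number
segments (BED-like TSV) and per-sample purity estimates.

## The model

For an SNV at a locus with tumour copy number $CN_t$ (major allele count
$CN_{maj}$), normal copy number $CN_n = 2$, in a sample of purity $\rho$,
a mutation on $m$ chromosomal copies carried by a fraction $c$ (the CCF) of
tumour cells is expected at variant allele frequency

$$\mathrm{VAF} = \frac{m\,c\,\rho}{\rho\,CN_t + (1-\rho)\,CN_n}.$$

Inverting, the **mutation copy number** $n_{mut} = \mathrm{VAF}\cdot(\rho\,
CN_t + (1-\rho)\,CN_n)/\rho = c\,m$, and the multiplicity $m \in
\{1..CN_{maj}\}$ is chosen by binomial maximum likelihood on the read
counts, giving $\hat c = n_{mut}/m$.

SNVs are then clustered jointly across all $S$ samples with a truncated
stick-breaking Dirichlet-process mixture. Component $k$ has a CCF location
$c_{ks}$ per sample, and SNV $i$'s likelihood under it is

$$\prod_{s=1}^{S} \mathrm{Binom}\!\left(a_{is} \mid d_{is},\;
c_{ks} f_{is}\right),$$

where $a, d$ are alt reads and depth and $f_{is}$ is the VAF expected for a
fully clonal mutation at that cell. Gibbs sampling over assignments, stick
weights, concentration $\alpha$ and locations yields posterior clusters,
labelled clonal / subclonal / absent per sample; a cluster clonal in every
sample is truncal (the MRCA).

Clone trees rooted at the truncal cluster are enumerated exhaustively under
the infinite sites assumption: CCF **dominance** of ancestors over
descendants, the **sum rule** (sibling CCFs may not exceed their parent's in
any sample) and the **crossing rule** (clusters whose CCF ordering flips
between samples must branch). Clusters violating the rules under every
topology are treated as artefacts and removed; surviving trees are ranked by
how much numerical tolerance they consume.

Before clustering, SNVs whose apparent heterogeneity is explainable by copy
number (differing CNA status across samples, or allele loss in the samples
where the SNV is missing) are filtered out — without this, CN differences
masquerade as subclonal structure.

## Worked example

Simulate the standard branching validation design (a trunk plus six
non-truncal clusters in three bifurcations, per-branch burden 100, trunk
scaled to 2,000 SNVs, four samples at Poisson(34) coverage and purities in
0.70–0.95), estimate CCFs, cluster, and rebuild the tree:

```python
from clonephy import *
from clonephy.simulate import (standard_design, simulate_reads,
                               simulated_segments, simulated_purities)

spec = standard_design(3, trunk_snvs=2000, seed=7)
reads, truth = simulate_reads(spec)
ccf = compute_ccf_matrix(reads, simulated_segments(spec), simulated_purities(spec))
res = DirichletProcessMixture(reads, ccf, ClusterConfig(seed=1)).fit()
print(res.summary())
print(write_newick(build_trees(res.called_cluster_set).best))
```

prints

```
Dirichlet-process mixture of per-sample CCFs
  SNVs clustered: 2536   samples: 4
  sweeps: 2000 (burn-in 1000, thin 10, 100 retained)
  mean concentration alpha: 2.672
  clusters called: 7

            n_snvs  ccf_S1  ccf_S2  ccf_S3  ccf_S4 clonality_S1 clonality_S2 clonality_S3 clonality_S4  truncal
cluster_id
C1            1940   1.000     1.0   1.000    1.00       clonal       clonal       clonal       clonal     True
C2             101   0.000     0.0   0.000    0.29       absent       absent       absent    subclonal    False
C3             100   0.685     0.0   0.000    0.00    subclonal       absent       absent       absent    False
C4             100   0.000     0.0   0.715    0.00       absent       absent    subclonal       absent    False
C5              99   0.000     0.3   0.000    0.00       absent    subclonal       absent       absent    False
C6              98   0.985     1.0   0.000    0.00       clonal       clonal       absent       absent    False
C7              97   0.000     0.0   1.000    1.00       absent       absent       clonal       clonal    False

((C3:100,C5:99)C6:98,(C2:101,C4:100)C7:97)C1:1940;
```

All seven generating clusters are recovered: the trunk at CCF 1 everywhere,
the two mutually exclusive clonal clusters (C6 in samples 1–2, C7 in 3–4),
and the four second-step subclonal branches at their generating means of
0.7 and 0.3, each in its carrying sample. The Newick tree reproduces the
generating topology — three bifurcations, branch lengths equal to cluster
SNV burdens.

The same workflow is available from the shell:

```
clonephy simulate --design 3 --trunk-snvs 2000 --out sim/
clonephy run --config pipeline.yaml --seed 1
```

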