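# divprof

Similarity-sensitive diversity profiles for microbial community data, with
tree-balance and community-dissimilarity statistics and a simulation study
of how often "naïve" and phylogenetic diversity rankings agree.

## The problem

Classical diversity indices (richness, Shannon's H, Simpson's D,
Berger-Parker) treat every OTU as equally distinct and each index weights
rare taxa differently, so microbial datasets — which span domains of life
and carry phylogenetic structure — can look more or less diverse depending
on an arbitrary choice of index. Diversity *profiles* address both
problems at once: they express diversity as an **effective number** of
equally abundant, completely dissimilar taxa, computed across a
sensitivity parameter *q* that smoothly shifts weight from rare (*q* = 0)
to dominant (*q* → ∞) taxa, and they can incorporate a taxon similarity
matrix **Z** (here: derived from a phylogeny).

For a community with relative abundances *p* (only present taxa,
Σ*pᵢ* = 1) and similarities 0 ≤ *Z_ij* ≤ 1 (*Z_ii* = 1):

    qD_Z(p) = ( Σ_i p_i (Zp)_i^(q−1) )^(1/(1−q))        q ∉ {1, ∞}
    1D_Z(p) = exp( −Σ_i p_i ln (Zp)_i )
    ∞D_Z(p) = 1 / max_i (Zp)_i

where (*Zp*)*ᵢ* = Σ*ⱼ Z_ij pⱼ* is the *ordinariness* of taxon *i*. With
the identity matrix (the naïve case) the profile reduces to the classical
Hill numbers: *q* = 0 is richness, *q* = 1 is exp(*H*), *q* = 2 is inverse
Simpson, *q* → ∞ is 1/Berger-Parker. Phylogenetic similarity uses
*Z_ij* = exp(−*d_ij*/*s*) on patristic distances *d_ij* (scale *s* =
mean pairwise distance by default; a linear transform is also provided).

The package also implements Colless' I tree balance with Yule
normalization ((I_C − E_Yule)/n, E_Yule = n·ln n + n·(γ − 1 − ln 2)),
weighted/unweighted Jaccard and UniFrac sample dissimilarity with Ward
(ward.D2) dendrograms, and a synthetic-data generator: four rank-abundance
families (log normal, geometric, log series via Fisher's alpha, uniform)
on beta-splitting phylogenies spanning balanced to caterpillar shapes, in
ultrametric and non-ultrametric versions.

## Worked example

```python
import numpy as np
from divprof import (Community, classical_indices, diversity,
                     naive_profile, relative_abundances)

comm = Community(["otu1", "otu2", "otu3"], [6, 3, 1])
p = relative_abundances(comm)                  # [0.6, 0.3, 0.1]
print(diversity(p, None, 0))                   # 3.0   (richness)
print(diversity(p, None, 1))                   # 2.4546 = exp(Shannon H)
print(diversity(p, None, 2))                   # 2.1739 = 1/Simpson D
print(diversity(p, None, np.inf))              # 1.6667 = 1/Berger-Parker
```

The analysis pipeline is a sequence of scripts over the library (each
writes its tables under `results/`):

```sh
python analysis/01_simulate_communities.py   # fixture pools per family
python analysis/02_diversity_profiles.py     # naive vs phylogenetic curves
python analysis/03_balance_and_dissimilarity.py
python analysis/04_agreement_experiment.py   # the headline simulation
```

Step 04 prints (seed 1):

```
grid: 96 conditions (25s, seed 1)
  pooled mean agreement : 50.6%
  empirical 95% interval: 30.0% to 80.4%
  by sample size : 64: 0.471, 128: 0.504, 256: 0.514, 512: 0.535
  ultrametric 0.491 vs non-ultrametric 0.521
```

i.e. across 96 simulated conditions the naïve and phylogenetic profiles
pick the same sample as "more diverse" only about half the time — a strong
argument for reporting similarity-aware diversity alongside classical
indices — and agreement rises with sampling depth and for non-ultrametric
trees while falling slightly with tree imbalance and abundance skew.

A CLI mirrors the library for shell use:
`divprof profile|treestats|dissimilarity|simulate|agreement|fixtures`
(every stochastic command takes `--seed`; see `divprof --help`).

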