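# hostphylo

Community phylogenetics of plant–herbivore assemblages.

`hostphylo` is a Python package for ecologists asking how the phylogenetic
structure of a host-plant community shapes its insect herbivore fauna —
the classic setting being caterpillar assemblages sampled from every tree
species in a forest plot. It implements, as a tested and reusable pipeline:

* **Tree metrics** — patristic distances d(j, k) and fair-proportions
  evolutionary distinctiveness ED (used as *phylogenetic isolation*, PI) on
  time-calibrated host phylogenies, with pruning to per-site species pools;
* **Site-stratified Mantel tests** — per-site phylogenetic-distance /
  assemblage-similarity matrix pairs (Jaccard, Bray–Curtis, Morisita–Horn)
  are vectorized and concatenated; the permutation null relabels each
  site's distance matrix independently, so sites that share no species are
  never compared directly;
* **DSI\***, the distance-based specialization index — a sign-flipped
  z-score of the observed mean pairwise phylogenetic distance (MPD) of a
  herbivore's hosts against an availability-weighted null
  (hosts resampled with replacement in proportion to their summed leaf
  area in m²), rescaled by the extreme achievable scores to [−1, 1]:

  DSI = −(MPD_obs − mean(Null)) / sd(Null),  DSI\* = DSI / |DSI_lim|

  with DSI\* = 1 for a strict monophage and −1 for the maximally
  overdispersed host allocation;
* **AICc-ranked linear mixed models** — herbivore abundance, density,
  richness and mean DSI\* per plant species × feeding guild, modeled
  against PI, √leaf area, site and guild (plus guild×site), random
  intercept per host tree species, ML fits, Akaike weights, parsimony
  selection (ΔAICc ≤ 2, fewest parameters), likelihood-ratio tests and
  Holm-adjusted guild contrasts;
* **A synthetic data generator** — multi-site communities with
  controllable phylogenetic niche signal (an exponential distance kernel
  around each herbivore's focal host), guild-specific niche breadth and an
  optional negative coupling between leaf area and phylogenetic isolation,
  so the whole pipeline is testable without field data.

## Worked example

```python
import hostphylo as hp

# a three-site study (default dimensions: 8/20/15 host species per site,
# two caterpillar guilds with phylogenetically structured host use)
dataset = hp.generate_dataset(hp.SyntheticConfig(seed=7))
records = hp.filter_rare_herbivores(dataset.interactions)  # drop n < 3

results = hp.run_overlap_analysis(
    records, dataset.site_distances(),
    indices=("jaccard",), n_permutations=999, seed=1,
)
for (scope, index), res in sorted(results.items()):
    print(f"{scope:8s} {index}: r = {res.r_obs:+.3f}, p = {res.p_value:.4f}")

scores = hp.compute_specialization(
    records, dataset.community, dataset.site_distances(),
    n_iterations=499, seed=2,
)
print(scores.groupby("guild")["dsi_star"].mean().round(3))
```

Output:

```
all      jaccard: r = -0.687, p = 0.0010
exposed  jaccard: r = -0.463, p = 0.0010
shelter  jaccard: r = -0.735, p = 0.0010
guild
exposed    0.317
shelter    0.782
Name: dsi_star, dtype: float64
```

Caterpillar assemblages overlap less the more distantly related their host
plants are (negative Mantel r; p is the one-tailed permutation p-value at
999 iterations, so 0.0010 is the smallest attainable value), and the
decay is steeper for shelter builders — the guild the generator gave the
narrower phylogenetic niche, which is also why its mean DSI\* is higher.

The same analysis runs from the shell, end to end:

```sh
hostphylo run-all --config examples/demo_config.yaml --out demo_run
```

writing filtered tables, per-site distance/ED/similarity matrices, Mantel
JSON, specialization tables, ranked model tables and a manifest; the same
config and seeds reproduce the bundle byte for byte.

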