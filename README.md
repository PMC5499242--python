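# brainhubs

Hub location in weighted structural brain networks built from diffusion
MRI tractography, for researchers analysing region-by-region structural
connectomes (and, more generally, anyone ranking nodes in a weighted
undirected network).

Most hub-detection practice ranks regions by a single local index such
as degree or betweenness centrality. `brainhubs` implements an
importance index that combines a node's **local contribution** to its
neighbors with its **global information-transfer efficiency**, on a
connectivity matrix that fuses two complementary biosignals:

1. **NoS-FA fusion.** Starting from a streamline-count matrix
   `M^NoS` and a fractional-anisotropy matrix `M^FA` over the same
   parcellation (83 regions in the reference setting), FA is min-max
   normalized over existing edges and the fused weight is

   `w_ij = M^NoS_ij · (M^FA_ij − min FA) / (max FA − min FA)`.

2. **Importance contribution matrix.** With binary degree `D_i`,
   mean degree `k̄` and mean strength `S̄`, region *i* contributes
   `h_ij = D_i · w_ij / (S̄ k̄²)` to each connected region *j*
   (`H_BRIM`, diagonal 1).

3. **Transfer efficiency.** With shortest weighted distances
   `d^w` computed on edge lengths `1/w`,
   `E_i^w = (1/n) · Σ_{j≠h ∈ N(i)} (d^w_jh)^{-1} / (D_i (D_i − 1))`
   measures how efficiently region *i*'s neighborhood communicates.

4. **RC index and hubs.**
   `RC_i = E_i^w · Σ_{j≠i} D_j w_ji E_j^w / (S̄ k̄²)`;
   the top 15 regions by `RC_i` (configurable `k`) are the hubs.

The package also provides the weighted-betweenness baseline ranking,
global/local network metrics (density, global efficiency, strength,
clustering), targeted-attack vulnerability analysis under the
edge-zeroing removal convention, a three-group cohort comparison
(percent reductions of group means + one-way ANOVA), and a synthetic
connectome generator with planted rich-club hubs so the whole pipeline
is testable without MRI data. See `docs/methods.md` for model details
and design choices.

## Worked example

Simulate a small 30-region connectome with 5 planted hubs, fuse, and
rank:

```bash
brainhubs simulate --seed 11 -o sim --config cfg.yaml   # n_regions: 30, n_modules: 3, n_hubs: 5
brainhubs fuse sim/nos.csv sim/fa.csv -o fused.csv
brainhubs hubs fused.csv -k 5 -o hubs.tsv
```

`hubs.tsv` starts:

```
rank  region_number  region_abbreviation  score               is_hub
1     1              R001                 1.206643466971132   True
2     18             R018                 0.8877575595117606  True
3     16             R016                 0.8672775626741605  True
4     27             R027                 0.6879673465743295  True
5     4              R004                 0.5553619262859041  True
6     12             R012                 0.5352290186405996  False
```

The planted hubs for this seed were R001, R008, R016, R018, R027: four
of five land in the top 5, with R008 narrowly displaced by R004 — at
this small size a non-hub that happens to sit between several hubs can
edge out a weak planted one. At the default 83-region scale the RC
top-15 typically recovers all 15 planted hubs (see the acceptance
suite). Scores are on the arbitrary scale of the RC formula; only their
ranking matters.

`brainhubs metrics fused.csv` prints the global properties of the same
network:

```json
{
  "density": 0.4482758620689655,
  "global_efficiency": 55.970981021883254,
  "mean_strength": 586.3691475857561,
  "mean_clustering": 0.5172726913634169
}
```

i.e. 45% of possible region pairs are connected, and the mean inverse
shortest weighted distance (in streamline-count units) is about 56.

Other subcommands: `vulnerability` (per-region property drop when a
region's edges are zeroed), `attack-curve` (cumulative targeted attack
in rank order, with a seeded random baseline), `groups` (cohort study
from a subject manifest), each with `--help`.

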