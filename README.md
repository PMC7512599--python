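# pdgain

Point-divergence-gain analysis of grayscale image sequences.

The point divergence gain `Omega_alpha(l -> m)` is the change in Rényi
entropy when one occurrence of intensity `l` is removed from an image
histogram and one occurrence of intensity `m` is added — the information
gained or lost when a pixel changes from `l` to `m` between consecutive
frames. Two macroscopic summaries describe a frame pair: the entropy
`I_alpha` (sum of |Omega| over all pixels) and the entropy density
`P_alpha` (sum over distinct realised transitions). Their alpha spectra
support multifractality inspection, focus detection in z-stacks, change
segmentation, and clustering of image series.

## Layout

- `pdgain.histogram` — count histograms and alpha grids
- `pdgain.core` — Rényi entropy, point information gain, point divergence
  gain (closed form plus Shannon/alpha-0 branches), Omega matrices
- `pdgain.distributions` — discretised Cauchy/Gauss/Lévy/Rayleigh reference
  histograms
- `pdgain.sequence` — transition tables, per-pixel Omega maps, I/P spectra
- `pdgain.clustering` — [I, P] feature vectors, z-scoring, PCA + k-means++,
  consecutive relabeling
- `pdgain.segmentation` — zero-stability and extreme-value masks, 8-bit map
  rendering, least-information-loss bit-depth reduction
- `pdgain.synth` / `pdgain.io` / `pdgain.cli` — seeded synthetic fixtures,
  TIFF/PNG stack IO, `pdg` command line

## CLI

```sh
# synthetic 10-frame test stack
pdg synth --kind moving_square --frames 10 --shape 64 64 --out stack.tiff

# I/P spectra for all consecutive pairs on the 13-point alpha grid
pdg spectra --input stack.tiff --alphas default13 --lag 1 --log-base 2 --out spectra.csv

# cluster frame pairs by their [I, P] spectra
pdg cluster --spectra spectra.csv --k 2 --seed 42 --out labels.csv

# per-pixel Omega maps and segmentation for one pair
pdg transform --pair a.tif b.tif --alpha 0.99 --alpha 2.0 --out maps/
pdg segment --pair a.tif b.tif --alpha 4.0 --rule zero --tol 0 --out mask.png

# reference histograms and Omega matrices
pdg hist --family gauss --c 4 --sigma 1 --alphas default13 --out hists/

# 12-bit to 8-bit least-information-loss conversion
pdg lil --input stack12/ --out stack8.tiff
```

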