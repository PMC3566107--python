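# nanomap

Two-color nanochannel genome mapping in Python: build consensus sequence-motif
maps from noisy single-molecule label data, tile them into a region genome map,
and use that map to validate and correct a draft sequence assembly.

The package covers the full desk-scale workflow:

* **motifmap** — in silico two-color label maps from DNA sequence
  (default motifs `GCTCTTC` / Nt.BspQI, green and `CCTCAGC` / Nt.BbvCI, red;
  both strands; scaffold N-gaps recorded) and label-density statistics.
* **molsim** — single-molecule simulator with known ground truth: per-site
  label dropout, Poisson false labels, Gaussian sizing noise, per-molecule
  stretch variation, optical-resolution merging, and orientation flips.
* **consensus** — pairwise molecule fingerprint distances, hierarchical
  clustering, orientation resolution, and Gaussian-peak consensus maps.
* **mapalign** — dynamic-programming alignment of ordered two-color maps
  (fit and dovetail/overlap modes) and merging of per-clone consensus maps
  into a region genome map with clone tiling and break tracking.
* **asmcheck** — assembly-vs-map discrepancy classification (extra sequence,
  missing sequence, interval mismatch, high-density/tandem-repeat regions,
  unaligned ends), scaffold anchoring into gaps, and completeness reporting.
* **mapio** — text dialects of BNX / CMAP / XMAP, FASTA, AGP v2.1,
  TSV/JSON reports, and the YAML run configuration.
* **cli** — `nanomap` subcommands wiring the pipeline end to end.

## Command-line usage

```sh
# in silico digestion of an assembly
nanomap digest --fasta asm.fa --motif 1:GCTCTTC --motif 2:CCTCAGC --out asm.cmap

# simulate single-molecule data from a reference map
nanomap simulate --cmap ref.cmap --out mols.bnx --truth truth.tsv --seed 7

# cluster molecules and build consensus maps
nanomap consensus --bnx mols.bnx --out clones.cmap --report clusters.tsv

# align maps (fit = query contained in reference; overlap = dovetail)
nanomap align --query q.cmap --ref r.cmap --mode overlap --out aln.xmap

# merge per-clone consensus maps into a region genome map
nanomap assemble-map --clones clones.cmap --out genome.cmap --tiling tiling.tsv

# compare an assembly to the genome map / anchor unplaced scaffolds
nanomap compare --assembly asm.fa --genome-map genome.cmap --out report.tsv
nanomap anchor --unplaced rest.fa --genome-map genome.cmap --gaps report.tsv \
    --out placements.tsv

# full synthetic scenario (region -> clones -> consensus -> genome map ->
# corrupted assembly -> detection -> correction), deterministic per seed
nanomap end2end-demo --seed 1 --out-dir demo_out
```

Defaults for every stage live in `src/nanomap/data/defaults.yaml`; override
them with a YAML config file passed via `--config` (or `--params` for
`simulate`). Exit codes: 0 ok, 2 validation error, 3 alignment/clustering
failure.

## Notes

* All on-disk map formats are simplified text dialects (`# nanomap-dialect=1`)
  of the corresponding public formats: column subsets, 1-based positions on
  disk, 0-based in memory.
* Writers are deterministic: identical runs produce byte-identical files.
* Coordinates are calibrated bp throughout; the physical channel stretch
  (85% of B-DNA contour) appears only in the nm-scale molecule-length report.
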