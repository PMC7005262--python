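# arraysta

Desk-scale subtomogram averaging for membrane-bound hexagonal protein
arrays, built around a fully synthetic forward model so every stage is
testable without external data. The package covers:

- **simulator** — grouped dose-symmetric tilt schemes, curved-membrane
  (sphere-cap) hexagonal / honeycomb ground-truth arrays, a parametric
  C2-symmetric pseudo-CSU density motif, tomogram rendering, single-axis
  missing-wedge degradation, white-noise injection, and an optional
  projection + weighted-back-projection reconstruction path.
- **seeding** — least-squares sphere fitting to membrane annotation points,
  grid seeding at a target mean spacing, normal-derived initial orientations
  (ZYZ intrinsic Euler angles, principal axis +z).
- **alignment** — subvolume extraction, missing-wedge-compensated masked
  normalized cross-correlation with sub-voxel (zoomed-DFT) peak refinement,
  cone-constrained angular search, and two-stage masked iterative refinement
  with an optional matched-template pose polish.
- **curation** — duplicate collapse (connected components of the
  threshold-distance graph), lattice-neighbour annulus filtering, and
  nearest-neighbour lattice statistics (honeycomb lattice constant =
  sqrt(3) x ToD spacing).
- **validation** — wedge-weighted Fourier-space averaging, tomogram-split
  half-maps, FSC with 0.5 / 0.143 threshold resolutions, windowed-FSC local
  resolution maps, local filtering, and C2 symmetrisation about a refined
  axis.
- **dose_response** — synthetic FRET kinase traces, fractional-inhibition
  dose-response tables, and multi-site Hill fits (K1/2, Hill coefficient)
  with wild-bootstrap confidence intervals.

All lengths are Angstrom internally; particle tables are plain TSV and
volumes are MRC2014 (mode 2) via a self-contained reader/writer.

## CLI

The `arraysta` entry point chains the pipeline stages:

```sh
# synthetic tomograms of a curved-membrane array (lengths in nm here)
arraysta simulate --radius 150 --tod-spacing 6.93 --snr 0.3 --seed 1 --out-dir sim_out

# fit a sphere to membrane annotation points and emit seeds
arraysta seed-surface points.tsv --spacing 30 --out seeds.tsv

# alignment, curation, averaging, validation
arraysta align seeds.tsv sim_out/tomo_0.mrc --box 288 --out refined.tsv
arraysta clean refined.tsv --dup-threshold 10 --expected 120 --tol 20 --min-neighbors 3
arraysta average particles_clean.tsv sim_out/tomo_0.mrc --out average.mrc
arraysta fsc half_a.mrc half_b.mrc
arraysta localres half_a.mrc half_b.mrc
arraysta symmetrize average.mrc --out map_c2.mrc

# Hill fit of a dose / fractional-inhibition table
arraysta hillfit dose_table.tsv --plot fit.png

# or everything end to end from a YAML config
arraysta run-all --seed 1 --out-dir pipeline_out
```

`run-all` simulates tomograms, seeds the fitted membrane surface, picks
particles by translation-only alignment against a rendered template,
collapses duplicates, applies the lattice-neighbour filter, runs the
two-stage masked refinement, splits gold-standard half-maps by tomogram,
and reports FSC resolutions, local-resolution statistics and the C2
symmetrisation — all into a machine-readable `report.json` that is
byte-reproducible for a fixed seed.

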