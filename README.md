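# npcfit

Desk-scale inference of nuclear pore complex (NPC) scaffold architecture
from synthetic cryo-electron tomography data.

The NPC is a ~100 nm, eight-fold symmetric assembly of ~30 nucleoporins.
Its scaffold is built from a small repertoire of subcomplexes — the
Y-shaped coat complex that oligomerizes head-to-tail into the two outer
rings, and compact protomers stacked four per spoke in the inner ring —
and different organisms use different copy numbers of the same parts.
Determining those copy numbers from an in-situ subtomogram average is a
statistical problem: a subcomplex model is fitted exhaustively over all
rigid-body poses, each pose is scored by density cross-correlation and
map overlap, placements are tested against an empirical null and
corrected for multiple testing, and the significant, mutually exclusive
placements are counted per ring.

`npcfit` implements that whole chain on phantoms with known ground
truth:

* **`density`** — volumetric data model (MRC I/O, nm units, ZYZ poses),
  low-pass/wedge Fourier filters, symmetrization, FSC.
* **`phantoms`** — bead-model subunits, C8 ring architectures (a stock
  algal layout with 8 cytoplasmic + 16 nuclear Y-copies and 32 inner-ring
  protomers, and a human-like 16+16 layout), Gaussian rendering,
  missing-wedge + noise particle simulation, and block-correlated
  expression matrices.
* **`averaging`** — missing-wedge-constrained alignment, iterative
  wedge-compensated averaging, asymmetric-unit extraction, masked
  per-ring refinement.
* **`fitting`** — exhaustive SO(3) × lattice search with FFT-accelerated
  scoring (`score = cc × overlap`), phase-randomized empirical-null
  p-values, Benjamini–Hochberg over clustered placements, and
  copy-number census with sequential density claiming.
* **`architecture`** — difference maps, ring geometry (channel diameter,
  axial extent), rotational register, head-to-tail adjacency.
* **`coexpression`** — log2/quantile/centering normalization, PCC
  matrices with significance masking, complete-linkage ordering,
  module density comparison.

See `docs/methods.md` for the model and the statistical design.

## Worked example

The bundled demo builds the algal-NPC phantom (3 nm voxels, 6 nm
rendering resolution, snr 1 particles under a ±60° missing wedge),
averages six particles, fits the Y-complex into the cytoplasmic and
nuclear ring maps and the protomer into the inner ring, and measures the
ring geometry:

```sh
npcfit run --seed 42 --out demo_run
```

or in Python:

```python
from npcfit.config import run_pipeline
out = run_pipeline({"seed": 42}, "demo_run")
```

On one CPU this takes about a minute and writes, among other outputs,
`demo_run/copy_counts.tsv`:

```
      model  CR  IR  NR  unassigned
IR-protomer   0  32   0           0
  Y-complex   8   0  16           0
```

i.e. exactly the planted architecture is recovered: 8 Y-complexes in the
cytoplasmic ring (CR), 16 in the nuclear ring (NR) — 24 in total, the
asymmetric distribution characteristic of the algal pore — and 32
inner-ring (IR) protomers. `demo_run/analysis.json` reports the ring
geometry measured from the rendered density,

```
inner_diameter_nm: 63.0   outer_diameter_nm: 99.0   axial_extent_nm: 57.0
```

(the phantom declares a 60 nm channel and a ~60 nm tall scaffold; both
are recovered to within a voxel or two), and confirms that the
cytoplasmic and nuclear Y-rings are in rotational register (median
azimuthal offset 0.0° modulo the 45° symmetry unit).

Individual stages are available as subcommands (`generate`, `average`,
`fit`, `analyze`, `coexpr`) and every run directory carries a manifest
with the configuration hash and derived per-stage seeds, so reruns are
reproducible and resumable.

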