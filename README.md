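# tlstrack

Cluster-based displacement tracking for terrestrial-laser-scanning (TLS) time
series of plants.

Trees move on a circadian rhythm: branches and foliage droop overnight by up
to decimeters and recover after sunrise. Tripod-mounted laser scanners can
observe this at ~20 min cadence with millimeter-level range noise, independent
of lighting — but the resulting multi-million-point time series need a
processing framework that is fast, robust to point-cloud noise, and honest
about its own stability floor. `tlstrack` provides that framework for
researchers in plant phenomics, forest inventory, and TLS change detection.

## Method

Per object (a tree; a static control target), the first epoch's point cloud is
partitioned once into clusters of nominal diameter *d*<sub>min</sub> = 0.15 m:
dart-throwing Poisson-disk sampling picks cluster seeds (no two seeds closer
than *d*<sub>min</sub>; every point within *d*<sub>min</sub> of a seed), each
point joins its nearest seed, and clusters below 100 points are dissolved into
their neighbors. Every later epoch inherits labels by nearest-neighbor search
against the previous epoch's labeled points. The cluster center is the
per-axis median **c**<sub>k</sub>(t) of its members, and the reported movement
is the Euclidean displacement

> d<sub>k</sub>(t) = ‖**c**<sub>k</sub>(t) − **c**<sub>k</sub>(t₀)‖

from the cluster's initial position (or from the previous epoch, for step
amplitudes). For whole-crown views, cluster centers are projected into
cylindrical coordinates (r, φ, z) around a vertical axis through the stem and
binned on a height-normalized grid, (r<sub>norm</sub>, z<sub>norm</sub>) =
(r, z)·100/z<sub>max</sub>, each cell colored by the maximum displacement of
its clusters.

Upstream of clustering the package provides the standard TLS hygiene: a
structured stray-point filter (3×3 range-image window, 0.02 m range threshold,
50% allocation), an intensity gate (raw counts < 650 removed), an isolation
filter (fewer than two neighbors within 0.01 m removed), least-squares sphere
fitting (radius 0.099 m reference targets) with Kabsch rigid co-registration
from sphere correspondences, and sphere-based stability QA.

Because raw field data of this kind is rarely shareable, the package includes
a fully ground-truthed synthetic scene generator — a deforming vase-crowned
tree whose tips move by A<sub>tip</sub>·(r/r<sub>crown</sub>)·(z/h) along
fixed droop directions with a ramp–peak–return night profile, a static
lamppost, and reference spheres — so the entire pipeline is testable against
exact truth. See `docs/methods.md` for the model, conventions, and measured
limitations.

## Worked example

```python
import numpy as np
from tlstrack import (ClusterParams, DeformationConfig, FilterParams, SceneConfig,
                      SceneModel, displacements, generate_time_series,
                      percentile_summary, track_sequence)

# a small deforming tree observed for 12 epochs at 20 min; the nocturnal
# movement ramps up from t=20 min, peaks at t=2 h, then relaxes
model = SceneModel.default_tree_scene(
    density=20_000, n_branches=4, stem_height=3.0,
    include_lamppost=False, include_spheres=False,
)
deform = DeformationConfig(t_onset=1200, t_peak=7200, t_return=12000, a_tip=0.15)
config = SceneConfig(model=model, deformation=deform, n_dai=12, master_seed=42)
dais, truth = generate_time_series(config)

tracks = track_sequence(dais, ClusterParams(rng_seed=0), FilterParams())
disp = displacements(tracks, reference="initial")

print(f"clusters tracked:           {tracks.n_clusters}")
print(f"points per epoch:           ~{dais.clouds[0].n}")
print(f"peak activation s(t):       {truth.s.max():.2f}")
print(f"largest cluster move:       {np.nanmax(disp.values):.3f} m")
print(f"99th pct of cluster maxima: {percentile_summary(disp, 99):.3f} m")
```

prints

```
clusters tracked:           66
points per epoch:           ~53579
peak activation s(t):       1.00
largest cluster move:       0.161 m
99th pct of cluster maxima: 0.150 m
```

The tree is segmented into 66 clusters; at full activation the fastest
cluster (an outer tip clump plus its measurement noise) has moved 0.161 m
from its pre-onset position, and the 99th percentile of per-cluster maximum
displacement recovers the imposed 0.15 m tip amplitude. On a static target
the same statistic stays at a few millimeters (see `docs/methods.md` for the
chain-propagation stability floor).

## Command line

The `tlstrack` command drives the same pipeline from a shell, one stage per
subcommand, each writing a run manifest (parameters, seed, input digests):

```sh
tlstrack simulate   --config scene.yaml --out sim/ --seed 1
tlstrack preprocess --in sim/ --out pre/
tlstrack track      --in pre/ --out trk/ --reference initial --mode chain
tlstrack aggregate  --tracks trk/tracks.csv --out agg/ --q 99
tlstrack report     --tracks trk/tracks.csv --out rep/
```

All outputs are CSV/JSON with unit-bearing headers; `report` renders the
height-normalized displacement map and per-cluster time-series figures.

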