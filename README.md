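# swimquad

Quadrat dispersion statistics and excluded-volume Monte Carlo simulation
for spatial point patterns of microswimmers at low density.

## The problem

Swimming unicellular organisms (flagellated microalgae such as
*Chlamydomonas*, ~10 µm diameter, ~100 µm/s) observed in a quasi-2D
chamber form a time series of 2D point patterns.  At low area fraction
(φ ≈ 0.01) the scientific question is whether cells interact — attract,
avoid, or ignore each other — beyond the trivial hard-core constraint
that two cell bodies cannot overlap.  `swimquad` answers this with the
classic partitioning (quadrat) method: divide the square observation
window into N = m × m equal sections, count cells per section per frame,
and compare the **variance-to-mean ratio** (VMR, index of dispersion) of
the pooled counts against null models:

- **Poisson**: `VMR = 1` — complete spatial randomness in infinite space.
- **Binomial** (point cells, finite window): `VMR = 1 − 1/N`; placing n
  independent points, each landing in a given section with p = 1/N.
- **Hypergeometric** (finite cell area): tile the window of area S into
  M = S/A seats of one cell area A; a section holds K = D/A seats;
  `VMR = (1 − 1/N)(M − n)/(M − 1)`.
- **Monte Carlo excluded-volume placement**: n hard disks of diameter d
  placed sequentially with uniform rejection sampling, optionally around
  pinned *stationary cells* (cells adhered to the glass, detected from
  trajectories as moving < 18 µm/s for > 30 s).

`VMR < 1 − 1/N` indicates avoidance beyond the finite-window effect;
`VMR > 1 − 1/N` indicates clumping or environmental inhomogeneity (for
example, stationary cells concentrated in particular sections).

Since raw microscopy recordings are rarely shareable, the package ships a
synthetic trajectory generator (persistent-random-walk swimmers with
pinned cells, hard-core exclusion, and a loading transient in a circular
chamber) that emits tracker-format files with the statistical structure
the analysis assumes, plus ground truth for validation.

## Worked example

Place 185 cells of diameter 10 µm in a 1150 µm square window, 900
independent frames, and compute the VMR curve:

```python
import swimquad as sq

frames = sq.simulate_frames(sq.PlacementConfig(n_total=185, d=10.0,
                                               n_frames=900, seed=1))
curve = sq.vmr_curve(frames, sq.ArenaSpec(), range(2, 11))
curve["binomial"] = 1 - 1 / curve["N"]
print(curve.round(3).to_string(index=False))
```

```
 m   N   mean  variance   vmr  binomial
 2   4 46.250    32.847 0.710     0.750
 3   9 20.556    17.464 0.850     0.889
 4  16 11.562    10.378 0.898     0.938
 5  25  7.400     6.696 0.905     0.960
 6  36  5.139     4.776 0.929     0.972
 7  49  3.776     3.490 0.924     0.980
 8  64  2.891     2.710 0.938     0.984
 9  81  2.284     2.151 0.942     0.988
10 100  1.850     1.739 0.940     0.990
```

The measured VMR sits below the binomial line `1 − 1/N` at every
partition: the hard-core constraint alone produces an avoidance-like
(sub-binomial) dispersion.  Setting `d=0` recovers the binomial value,
and adding clustered `fixed_points` pushes the VMR above it.

The closed-form nulls at the textbook parameters (M=900 seats, K=100
seats per section, n=45 cells, N=9 sections):

```sh
$ swimquad models --M 900 --K 100 --n 45 --N 9 --out models
```

reports hypergeometric mean 5.0, variance 4.227 (VMR 0.845), binomial
mean 5.0, variance 4.444 (VMR 0.889), Poisson VMR 1.0.

## Command-line pipeline

```sh
swimquad synth      --n-cells 430 --n-stationary 10 --seed 1 --out tracks.csv
swimquad stationary --tracks tracks.csv --fps 30 --stride 30 --out fixed.csv
swimquad place      --n-total 185 --fixed-points fixed.csv --seed 1 --out ev_sc.csv
swimquad place      --n-total 185 --seed 2 --out ev.csv
swimquad vmr        --tracks ev_sc.csv --out run/ev_sc
swimquad vmr        --tracks ev.csv    --out run/ev
swimquad report     --run-dir run --n-mean 185 --out run/report.json
swimquad rdf        --frames ev.csv --out run/gr.tsv
```

All commands accept `--seed`, pixel or µm units (`--units px
--px-scale ...`), and emit delimited text with a `#` metadata header.

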