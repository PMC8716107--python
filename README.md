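# axonstat

Quantitative morphometry and statistics for electron-microscopy-traced
axons, built around the anatomy of dopaminergic (DA) axons in the nucleus
accumbens and how it changes after cocaine exposure.

The package is aimed at connectomics analysts working with Knossos-style
skeleton annotations of neurites: it parses and writes an NML dialect
(things/nodes/edges/comments, with per-node radii and annotation tags),
measures skeleton geometry (cable length, geodesic distances, branch points,
varicosity detection from the diameter profile, mitochondrial lengths,
per-µm densities), classifies axonal varicosities by their vesicle content,
tests whether varicosity types are non-randomly organized along axons, and
runs two-group comparisons.  A synthetic-data generator with known ground
truth stands in for the original EM annotation volumes, so the full analysis
is testable end to end at the desk.

## The statistics at the core

**Varicosity typing.** A varicosity (bouton) is a localized axonal swelling
where the diameter rises ≥ 2-fold above the local minimum within ~1 µm.
Each is typed by vesicle content: I (empty), II (only small vesicles, 26–67
nm diameter), III (only large vesicles, 90–238 nm), IV (both).

**Exceedance null model.** Are types clustered along individual axons?  For
type *T* and threshold *k*, the statistic is the exceedance count

&nbsp;&nbsp;&nbsp;&nbsp;*C(T, k)* = #{axons *a* : count of type-*T* varicosities on *a* > *k*},

over axons with ≥ 3 varicosities.  Under the null, each axon's *n_a* types
are drawn iid from the pooled population frequencies *f* (plug-in, held
fixed).  Two routes to the null distribution of *C*:

* **Monte Carlo** — *M* = 100,000 simulated datasets matching the per-axon
  varicosity counts; *p* = Pr(*C*_sim ≥ *C*_obs);
* **exact** — per axon *q_a* = P(Binomial(*n_a*, *f_T*) > *k*), so *C* is
  Poisson-binomial(*q₁…q_A*); its mass function is computed by dynamic
  programming and the tail gives the analytic *p*.

The two agree within Monte Carlo error by construction; the exact route is
kept alongside the simulation so that tests never rest on stochastic
agreement alone.

**Group comparisons.** Per-axon densities (branches/µm, contact points/µm,
swellings/µm) and per-structure lengths (mitochondria, µm) are compared
between saline and cocaine groups with a two-tailed Mann-Whitney U test
(U = min(U_x, U_y); exact for small tie-free samples, normal approximation
with tie/continuity correction otherwise), reported as mean ± SEM.
Inter-varicosity spacings are fit with a maximum-likelihood log-normal.

## Worked example

```sh
python examples/group_comparison.py
```

prints (seeds fixed in the script):

```
branch_density_per_um      saline  0.0061 ± 0.0011 (n=  44)  cocaine  0.0357 ± 0.0019 (n=  41)  U=     57.0  p=7.23e-14 [/µm]
swelling_density_per_um    saline  0.0000 ± 0.0000 (n=  44)  cocaine  0.0391 ± 0.0020 (n=  41)  U=     22.0  p=5.22e-17 [/µm]
contact_density_per_um     saline  0.2049 ± 0.0061 (n=  44)  cocaine  0.2037 ± 0.0033 (n=  41)  U=    896.0  p=0.961 [/µm]
mito_length_um             saline  0.3621 ± 0.0037 (n=1287)  cocaine  0.8037 ± 0.0102 (n=3921)  U=1123283.0  p=1.46e-196 [µm]
```

Cocaine-group axons were generated with a 4-fold higher branch rate, a
non-zero swelling rate and ~2.2-fold longer mitochondria, while the
contact-point rate is identical in both groups — the comparisons recover
exactly that pattern: three strong rejections and one null result.  The
other examples cover NML parsing (`parse_nml.py`), simulation and
morphometry (`simulate_and_measure.py`), vesicle-based classification
(`classify_varicosities.py`) and the organization null model
(`null_model_test.py`, where axons generated with Markov persistence
ρ = 0.5 produce starred exceedance cells that iid sampling cannot explain).

A thin CLI wraps the same stages:

```sh
axonstat simulate --seed 1 --outdir study/
axonstat nulltest study/saline_DA_axon.nml --trials 100000 --seed 1 --out null.csv
axonstat run --seed 1 --outdir out/    # simulate → measure → classify → nulltest → compare
```

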