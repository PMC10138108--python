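# sparsect

Sparse-view CT artifact simulation and suppression: learn the spectral
signature of angular aliasing streaks from random-phantom simulations and
use it as the "noise" spectrum of a BM3D collaborative filter.

Sparse-view CT trades dose for artifacts: with far fewer view angles than
the angular Nyquist requirement, filtered backprojection (FBP) produces
object-dependent streak patterns that are deterministic, not random — so
ordinary denoisers, which need a noise model, have nothing to work with.
This package implements a simulation-driven workaround for that problem,
aimed at researchers studying low-dose acquisition and image-domain
artifact correction.

## The method

For a random ellipse phantom with true image *T* and sparse-scan FBP
reconstruction *G*, the artifact image is

    A = T − G

and its power spectrum is *P* = |ℱA|², the squared modulus of the 2-D DFT.
Averaging *P* over a cohort of random two-ellipse phantoms (1000 at 512² in
the full protocol) gives the averaged artifact power spectral density *P̄*,
which depends on the scan geometry but not on any particular object.  A
sparse-view reconstruction *G* — simulated or clinical — is then filtered
with BM3D using *P̄* as its correlated-noise PSD:

    H = BM3D(G, λ·P̄)

where λ is the single operating-point hyperparameter (larger smooths more;
λ = 1 takes the learned spectrum at face value).  The simulation geometry,
view count, and reconstruction algorithm must match those of the image
being filtered.  The package provides every stage: random phantoms with
closed-form projections, parallel and equiangular fan-beam projectors, FBP,
the PSD learner, a from-scratch two-stage BM3D with the correlated-noise
variance mapping, a TV-minimization baseline, and an evaluation harness.

## Worked example

`examples/` contains one short script per capability.  The core pipeline
(`examples/04_filter_sparse_recon.py`) learns *P̄* from 25 two-ellipse
phantoms at 128², reconstructs an unseen three-ellipse phantom from a
180-view fan-beam scan, and filters it:

```
learned artifact PSD from 25 two-ellipse phantoms
raw sparse-view FBP error (L2):  1.875
after BM3D with learned PSD:     1.708
error reduction: 8.9%
```

The errors are Frobenius norms of the difference to the true image inside
the scan field of view; the filter removes spectral energy where the cohort
identified aliasing, and the error drops without touching the phantom's
structure.  `examples/02_sparse_vs_dense_fbp.py` shows the artifact being
created in the first place:

```
 720 views: relative RMSE inside FOV = 6.90%
 180 views: relative RMSE inside FOV = 9.78%
```

and `examples/05_tv_baseline.py` runs the comparison method (alternating
SIRT/TV minimization) on a heavily undersampled 20-view scan, where it
beats raw FBP (RMSE 0.051 vs 0.126) at the price of smoothing.

A thin CLI mirrors the library (`sparsect phantom | project | recon |
learn-psd | filter | tv-recon | experiment`); see `sparsect --help`.

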