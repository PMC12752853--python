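# bemdmf

Texture characterization of grayscale images by **bidimensional empirical
mode decomposition (BEMD)** combined with **multifractal spectrum
estimation**, with an SVM classification stage for two-population studies
(e.g. healthy vs. pathological regions of interest in mammography).

## Who this is for

Researchers in biomedical image analysis who want to (a) split a texture
into data-driven oscillatory modes (BIMFs) plus a residue, (b) quantify the
roughness heterogeneity of each mode by its singularity spectrum, and (c)
use those spectrum summaries as features to separate two texture
populations.

## The method

**Decomposition.** BEMD extracts modes by 2D *sifting*: find the local
maxima/minima of the surface, interpolate each set with a thin-plate
radial basis function into upper/lower envelopes, subtract the envelope
mean, and repeat until the relative squared change between consecutive
iterates,

    SD = Σ (d_j − d_{j−1})² / Σ d_{j−1}²,

drops below `sd_max` (default 0.2). The detail becomes BIMF₁; sifting the
residue yields BIMF₂, and so on until the residue has too few extrema or a
mode cap (default 5) is hit. By construction

    I = Σ_k BIMF_k + residue        (exact reconstruction).

**Spectrum.** Each mode is read as a mass distribution. For box sizes *s*
and moment orders *q*, with box probabilities `P_i(s)` and normalized
measures `μ_i(q,s) = P_i^q / Σ_j P_j^q`:

    α(q) = slope of Σ_i μ_i log P_i  vs log s      (Hölder exponent)
    f(q) = slope of Σ_i μ_i log μ_i  vs log s      (singularity spectrum)
    D(q) = slope of log Σ_i P_i^q    vs log s / (q−1)

The spectrum width `Δα = α_max − α_min` measures the degree of
multifractality; `Δf = f(α_max) − f(α_min)` its asymmetry. Per mode, the
feature vector is `(α(0), f(0), Δα, Δf)`.

**Classification.** An RBF-kernel SVM with stratified 5-fold
cross-validation and an inner grid search over C ∈ [0.5, 1.16·10⁶] and
γ ∈ [0.0722, 16], or a one-dimensional threshold rule on the first mode's
α: `threshold = (max α_pathological + min α_healthy)/2`, value strictly
below ⇒ positive.

All estimators are validated against multiplicative cascades — synthetic
textures whose spectrum is known in closed form (see
[docs/methods.md](docs/methods.md)).

## Worked example

```python
import numpy as np
from bemdmf import (
    BoxCountingConfig, CascadeSpec, cascade_analytic_spectrum,
    decompose, generate_binomial_cascade, legendre_spectrum, reconstruct,
)

# a 128x128 multiplicative-cascade texture with known spectrum
img = generate_binomial_cascade(CascadeSpec((0.4, 0.3, 0.2, 0.1), depth=7, seed=0))

stack = decompose(img)
print("modes:", stack.n_bimfs)                     # modes: 5
err = np.abs(reconstruct(stack) - img).max() / (img.max() - img.min())
print("reconstruction error:", err)                # ~1.3e-16

cfg = BoxCountingConfig(box_sizes=(2, 4, 8, 16, 32, 64))
spec = legendre_spectrum(img, cfg)
print(f"alpha0 = {spec.feature('alpha0'):.4f}")    # alpha0 = 2.1757
print(f"delta_alpha = {spec.delta_alpha:.4f}")     # delta_alpha = 1.7588

ref, _ = cascade_analytic_spectrum((0.4, 0.3, 0.2, 0.1), spec.q_grid)
print(f"analytic width = {ref.max() - ref.min():.4f}")  # 1.7588
```

The estimated apex `α(0) = 2.1757` and width `Δα = 1.7588` match the
cascade's closed form exactly, because on dyadic cascades with power-of-2
boxes the scaling relation is an exact line. The first extracted mode is
nearly monofractal (`Δα ≈ 0.02`): sifting has separated the fine-scale
oscillation from the multiplicative structure.

## Command line

```sh
bemdmf synth --n-per-class 10 --out-dir data/        # labeled synthetic set
bemdmf decompose data/synth_0000.tif --out-dir dec/  # BIMFs + residue + log
bemdmf spectrum data/synth_0000.tif --out spec.csv   # (q, alpha, f, D) table
bemdmf features data/manifest.csv --out features.csv
bemdmf classify features.csv --out report.json
bemdmf run --config run.yaml                         # end-to-end run directory
```

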