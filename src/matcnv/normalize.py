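"""Two-step read-depth normalization: LOESS GC correction, then
reference-panel PCA denoising.

Step 1 regresses raw bin counts on GC fraction with a robust locally
weighted (tricube, local-linear) smoother fitted on autosomal mappable
bins, divides counts by the fitted trend, and rescales so the autosomal
median ratio is exactly 1.  Step 2 removes the projection of the
autosomal ratio vector onto the top-k principal directions of a
CNV-sparse reference panel — higher-order population/batch artifacts
that GC correction cannot explain.  X-chromosome bins are median-scaled
but never projected: the panel is fitted on autosomes only (all
subjects are pregnant women, expected diploid X).

Noise is summarised per sample as 1.4826 x MAD of the autosomal ratios,
a robust SD estimate that CNV outlier bins cannot inflate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeModel
from .simulate import BinnedSample

MIN_BINS = 200


@dataclass
class NormalizedProfile:
    """Per-mappable-bin copy ratios, diploid expectation 1.0."""

    sample_id: str
    ratio: np.ndarray
    noise_sd: float


@dataclass
class ReferencePanel:
    """Mean profile and top-k orthonormal directions over autosomal bins."""

    mean_profile: np.ndarray   # length = n autosomal mappable bins
    components: np.ndarray     # (k, n autosomal mappable bins)
    k: int


def robust_sd(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation — SD under normality."""
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def loess_gc_correct(
    sample: BinnedSample,
    model: GenomeModel,
    span: float = 0.3,
    robust_iters: int = 2,
) -> NormalizedProfile:
    """Divide out the GC trend fitted on autosomal mappable bins.

    The smoother is evaluated at every mappable bin's GC (including X),
    so the correction extrapolates the autosomal trend to X.  Ratios are
    rescaled so the autosomal median is exactly 1.  A degenerate GC
    track (constant) skips the fit with a warning and returns
    median-scaled ratios.
    """
    mb = model.mappable_view()
    counts = np.asarray(sample.counts, dtype=float)
    if counts.size != mb.n:
        raise ValueError(
            f"sample has {counts.size} bins, model expects {mb.n}")
    if mb.n < MIN_BINS:
        raise ValueError(f"need >= {MIN_BINS} mappable bins, got {mb.n}")
    if not counts.any():
        raise ValueError("all-zero sample cannot be normalized")

    auto = mb.autosomal
    gc_a, cnt_a = mb.gc[auto], counts[auto]

    if np.ptp(gc_a) < 1e-6:
        warnings.warn("degenerate GC range; skipping LOESS correction")
        ratio = counts / np.median(cnt_a)
    else:
        fit = lowess(
            cnt_a, gc_a,
            frac=span, it=robust_iters,
            delta=0.01 * np.ptp(gc_a),
            return_sorted=True,
        )
        floor = 0.05 * max(np.median(fit[:, 1]), 1.0)
        pred = np.interp(mb.gc, fit[:, 0], fit[:, 1])
        ratio = counts / np.maximum(pred, floor)

    med = np.median(ratio[auto])
    if med <= 0:
        raise ValueError("median corrected ratio is non-positive")
    ratio = ratio / med
    return NormalizedProfile(
        sample_id=sample.sample_id,
        ratio=ratio,
        noise_sd=robust_sd(ratio[auto]),
    )


def fit_reference_panel(
    profiles: list[NormalizedProfile],
    model: GenomeModel,
    k: int = 3,
) -> ReferencePanel:
    """PCA of a CNV-sparse panel's autosomal ratios.

    Mean-centers the (samples x autosomal bins) ratio matrix and keeps
    the top-k right singular directions.  Sign is fixed by making each
    component's largest-magnitude coordinate positive, so the
    decomposition is deterministic.  Numerically null directions
    (singular value < 1e-8 of the largest) are dropped with a warning,
    reducing k.
    """
    n_samples = len(profiles)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= n_samples:
        raise ValueError(f"k={k} requires more than {n_samples} panel samples")
    if n_samples < k + 2:
        raise ValueError(f"need >= k+2 = {k + 2} panel samples")

    auto = model.mappable_view().autosomal
    X = np.stack([p.ratio[auto] for p in profiles])
    mean = X.mean(axis=0)
    if k == 0:
        return ReferencePanel(mean_profile=mean,
                              components=np.zeros((0, mean.size)), k=0)

    # Remove each centered row's DC component: overall depth scale is
    # the median normalization's job, so the panel captures shape only.
    # This also makes every component orthogonal to the constant vector,
    # which is what renders projection + re-centering exactly idempotent.
    Xc = X - mean
    Xc = Xc - Xc.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = (s[0] if s.size else 0.0) * 1e-8
    usable = int((s > tol).sum())
    if usable < k:
        warnings.warn(
            f"panel is rank-deficient: keeping {usable} of {k} requested "
            "components")
        k = usable
    comps = vt[:k].copy()
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return ReferencePanel(mean_profile=mean, components=comps, k=k)


def pca_denoise(
    profile: NormalizedProfile,
    panel: ReferencePanel,
    model: GenomeModel,
) -> NormalizedProfile:
    """Remove the panel subspace from a profile's autosomal ratios.

    Autosomal ratios become ``r - sum_k <r - mean, v_k> v_k``,
    re-centered so the autosomal median is exactly 1; X bins receive the
    same median re-centering but are never projected.  Because the
    panel components carry no DC component, the whole operation is
    exactly idempotent: a second application is a no-op to machine
    precision.  The noise SD is recomputed from the denoised autosomal
    ratios.
    """
    mb = model.mappable_view()
    auto = mb.autosomal
    if profile.ratio.size != mb.n:
        raise ValueError("profile does not match the model's bin grid")
    if panel.mean_profile.size != int(auto.sum()):
        raise ValueError("panel does not match the model's autosomal grid")

    r = profile.ratio[auto]
    if panel.k:
        coef = panel.components @ (r - panel.mean_profile)
        r = r - coef @ panel.components
    med = np.median(r)
    if med <= 0:
        raise ValueError("median denoised ratio is non-positive")

    out = profile.ratio - (med - 1.0)
    out[auto] = r - (med - 1.0)
    np.maximum(out, 0.0, out=out)  # ratios are physical, never negative
    return NormalizedProfile(
        sample_id=profile.sample_id,
        ratio=out,
        noise_sd=robust_sd(out[auto]),
    )


def normalize_cohort(
    samples: list[BinnedSample],
    model: GenomeModel,
    span: float = 0.3,
    k: int = 3,
    leave_one_out: bool = True,
) -> list[NormalizedProfile]:
    """GC-correct every sample, then PCA-denoise each against a panel of
    the others.

    Leave-one-out panels (default) prevent a sample's own CNVs from
    being absorbed into the subspace and subtracted from themselves —
    self-projection demonstrably erases true signal.  With
    ``leave_one_out=False`` one cohort-wide panel is fitted, appropriate
    when the analyzed sample is external to the panel.
    """
    corrected = [loess_gc_correct(s, model, span=span) for s in samples]
    if len(corrected) < k + 2:
        warnings.warn("cohort too small for PCA denoising; returning "
                      "GC-corrected profiles")
        return corrected
    if not leave_one_out:
        panel = fit_reference_panel(corrected, model, k=k)
        return [pca_denoise(p, panel, model) for p in corrected]
    out = []
    for i, p in enumerate(corrected):
        others = corrected[:i] + corrected[i + 1:]
        panel = fit_reference_panel(others, model,
                                    k=max(0, min(k, len(others) - 2)))
        out.append(pca_denoise(p, panel, model))
    return out
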