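"""Synthetic point-pattern generators with closed-form validation oracles.

No immunogold coordinate data accompany the study this pipeline targets,
so every stage is validated against generated patterns whose statistical
structure is known. The core model is the Thomas cluster process:
Poisson-distributed parents (intensity ``kappa`` per nm^2), a Poisson
number of offspring per parent (mean ``mu``), and isotropic Gaussian
offspring displacement (scale ``sigma`` nm). Its K-function has the
closed form

    K(r) = pi r^2 + (1 - exp(-r^2 / (4 sigma^2))) / kappa,

used as an independent oracle for the estimators. Defaults (50 parents
per um^2, 5 offspring each, sigma = 10 nm) give ~250 points per 1 um^2
image with cluster radii of tens of nm — the density and length scales
typical of gold-labeled membrane-protein nanoclusters.

Additional generators emulate what the experiments manipulate:
a curvature-response mixture (a fraction ``phi`` of points clustered,
the rest CSR), two-channel pairs that co-cluster (shared parents), are
independent, or segregate (hard-core exclusion), and independent
binomial thinning for incomplete antibody labeling.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .geometry import (
    BivariatePattern,
    PointPattern,
    PointPatternError,
    StudyRegion,
)

__all__ = [
    "ClusterProcessParams",
    "CurvatureResponseParams",
    "simulate_csr",
    "simulate_thomas",
    "thomas_k_closed_form",
    "simulate_curvature_response",
    "simulate_bivariate",
    "thin_by_labeling",
    "fit_thomas_params",
]

#: guard band around the window, in units of sigma, in which parents are
#: simulated so clusters straddling the boundary are not truncated.
GUARD_SIGMAS = 4.0


@dataclass(frozen=True)
class ClusterProcessParams:
    """Thomas-process and labeling parameters for the synthetic generator.

    kappa : parent intensity, parents per nm^2 (default 5e-5 = 50 per um^2)
    mu : mean offspring per parent (default 5)
    sigma : Gaussian offspring dispersion, nm (default 10)
    labeling_efficiency : independent retention probability in (0, 1]
    seed : default RNG seed when none is passed to a simulator
    """

    kappa: float = 5e-5
    mu: float = 5.0
    sigma: float = 10.0
    labeling_efficiency: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.mu <= 0 or self.sigma <= 0:
            raise PointPatternError("kappa, mu, sigma must all be > 0")
        if not 0.0 < self.labeling_efficiency <= 1.0:
            raise PointPatternError("labeling_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class CurvatureResponseParams:
    """Mixture emulating curvature-driven monomer/multimer shifts.

    ``phi`` is the clustered fraction: phi = 0 is pure CSR (all
    monomer-like), phi = 1 puts every point in Thomas clusters. The
    total per-region count is fixed at ``n_total`` so conditions differ
    in organization, not labeling density.
    """

    phi: float
    base: ClusterProcessParams = ClusterProcessParams()
    n_total: int = 250

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise PointPatternError(f"phi must be in [0, 1], got {self.phi}")
        if self.n_total < 1:
            raise PointPatternError("n_total must be >= 1")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _expanded(region: StudyRegion, sigma: float) -> StudyRegion:
    pad = GUARD_SIGMAS * sigma
    return StudyRegion(
        region.x_min - pad, region.y_min - pad, region.x_max + pad, region.y_max + pad
    )


def _uniform_in(rng, n: int, region: StudyRegion) -> np.ndarray:
    return rng.uniform(
        (region.x_min, region.y_min), (region.x_max, region.y_max), size=(n, 2)
    )


def simulate_csr(n: int, region: StudyRegion, seed=0, channel: str = "") -> PointPattern:
    """Exactly ``n`` independent uniform points (binomial CSR)."""
    if n < 0:
        raise PointPatternError("n must be >= 0")
    return PointPattern(_uniform_in(_rng(seed), n, region), region, channel)


def simulate_thomas(
    params: ClusterProcessParams,
    region: StudyRegion,
    seed=None,
    channel: str = "",
) -> PointPattern:
    """One realization of a (thinned) Thomas process on the region.

    Parents are Poisson in the region expanded by a 4-sigma guard band,
    offspring counts Poisson(mu), displacements isotropic Gaussian(sigma);
    offspring outside the window are discarded, then points are thinned
    independently at the labeling efficiency.
    """
    rng = _rng(params.seed if seed is None else seed)
    outer = _expanded(region, params.sigma)
    n_parents = rng.poisson(params.kappa * outer.area)
    parents = _uniform_in(rng, n_parents, outer)
    counts = rng.poisson(params.mu, size=n_parents)
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, params.sigma, size=centers.shape)
    pts = pts[region.contains(pts)] if len(pts) else pts.reshape(0, 2)
    if params.labeling_efficiency < 1.0 and len(pts):
        pts = pts[rng.random(len(pts)) < params.labeling_efficiency]
    return PointPattern(pts, region, channel)


def thomas_k_closed_form(params: ClusterProcessParams, r) -> np.ndarray | float:
    """Exact K(r) of the (unthinned) Thomas process; thinning leaves K unchanged."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise PointPatternError("r must be >= 0")
    k = np.pi * r**2 + (1.0 - np.exp(-(r**2) / (4.0 * params.sigma**2))) / params.kappa
    return float(k) if k.ndim == 0 else k


def _offspring_in_region(
    rng, parents: np.ndarray, n: int, sigma: float, region: StudyRegion
) -> np.ndarray:
    """Exactly n offspring inside the window, parents chosen uniformly.

    Points falling outside the window are redrawn (new parent and new
    displacement), which conditions the process on the in-window count.
    """
    out = np.empty((n, 2))
    need = np.arange(n)
    while len(need):
        pick = rng.integers(0, len(parents), size=len(need))
        cand = parents[pick] + rng.normal(0.0, sigma, size=(len(need), 2))
        ok = region.contains(cand)
        out[need[ok]] = cand[ok]
        need = need[~ok]
    return out


def _parents_for(rng, params: ClusterProcessParams, region: StudyRegion) -> np.ndarray:
    outer = _expanded(region, params.sigma)
    n_parents = rng.poisson(params.kappa * outer.area)
    while n_parents == 0:  # a conditioned draw needs at least one parent
        n_parents = rng.poisson(params.kappa * outer.area)
    return _uniform_in(rng, n_parents, outer)


def simulate_curvature_response(
    params: CurvatureResponseParams,
    region: StudyRegion,
    seed=0,
    channel: str = "",
) -> PointPattern:
    """Fixed-count mixture: Binomial(n_total, phi) clustered points, rest CSR."""
    rng = _rng(seed)
    n_clustered = int(rng.binomial(params.n_total, params.phi))
    parts = []
    if n_clustered:
        parents = _parents_for(rng, params.base, region)
        parts.append(
            _offspring_in_region(rng, parents, n_clustered, params.base.sigma, region)
        )
    n_csr = params.n_total - n_clustered
    if n_csr:
        parts.append(_uniform_in(rng, n_csr, region))
    pts = np.vstack(parts) if parts else np.empty((0, 2))
    return PointPattern(pts, region, channel)


def simulate_bivariate(
    mode: str,
    params: ClusterProcessParams,
    n_b: int,
    n_s: int,
    region: StudyRegion,
    seed=0,
) -> BivariatePattern:
    """Two-channel pattern with known cross-channel structure.

    colocalized : both channels are offspring of one SHARED parent set
    independent : each channel clusters around its own parent set
    segregated  : big channel clustered; small-channel CSR candidates
                  within 3 sigma of any big parent are rejected
    """
    if n_b < 1 or n_s < 1:
        raise PointPatternError("bivariate simulation needs n_b >= 1 and n_s >= 1")
    rng = _rng(seed)
    sigma = params.sigma
    if mode == "colocalized":
        parents = _parents_for(rng, params, region)
        big = _offspring_in_region(rng, parents, n_b, sigma, region)
        small = _offspring_in_region(rng, parents, n_s, sigma, region)
    elif mode == "independent":
        big = _offspring_in_region(rng, _parents_for(rng, params, region), n_b, sigma, region)
        small = _offspring_in_region(rng, _parents_for(rng, params, region), n_s, sigma, region)
    elif mode == "segregated":
        parents = _parents_for(rng, params, region)
        big = _offspring_in_region(rng, parents, n_b, sigma, region)
        small = np.empty((n_s, 2))
        exclusion = 3.0 * sigma
        filled = 0
        while filled < n_s:
            cand = _uniform_in(rng, n_s - filled, region)
            d2 = ((cand[:, None, :] - parents[None, :, :]) ** 2).sum(axis=2)
            ok = d2.min(axis=1) > exclusion**2
            kept = cand[ok]
            small[filled : filled + len(kept)] = kept
            filled += len(kept)
    else:
        raise PointPatternError(f"unknown bivariate mode {mode!r}")
    return BivariatePattern(
        big=PointPattern(big, region, "big"),
        small=PointPattern(small, region, "small"),
    )


def thin_by_labeling(pattern: PointPattern, efficiency: float, seed=0) -> PointPattern:
    """Independent binomial thinning (incomplete antibody labeling).

    Each point is retained with probability ``efficiency``; thinning
    leaves Ripley's K unchanged in expectation.
    """
    if not 0.0 < efficiency <= 1.0:
        raise PointPatternError(f"efficiency must be in (0, 1], got {efficiency}")
    if efficiency == 1.0:
        return pattern
    rng = _rng(seed)
    keep = rng.random(pattern.n) < efficiency
    return pattern.with_points(pattern.points[keep])


def fit_thomas_params(
    k_mean: np.ndarray,
    radii: np.ndarray,
    sigma0: float = 20.0,
    kappa0: float = 1e-4,
) -> ClusterProcessParams:
    """Recover (kappa, sigma) by least squares of a pooled K-hat curve
    against the Thomas closed form. ``mu`` does not enter K and is left
    at its default."""

    def model(r, kappa, sigma):
        return np.pi * r**2 + (1.0 - np.exp(-(r**2) / (4.0 * sigma**2))) / kappa

    popt, _ = curve_fit(
        model,
        np.asarray(radii, float),
        np.asarray(k_mean, float),
        p0=(kappa0, sigma0),
        bounds=([1e-8, 0.1], [1.0, 1e4]),
        maxfev=20000,
    )
    return ClusterProcessParams(kappa=float(popt[0]), sigma=float(popt[1]))
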