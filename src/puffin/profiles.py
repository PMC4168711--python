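"""Multi-scale nucleosome profiles and landscapes.

Each mapped fragment i is replaced by a Gaussian with mean at its midpoint
µ_i and standard deviation α·w_i, where w_i is the insert size and α a
smoothing scale.  The profile at scale α is the weighted sum

    S_α(x) = Σ_i β_i · φ(x; µ_i, α·w_i),        β_i = γ(w_i)/n,

with a penalty γ(w) < 1 down-weighting fragments shorter than the nucleosome
size so that short inserts do not dominate.  Because σ scales with each
fragment's own length, a loosely mapped pair (long insert) spreads its mass
wider than a tight one — this is what distinguishes the construction from
plain kernel smoothing of coverage.

A family of m profiles over an α grid is then normalized by one very-smooth
reference profile S_A (A well above every grid α) into landscapes

    N_α(x) = log (S_α(x)+ε) / (S_A(x)+ε),

which equalizes peak heights across coverage levels and cancels slowly
varying biases (mappability, digestion preference) present in both numerator
and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import FragmentRecord, GenomicRegion

log = logging.getLogger(__name__)


def default_gamma(w: float, nuc_size: int = 146) -> float:
    """Linear short-fragment penalty: γ(w) = min(1, w/nuc_size)."""
    return min(1.0, w / nuc_size)


@dataclass(frozen=True)
class ProfileConfig:
    """Fixed constants of the multi-scale construction.

    m
        number of smoothing scales (40).
    alpha_min, alpha_max
        bounds of the equally spaced α grid, both included ([0.05, 0.63]).
    low_res_alpha
        the reference scale A used for normalization (1.5); must exceed
        every grid α.
    epsilon
        pseudocount in the log ratio; only regularizes exact zeros.
    nuc_size
        nucleosome footprint in bp (146): the overlap threshold downstream
        and the knee of the weight penalty γ.
    truncation
        kernel support cutoff in units of σ; mass beyond ±6σ (< 2e-9) is
        dropped.
    gamma
        optional override for the fragment-length penalty; maps w to (0, 1],
        nondecreasing, 1 at and above nuc_size.
    """

    m: int = 40
    alpha_min: float = 0.05
    alpha_max: float = 0.63
    low_res_alpha: float = 1.5
    epsilon: float = 1e-6
    nuc_size: int = 146
    truncation: float = 6.0
    gamma: Callable[[float], float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.alpha_min < self.alpha_max:
            raise ValueError("need 0 < alpha_min < alpha_max")
        if self.low_res_alpha <= self.alpha_max:
            raise ValueError("low_res_alpha (A) must exceed alpha_max")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.truncation <= 0:
            raise ValueError("truncation must be > 0")

    @property
    def alpha_grid(self) -> np.ndarray:
        """m equally spaced scales from alpha_min to alpha_max inclusive."""
        if self.m == 1:
            return np.array([self.alpha_min])
        return np.linspace(self.alpha_min, self.alpha_max, self.m)

    def weight_factor(self, w: float) -> float:
        g = self.gamma(w) if self.gamma is not None else default_gamma(w, self.nuc_size)
        if not 0 < g <= 1:
            raise ValueError(f"gamma({w}) = {g} outside (0, 1]")
        return g


@dataclass
class ScaleProfile:
    """S_α sampled at every integer position of a region."""

    region: GenomicRegion
    alpha: float
    values: np.ndarray


@dataclass
class Landscape:
    """N_α = log((S_α+ε)/(S_A+ε)) sampled at every integer position."""

    region: GenomicRegion
    alpha: float
    values: np.ndarray


def read_kernel(alpha: float, w: int, truncation: float = 6.0,
                shift: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate the per-fragment Gaussian at integer offsets.

    Returns ``(offsets, values)`` where values are the density of a Gaussian
    with σ = α·w evaluated at ``offsets - shift``; with ``shift = 0`` the
    table is symmetric with its maximum at offset 0.  ``shift = 0.5``
    accounts for the half-integer midpoint of odd-length fragments.
    """
    sigma = alpha * w
    radius = int(np.ceil(truncation * sigma))
    radius = max(radius, 1)
    offsets = np.arange(-radius, radius + 1)
    x = offsets - shift
    values = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    values[np.abs(x) > truncation * sigma] = 0.0
    return offsets, values


def fragment_weight(w: int, n: int, config: ProfileConfig | None = None) -> float:
    """Weight β = γ(w)/n of one fragment among n."""
    if n == 0:
        raise ValueError("empty fragment set")
    if w <= 0:
        raise ValueError("fragment length must be positive")
    cfg = config or ProfileConfig()
    return cfg.weight_factor(w) / n


def _group_fragments(
    fragments: Sequence[FragmentRecord],
) -> dict[int, list[float]]:
    groups: dict[int, list[float]] = {}
    for f in fragments:
        groups.setdefault(f.length, []).append(f.midpoint)
    return groups


def compute_profile(
    fragments: Sequence[FragmentRecord],
    alpha: float,
    region: GenomicRegion,
    config: ProfileConfig | None = None,
    n: int | None = None,
    weights: Sequence[float] | None = None,
) -> ScaleProfile:
    """Sum the weighted, truncated per-fragment Gaussians over a region.

    Fragments sharing an insert size share a kernel, so each length class is
    accumulated as an impulse train convolved once with its kernel.  ``n``
    overrides the denominator of β (defaults to ``len(fragments)``);
    ``weights`` overrides β entirely (one value per fragment).
    """
    cfg = config or ProfileConfig()
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    values = np.zeros(region.length)
    if not fragments:
        log.warning("compute_profile: empty fragment list, returning zeros")
        return ScaleProfile(region, alpha, values)
    if weights is not None:
        if len(weights) != len(fragments):
            raise ValueError("weights length must match fragments")
        by_w: dict[int, tuple[list[float], list[float]]] = {}
        for f, b in zip(fragments, weights):
            mids_w, bs = by_w.setdefault(f.length, ([], []))
            mids_w.append(f.midpoint)
            bs.append(float(b))
        for w, (mids_w, bs) in by_w.items():
            _accumulate(values, region, alpha, w, mids_w, np.asarray(bs), cfg)
    else:
        # β depends only on w, so each insert-size class shares one weight
        n_eff = n if n is not None else len(fragments)
        for w, mids in _group_fragments(fragments).items():
            b = fragment_weight(w, n_eff, cfg)
            _accumulate(values, region, alpha, w, mids, np.full(len(mids), b), cfg)
    return ScaleProfile(region, alpha, values)


def _accumulate(values: np.ndarray, region: GenomicRegion, alpha: float,
                w: int, mids: Sequence[float], betas: np.ndarray,
                config: ProfileConfig) -> None:
    """Add one insert-size class to a profile via impulse-train convolution."""
    shift = 0.5 if w % 2 else 0.0
    _, kernel = read_kernel(alpha, w, config.truncation, shift=shift)
    radius = (len(kernel) - 1) // 2
    L = region.length
    imp = np.zeros(L + 2 * radius)
    anchors = np.floor(np.asarray(mids, dtype=float)).astype(np.int64)
    idx = anchors - region.start + radius
    keep = (idx >= 0) & (idx < len(imp))
    np.add.at(imp, idx[keep], betas[keep])
    if not np.any(keep):
        return
    # full convolution: genomic x maps to index (x - region.start) + 2*radius
    full = np.convolve(imp, kernel)
    values += full[2 * radius: 2 * radius + L]


def compute_landscape(profile: ScaleProfile, reference: ScaleProfile,
                      epsilon: float = 1e-6) -> Landscape:
    """Pointwise log-ratio of a profile to the low-resolution reference."""
    if profile.region != reference.region:
        raise ValueError("profile and reference cover different regions")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    ratio = (profile.values + epsilon) / (reference.values + epsilon)
    return Landscape(profile.region, profile.alpha, np.log(ratio))


def build_landscape_family(
    fragments: Sequence[FragmentRecord],
    region: GenomicRegion,
    config: ProfileConfig | None = None,
) -> tuple[list[Landscape], ScaleProfile]:
    """All m landscapes (increasing α), normalized by one shared S_A.

    The fragment count n used in the weights is the number of fragments
    passed in (per processed region); the same weights feed every scale and
    the reference, so the landscapes are invariant to rescaling n.
    """
    cfg = config or ProfileConfig()
    n = len(fragments)
    reference = compute_profile(fragments, cfg.low_res_alpha, region, cfg, n=n or 1)
    landscapes = [
        compute_landscape(
            compute_profile(fragments, a, region, cfg, n=n or 1),
            reference, cfg.epsilon,
        )
        for a in cfg.alpha_grid
    ]
    return landscapes, reference
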