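"""Synthetic communities and benchmark manifolds.

Two generators back the validation story:

* A gradient-driven community built from Gaussian coenoclines — unimodal
  species response curves spaced evenly along a one-dimensional
  environmental gradient. Samples taken along the gradient share fewer
  and fewer species as they move apart, so Bray-Curtis distances
  saturate at 1 beyond a few response-curve widths: exactly the regime
  that produces arches and horseshoes in ordination. Optional
  compositional noise is drawn from a Dirichlet distribution whose
  concentration vector is the parent sample's composition times a scale
  factor (larger scale, tighter noise).

* The Swiss roll, the classic manifold-unrolling benchmark: a 2-D sheet
  rolled up in 3-D, where Euclidean distance cuts across whorls but the
  intrinsic geometry follows the sheet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.datasets import make_swiss_roll

from .io import check_abundance_table

__all__ = [
    "CoenoclineParams",
    "SimulatedCommunity",
    "simulate_coenocline_community",
    "add_dirichlet_noise",
    "simulate_gradient_community",
    "swiss_roll",
]

#: Floor applied to Dirichlet concentrations so that features far from a
#: sample's gradient position (density underflows to 0) stay legal.
_CONCENTRATION_FLOOR = 1e-12


@dataclass(frozen=True)
class CoenoclineParams:
    """Knobs of the coenocline community generator.

    gradient_length : extent of the gradient in arbitrary units
        (default 1000).
    center_spacing : distance between adjacent species response-curve
        centers (default 10).
    sd : standard deviation of every Gaussian response curve; controls
        species turnover rate along the gradient (default 150).
    n_samples : base samples, evenly spaced over the full gradient
        (default 50).
    center_margin : how far beyond both gradient ends the response-curve
        centers extend, so edge samples see a full species pool; with
        the defaults the centers run from -650 to 1650 and the community
        has 231 features (default 650).
    noise_replicates_per_sample : Dirichlet noise draws per base sample
        (default 1, giving 100 samples in total).
    dirichlet_scale : concentration multiplier; larger values keep noise
        samples closer to their parent composition (default 500).
    seed : RNG seed for the noise draws.
    """

    gradient_length: float = 1000.0
    center_spacing: float = 10.0
    sd: float = 150.0
    n_samples: int = 50
    center_margin: float = 650.0
    noise_replicates_per_sample: int = 1
    dirichlet_scale: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("sd must be positive")
        if not self.center_spacing > 0:
            raise ValueError("center_spacing must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not self.dirichlet_scale > 0:
            raise ValueError("dirichlet_scale must be positive")
        if self.noise_replicates_per_sample < 0:
            raise ValueError("noise replicate count must be nonnegative")

    def feature_centers(self) -> np.ndarray:
        lo = -self.center_margin
        hi = self.gradient_length + self.center_margin
        n = int(np.floor((hi - lo) / self.center_spacing + 0.5)) + 1
        return lo + self.center_spacing * np.arange(n)


@dataclass(frozen=True)
class SimulatedCommunity:
    """A generated community: composition table plus ground truth.

    ``table`` rows are relative abundances (each sums to 1);
    ``positions`` holds every sample's true gradient coordinate (noise
    samples inherit their parent's); ``is_noise`` flags the Dirichlet
    replicates.
    """

    table: pd.DataFrame
    positions: np.ndarray
    is_noise: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.table.shape[0]

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "is_noise": self.is_noise},
            index=self.table.index,
        )


def simulate_coenocline_community(params: CoenoclineParams | None = None) -> SimulatedCommunity:
    """Sample a gradient community from Gaussian coenoclines.

    Every feature k has a Gaussian density curve centered at c_k; the
    sample at gradient position x receives raw abundance equal to each
    curve's density at x, then the row is closed to relative abundances
    (curve heights are arbitrary once compositions are formed). Base
    samples sit at ``n_samples`` evenly spaced positions spanning
    [0, gradient_length].
    """
    p = params or CoenoclineParams()
    centers = p.feature_centers()
    if centers.size < 2:
        raise ValueError("margin and spacing admit fewer than 2 features")
    positions = np.linspace(0.0, p.gradient_length, p.n_samples)
    raw = stats.norm.pdf(positions[:, None], loc=centers[None, :], scale=p.sd)
    comp = raw / raw.sum(axis=1, keepdims=True)
    width = len(str(p.n_samples))
    table = pd.DataFrame(
        comp,
        index=[f"s{i + 1:0{width}d}" for i in range(p.n_samples)],
        columns=[f"f{int(k) + 1}" for k in range(centers.size)],
    )
    check_abundance_table(table)
    return SimulatedCommunity(
        table, positions.copy(), np.zeros(p.n_samples, dtype=bool)
    )


def add_dirichlet_noise(
    community: SimulatedCommunity, params: CoenoclineParams | None = None
) -> SimulatedCommunity:
    """Append Dirichlet noise replicates of every base sample.

    Each base composition, scaled by ``dirichlet_scale`` (and floored at
    a tiny positive value), is the concentration vector of a Dirichlet
    draw; the draw's expectation is therefore the parent composition and
    the scale sets how tightly replicates cluster around it. Replicates
    inherit the parent's gradient position and are flagged as noise.
    """
    p = params or CoenoclineParams()
    if p.noise_replicates_per_sample == 0:
        return community
    rng = np.random.default_rng(p.seed)
    base = community.table.to_numpy()
    rows, labels, pos = [], [], []
    for rep in range(1, p.noise_replicates_per_sample + 1):
        conc = np.maximum(p.dirichlet_scale * base, _CONCENTRATION_FLOOR)
        for i in range(base.shape[0]):
            rows.append(rng.dirichlet(conc[i]))
            labels.append(f"{community.table.index[i]}_noise{rep}")
            pos.append(community.positions[i])
    noise = pd.DataFrame(rows, index=labels, columns=community.table.columns)
    table = pd.concat([community.table, noise])
    positions = np.concatenate([community.positions, pos])
    is_noise = np.concatenate(
        [community.is_noise, np.ones(len(rows), dtype=bool)]
    )
    return SimulatedCommunity(table, positions, is_noise)


def simulate_gradient_community(
    params: CoenoclineParams | None = None,
) -> SimulatedCommunity:
    """Base coenocline samples plus their Dirichlet noise replicates."""
    p = params or CoenoclineParams()
    return add_dirichlet_noise(simulate_coenocline_community(p), p)


def swiss_roll(n: int = 300, seed: int = 0):
    """Sample the Swiss roll manifold.

    Standard parametrization: u, v uniform on [0, 1],
    t = 1.5 pi (1 + 2u), point = (t cos t, 21 v, t sin t).

    Returns
    -------
    coordinates : ndarray of shape (n, 3)
        Ambient 3-D points.
    intrinsic : ndarray of shape (n, 2)
        The manifold coordinates ``(t, 21 v)`` — arc parameter and
        height — that a successful unrolling should recover.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    X, t = make_swiss_roll(n_samples=n, random_state=seed)
    return X, np.column_stack([t, X[:, 1]])
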