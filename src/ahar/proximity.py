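"""Per-class Gaussian mixture densities and statistical class proximity.

For every activity class a diagonal-covariance GMM is fitted on its pooled
(normalized) training frames. The dissimilarity between two classes is the
symmetrized Kullback-Leibler divergence KL(M||N) + KL(N||M), each direction
estimated by Monte Carlo: draw omega samples from the first density and
average the log density ratio. The data-poor class is then paired with the
candidate class of minimal symmetrized divergence — its donor for transfer
learning.

Note on orientation: the directed estimate implemented here is the standard
nonnegative form E_M[log p_M(x) - log p_N(x)]; the symmetrized sum is used
throughout so the pairing is orientation-free anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

DEFAULT_COMPONENTS = 16   # mixture modes per class density
DEFAULT_DRAWS = 2000      # Monte Carlo draws per KL direction

_VAR_FLOOR = 1e-6


@dataclass
class GaussianMixtureDensity:
    """Diagonal-covariance Gaussian mixture for one class."""

    weights: np.ndarray     # (C,) on the simplex
    means: np.ndarray       # (C, K)
    variances: np.ndarray   # (C, K) diagonal covariances
    feature_set: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(
            np.asarray(self.variances, dtype=np.float64))
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.variances < _VAR_FLOOR).any():
            self.variances = np.maximum(self.variances, _VAR_FLOOR)

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Log mixture density, computed in log-space (no underflow)."""
        x = np.atleast_2d(x)
        diff = x[:, None, :] - self.means[None, :, :]          # (n, C, K)
        per_comp = -0.5 * (
            (diff ** 2 / self.variances[None]).sum(-1)
            + np.log(2 * np.pi * self.variances).sum(-1)[None])
        return logsumexp(per_comp + np.log(self.weights)[None], axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        return (self.means[comp]
                + rng.standard_normal((n, self.n_dims))
                * np.sqrt(self.variances[comp]))


@dataclass
class TransferPairing:
    """A limited class matched to its statistically closest donor class."""

    limited_class: str
    donor_class: str
    divergence: float
    table: dict[str, float] = field(default_factory=dict)


def fit_gmm(features: np.ndarray, n_components: int = DEFAULT_COMPONENTS,
            seed: int = 0, feature_set: str = "",
            label: str | None = None) -> GaussianMixtureDensity:
    """Fit a diagonal-covariance GMM by k-means-initialized EM.

    ``features`` are the pooled frames of one class (n x K). Deterministic
    given ``seed``.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[0] < 10 * n_components:
        raise ValueError(
            f"only {features.shape[0]} frames for {n_components} components; "
            "use fewer components (need >= 10 frames per component)")
    gm = GaussianMixture(n_components=n_components, covariance_type="diag",
                         init_params="kmeans", max_iter=100, tol=1e-4,
                         reg_covar=_VAR_FLOOR, random_state=seed)
    gm.fit(features)
    return GaussianMixtureDensity(gm.weights_, gm.means_, gm.covariances_,
                                  feature_set=feature_set, label=label)


def mc_kl(m: GaussianMixtureDensity, n: GaussianMixtureDensity,
          draws: int = DEFAULT_DRAWS, seed: int = 0) -> float:
    """Monte Carlo estimate of the directed KL divergence KL(M||N).

    Averages log p_M(x) - log p_N(x) over ``draws`` samples x ~ M. Exactly
    zero when M and N are the same object (the ratio vanishes pointwise).
    """
    if m.n_dims != n.n_dims:
        raise ValueError(f"feature-space mismatch: {m.n_dims} vs {n.n_dims}")
    if m.feature_set and n.feature_set and m.feature_set != n.feature_set:
        raise ValueError(
            f"feature-set mismatch: {m.feature_set!r} vs {n.feature_set!r}")
    rng = np.random.default_rng(seed)
    x = m.sample(draws, rng)
    return float(np.mean(m.log_density(x) - n.log_density(x)))


def symmetrized_divergence(m: GaussianMixtureDensity,
                           n: GaussianMixtureDensity,
                           draws: int = DEFAULT_DRAWS,
                           seed: int = 0) -> float:
    """Symmetrized divergence KL(M||N) + KL(N||M).

    Both directions reuse the same seed for their own sampling, so swapping
    the arguments returns the identical value.
    """
    return mc_kl(m, n, draws, seed) + mc_kl(n, m, draws, seed)


def divergence_table(target: str, models: dict[str, GaussianMixtureDensity],
                     draws: int = DEFAULT_DRAWS,
                     seed: int = 0) -> dict[str, float]:
    """Symmetrized divergence from ``target`` to every other class."""
    return {c: symmetrized_divergence(models[target], g, draws, seed)
            for c, g in models.items() if c != target}


def closest_class(target: str, models: dict[str, GaussianMixtureDensity],
                  draws: int = DEFAULT_DRAWS, seed: int = 0) -> TransferPairing:
    """Pair a limited class with its minimum-divergence donor.

    Ties are broken toward the lexicographically smallest class id;
    deterministic given the seed.
    """
    if target not in models:
        raise KeyError(f"unknown class {target!r}")
    if len(models) < 2:
        raise ValueError("need at least two classes to find a donor")
    table = divergence_table(target, models, draws, seed)
    donor = min(sorted(table), key=table.__getitem__)
    return TransferPairing(limited_class=target, donor_class=donor,
                           divergence=table[donor], table=table)


def save_gmm(path: str, g: GaussianMixtureDensity) -> None:
    """Serialize a class density (arrays + metadata; bit-exact round trip)."""
    np.savez(path, weights=g.weights, means=g.means, variances=g.variances,
             feature_set=np.array(g.feature_set),
             label=np.array(g.label if g.label is not None else ""))


def load_gmm(path: str) -> GaussianMixtureDensity:
    z = np.load(path)
    label = str(z["label"])
    return GaussianMixtureDensity(z["weights"], z["means"], z["variances"],
                                  feature_set=str(z["feature_set"]),
                                  label=label or None)


def gaussian_kl_closed_form(mu0: np.ndarray, var0: np.ndarray,
                            mu1: np.ndarray, var1: np.ndarray) -> float:
    """Closed-form KL between two diagonal Gaussians (reference formula)."""
    mu0, var0 = np.asarray(mu0, float), np.asarray(var0, float)
    mu1, var1 = np.asarray(mu1, float), np.asarray(var1, float)
    return float(0.5 * np.sum(np.log(var1 / var0)
                              + (var0 + (mu0 - mu1) ** 2) / var1 - 1.0))
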