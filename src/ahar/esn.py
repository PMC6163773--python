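"""Echo-state-network (reservoir) feature-space transfer learning.

A reservoir network with fixed random input weights ``Win`` (L x K) and
recurrent weights ``Wres`` (L x L, rescaled to a target spectral radius)
maps donor-class feature frames through the state recursion

    x(k) = tanh(Win u(k-1) + Wres x(k-1)),   x(0) = 0,

and a linear readout ``Wout`` (L x K), the only trained part, reconstructs
limited-class frames y(k) = Wout x(k). The readout is ridge regression
(Tikhonov-regularized least squares) on reservoir states collected after a
washout period. ``L = 0`` degenerates to a direct ridge regression from
input frames to targets (no reservoir memory).

The trained transform turns donor-class clips into synthetic limited-class
clips, augmenting a data-poor class with statistically adapted material.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .features import FeatureSequence
from .proximity import TransferPairing

logger = logging.getLogger(__name__)

#: Hyperparameter grids explored during transform selection.
DEFAULT_GRID = {
    "spectral_radius": (0.8, 0.9, 0.95, 0.99),
    "reservoir_size": (0, 500, 1000, 5000, 10000),
    "input_scaling": (0.1, 0.5, 0.7, 0.95, 0.99),
    "ridge": (1e-6,),
}

DEFAULT_WASHOUT = 10


def _spectral_radius(w: np.ndarray) -> float:
    if w.shape[0] > 600:  # dense eig is cubic; Arnoldi for big reservoirs
        val = scipy.sparse.linalg.eigs(w, k=1, which="LM",
                                       return_eigenvectors=False,
                                       maxiter=10000, tol=1e-10)
        return float(np.abs(val[0]))
    return float(np.max(np.abs(np.linalg.eigvals(w))))


@dataclass
class ReservoirTransform:
    """Fixed random reservoir + trainable linear readout (the MIMO map).

    The readout acts on the reservoir state extended with a constant bias
    unit (for ``reservoir_size == 0``, on the input frame plus bias), so it
    can realize affine maps between feature spaces.
    """

    w_in: np.ndarray            # (L, K)
    w_res: np.ndarray           # (L, L)
    w_out: np.ndarray | None    # (L+1, K); (K+1, K) when L == 0
    spectral_radius: float
    input_scaling: float
    reservoir_size: int
    n_dims: int
    ridge: float = 1e-6
    washout: int = DEFAULT_WASHOUT
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.w_out is not None


@dataclass
class AugmentationPlan:
    """How much synthetic material to create for one limited class."""

    pairing: TransferPairing
    target_count: int
    washout: int = DEFAULT_WASHOUT
    pairing_strategy: str = "random_truncate"

    def __post_init__(self) -> None:
        if self.target_count < 0 or self.washout < 0:
            raise ValueError("target_count and washout must be >= 0")


def init_reservoir(n_dims: int, reservoir_size: int,
                   spectral_radius: float = 0.9, input_scaling: float = 0.5,
                   seed: int = 0, ridge: float = 1e-6,
                   washout: int = DEFAULT_WASHOUT) -> ReservoirTransform:
    """Draw the fixed random reservoir; deterministic given ``seed``.

    ``Wres`` is zero-mean Gaussian rescaled so its largest absolute
    eigenvalue equals ``spectral_radius``; ``Win`` is uniform in
    [-input_scaling, +input_scaling]. ``reservoir_size = 0`` builds the
    degenerate direct-readout model.
    """
    if n_dims < 1 or reservoir_size < 0:
        raise ValueError("need n_dims >= 1 and reservoir_size >= 0")
    if reservoir_size > 0 and spectral_radius <= 0:
        raise ValueError("spectral_radius must be > 0")
    rng = np.random.default_rng(seed)
    L, K = reservoir_size, n_dims
    if L == 0:
        w_in = np.zeros((0, K))
        w_res = np.zeros((0, 0))
    else:
        w_res = rng.standard_normal((L, L))
        w_res *= spectral_radius / _spectral_radius(w_res)
        w_in = rng.uniform(-input_scaling, input_scaling, size=(L, K))
    return ReservoirTransform(w_in=w_in, w_res=w_res, w_out=None,
                              spectral_radius=spectral_radius,
                              input_scaling=input_scaling,
                              reservoir_size=L, n_dims=K, ridge=ridge,
                              washout=washout, seed=seed)


def run_reservoir(rt: ReservoirTransform, inputs: np.ndarray) -> np.ndarray:
    """Drive the reservoir with a frame sequence; return states (T x L).

    Row t is the state reached after consuming input frame t, starting from
    x(0) = 0. With ``reservoir_size == 0`` the inputs themselves are
    returned (identity "states" for the direct readout).
    """
    u = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    if u.shape[1] != rt.n_dims:
        raise ValueError(f"input dim {u.shape[1]} != reservoir dim {rt.n_dims}")
    if rt.reservoir_size == 0:
        return u
    T = u.shape[0]
    states = np.empty((T, rt.reservoir_size))
    x = np.zeros(rt.reservoir_size)
    for t in range(T):
        x = np.tanh(rt.w_in @ u[t] + rt.w_res @ x)
        states[t] = x
    return states


def learn_readout(states: np.ndarray, targets: np.ndarray,
                  ridge: float = 1e-6) -> np.ndarray:
    """Ridge-regression readout: solve (X'X + eps*I) W = X'D.

    Uses a symmetric positive-definite solve rather than explicit matrix
    inversion; with ``ridge == 0`` the problem must be full rank.
    """
    X = np.atleast_2d(np.asarray(states, dtype=np.float64))
    D = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if X.shape[0] != D.shape[0]:
        raise ValueError("states and targets must have aligned rows")
    gram = X.T @ X
    rhs = X.T @ D
    if ridge == 0:
        if np.linalg.matrix_rank(gram) < gram.shape[0]:
            raise np.linalg.LinAlgError(
                "state matrix is rank deficient; use ridge > 0")
        w = scipy.linalg.solve(gram, rhs, assume_a="sym")
    else:
        w = scipy.linalg.solve(gram + ridge * np.eye(gram.shape[0]), rhs,
                               assume_a="pos")
    return w


def apply_transfer(rt: ReservoirTransform,
                   donor_seq: FeatureSequence) -> FeatureSequence:
    """Transform a donor clip into a synthetic limited-class clip.

    Output frame t is Wout x(t) (identity output activation); the first
    ``washout`` frames are discarded. The result is tagged synthetic with
    provenance back to the source clip.
    """
    if not rt.trained:
        raise ValueError("reservoir transform has no trained readout")
    states = run_reservoir(rt, donor_seq.values)
    out = _design(states[rt.washout:]) @ rt.w_out
    if out.shape[0] == 0:
        raise ValueError("donor sequence shorter than the washout period")
    meta = {"synthetic": True, "source_clip": donor_seq.clip_id,
            "transform_seed": rt.seed}
    return FeatureSequence(out, donor_seq.feature_set,
                           clip_id=f"tl:{donor_seq.clip_id}",
                           label=rt.meta.get("limited_class"), meta=meta)


def _gaussian_ot_map(donor_frames: np.ndarray, limited_frames: np.ndarray,
                     reg: float = 1e-6,
                     target_cov: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form optimal-transport map between two Gaussian moment fits.

    Returns (A, m_d, m_l) such that T(u) = m_l + A (u - m_d) pushes the
    donor's mean/covariance exactly onto the limited class's:
    A = Sd^-1/2 (Sd^1/2 Sl Sd^1/2)^1/2 Sd^-1/2.
    """
    def _mat_power(s: np.ndarray, p: float) -> np.ndarray:
        vals, vecs = np.linalg.eigh(s)
        vals = np.maximum(vals, reg)
        return (vecs * vals ** p) @ vecs.T

    m_d = donor_frames.mean(axis=0)
    m_l = limited_frames.mean(axis=0)
    k = donor_frames.shape[1]
    sd = np.cov(donor_frames, rowvar=False) + reg * np.eye(k)
    sl = (np.cov(limited_frames, rowvar=False) if target_cov is None
          else target_cov) + reg * np.eye(k)
    sd_half = _mat_power(sd, 0.5)
    sd_ihalf = _mat_power(sd, -0.5)
    mid = _mat_power(sd_half @ sl @ sd_half, 0.5)
    return sd_ihalf @ mid @ sd_ihalf, m_d, m_l


def _pair_sequences(donor: list[FeatureSequence],
                    limited: list[FeatureSequence],
                    rng: np.random.Generator,
                    strategy: str = "moment") -> list[tuple[np.ndarray,
                                                            np.ndarray]]:
    """Build supervised (donor frame, target frame) training pairs.

    There is no true frame correspondence between independent clips of two
    classes; pairing donor and limited frames by clip and index ("index")
    makes the regression target conditionally independent of the input, so
    the least-squares readout collapses onto the target marginal mean and
    the synthesized class loses essentially all its variance. The default
    "moment" coupling instead pairs every donor frame u(t), in natural
    temporal order, with its image under the closed-form Gaussian
    optimal-transport map between the two classes' pooled moments — the
    correspondence that moves the donor distribution onto the limited one
    while preserving its spread. The reservoir readout is then trained to
    realize that correspondence (and, with memory, to exploit temporal
    context around it).
    """
    if strategy == "moment":
        du = np.vstack([fs.values for fs in donor])
        dl = np.vstack([fs.values for fs in limited])
        # a handful of limited clips cannot expose the class's between-clip
        # spread; shrink its covariance toward the donor's (the premise of
        # the pairing is that the two classes are statistically close)
        lam = len(limited) / (len(limited) + 8.0)
        sl = np.cov(dl, rowvar=False)
        sd = np.cov(du, rowvar=False)
        sl = lam * sl + (1.0 - lam) * sd
        a, m_d, m_l = _gaussian_ot_map(du, dl, target_cov=sl)
        return [(fs.values, m_l + (fs.values - m_d) @ a.T) for fs in donor]
    if strategy == "index":
        order = rng.permutation(len(donor))
        picks = rng.integers(0, len(limited), size=len(donor))
        pairs = []
        for di, li in zip(order, picks):
            u, d = donor[di].values, limited[li].values
            t = min(u.shape[0], d.shape[0])
            pairs.append((u[:t], d[:t]))
        return pairs
    raise ValueError(f"unknown pairing strategy {strategy!r}")


def _design(states: np.ndarray) -> np.ndarray:
    """Readout design matrix: states extended with a constant bias unit."""
    return np.hstack([states, np.ones((states.shape[0], 1))])


def _collect(rt: ReservoirTransform,
             pairs: list[tuple[np.ndarray, np.ndarray]]
             ) -> tuple[np.ndarray, np.ndarray]:
    """Readout design rows and aligned targets, washout rows removed."""
    xs, ds = [], []
    for u, d in pairs:
        states = run_reservoir(rt, u)
        xs.append(_design(states[rt.washout:]))
        ds.append(d[rt.washout:])
    return np.vstack(xs), np.vstack(ds)


def learn_transfer(donor: list[FeatureSequence],
                   limited: list[FeatureSequence],
                   grid: dict | None = None, seed: int = 0,
                   washout: int = DEFAULT_WASHOUT,
                   val_fraction: float = 0.2,
                   pairing_strategy: str = "moment") -> ReservoirTransform:
    """Learn the donor-to-limited MIMO transform.

    Builds supervised frame pairs from randomly matched donor/limited clips,
    then exhaustively searches the hyperparameter grid, choosing the
    configuration with minimum mean-squared reconstruction error on a
    held-out share of the pairs; the winner is refit on all pairs.
    """
    if not donor or not limited:
        raise ValueError("donor and limited sets must both be non-empty")
    K = donor[0].n_dims
    if any(s.n_dims != K for s in donor + limited):
        raise ValueError("donor and limited must share feature dimensionality")
    grid = dict(DEFAULT_GRID, **(grid or {}))
    rng = np.random.default_rng(seed)
    pairs = _pair_sequences(donor, limited, rng, pairing_strategy)

    n_val = max(1, int(round(val_fraction * len(pairs)))) \
        if len(pairs) > 1 else 0
    train_pairs, val_pairs = pairs[n_val:], pairs[:n_val]

    combos = list(itertools.product(grid["reservoir_size"],
                                    grid["spectral_radius"],
                                    grid["input_scaling"],
                                    grid["ridge"]))
    best, best_err = None, np.inf
    for L, sr, scale, eps in combos:
        rt = init_reservoir(K, L, sr, scale, seed=seed, ridge=eps,
                            washout=washout)
        X, D = _collect(rt, train_pairs)
        try:
            w_out = learn_readout(X, D, ridge=eps)
        except np.linalg.LinAlgError:
            continue
        rt = replace(rt, w_out=w_out)
        if val_pairs:
            Xv, Dv = _collect(rt, val_pairs)
            err = float(np.mean((Xv @ w_out - Dv) ** 2))
        else:
            err = float(np.mean((X @ w_out - D) ** 2))
        logger.debug("transfer grid L=%d SR=%.2f scale=%.2f eps=%g -> "
                     "MSE %.4g", L, sr, scale, eps, err)
        if err < best_err:
            best, best_err = (L, sr, scale, eps), err
    if best is None:
        raise RuntimeError("no grid configuration produced a solvable readout")

    L, sr, scale, eps = best
    rt = init_reservoir(K, L, sr, scale, seed=seed, ridge=eps, washout=washout)
    X, D = _collect(rt, pairs)
    rt = replace(rt, w_out=learn_readout(X, D, ridge=eps))
    rt.meta.update({"validation_mse": best_err,
                    "limited_class": limited[0].label,
                    "donor_class": donor[0].label})
    return rt


def augment_class(corpus: list[FeatureSequence], plan: AugmentationPlan,
                  rt: ReservoirTransform,
                  rng: np.random.Generator | None = None
                  ) -> list[FeatureSequence]:
    """Append synthetic limited-class clips built from transformed donors.

    Donor clips are drawn from the given (training-fold) corpus; if fewer
    donors exist than ``target_count``, donors are resampled with
    replacement (logged). The input corpus is never modified.
    """
    rng = rng or np.random.default_rng(0)
    # synthetic clips are never donors: no second-generation synthesis
    donors = [fs for fs in corpus if fs.label == plan.pairing.donor_class
              and not fs.meta.get("synthetic")]
    if plan.target_count == 0:
        return list(corpus)
    if not donors:
        raise ValueError(
            f"no donor clips of class {plan.pairing.donor_class!r}")
    if len(donors) < plan.target_count:
        logger.info("augment: resampling %d donor clips to reach %d "
                    "synthetic items", len(donors), plan.target_count)
        idx = list(range(len(donors)))
        idx += list(rng.integers(0, len(donors),
                                 size=plan.target_count - len(donors)))
    else:
        idx = list(rng.permutation(len(donors))[:plan.target_count])
    out = list(corpus)
    for j, i in enumerate(idx):
        syn = apply_transfer(rt, donors[i])
        syn.label = plan.pairing.limited_class
        syn.clip_id = f"tl:{plan.pairing.limited_class}:{j}:{donors[i].clip_id}"
        out.append(syn)
    return out


def save_transform(path: str, rt: ReservoirTransform) -> None:
    """Serialize all matrices and hyperparameters (bit-exact round trip)."""
    np.savez(path, w_in=rt.w_in, w_res=rt.w_res,
             w_out=rt.w_out if rt.w_out is not None else np.empty(0),
             trained=np.array(rt.trained),
             params=np.array([rt.spectral_radius, rt.input_scaling,
                              rt.reservoir_size, rt.n_dims, rt.ridge,
                              rt.washout, rt.seed]))


def load_transform(path: str) -> ReservoirTransform:
    z = np.load(path)
    sr, scale, L, K, eps, washout, seed = z["params"]
    return ReservoirTransform(
        w_in=z["w_in"], w_res=z["w_res"],
        w_out=z["w_out"] if bool(z["trained"]) else None,
        spectral_radius=float(sr), input_scaling=float(scale),
        reservoir_size=int(L), n_dims=int(K), ridge=float(eps),
        washout=int(washout), seed=int(seed))
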