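"""Hidden-Markov-model recognition of activity sound events.

Two generative schemes are supported:

* **Class-specific models** — one left-right HMM per activity class with
  diagonal-covariance GMM emissions, trained by Baum-Welch on that class's
  clips only. Left-right topology (self-loop + advance-by-one) suits the
  mostly forward-evolving structure of everyday sound events.
* **Universal model** — a single ergodic (fully connected) HMM trained on
  the pooled corpus; per-class recognizers are derived from it by MAP
  adaptation of the emission means toward each class's data, controlled by
  a relevance factor. This shares statistical strength across classes and
  is robust to per-class data scarcity.

Classification scores a clip under every class model with the forward
algorithm, normalizes by frame count so clip length does not bias the
decision, and picks the maximum-likelihood class (ties to the lower class
index).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GMMHMM

logger = logging.getLogger(__name__)

#: Default search grids: class-specific and universal model complexity.
CLASS_STATE_GRID = (3, 4, 5, 6, 7)
CLASS_COMPONENT_GRID = (2, 4, 8, 16, 32, 64, 128)
UNIVERSAL_STATE_GRID = (5, 6, 7, 8, 9, 10)
UNIVERSAL_COMPONENT_GRID = (64, 128, 256, 512)  # total emission components

BAUM_WELCH_ITER = 25
BAUM_WELCH_TOL = 1e-3
DEFAULT_RELEVANCE = 16.0


@dataclass
class ActivityHMM:
    """A trained HMM for one class (or the universal background)."""

    model: GMMHMM
    topology: str                 # "left_right" | "ergodic"
    label: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.model.n_components

    @property
    def transmat(self) -> np.ndarray:
        return self.model.transmat_

    @property
    def startprob(self) -> np.ndarray:
        return self.model.startprob_

    def loglik(self, values: np.ndarray, per_frame: bool = True) -> float:
        """Forward log-likelihood, optionally normalized by frame count."""
        ll = float(self.model.score(np.atleast_2d(values)))
        return ll / values.shape[0] if per_frame else ll

    @property
    def convergence_history(self) -> list[float]:
        """Baum-Welch log-likelihood per iteration."""
        return list(self.model.monitor_.history)


@dataclass
class RecognizerBundle:
    """One recognizer per class, plus the background model in universal mode."""

    mode: str                                  # class_specific | universal_adapted
    models: dict[str, ActivityHMM]
    background: ActivityHMM | None = None
    selection: dict = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return sorted(self.models)


def _left_right_transmat(n_states: int) -> np.ndarray:
    """Self-loop + advance-by-one transitions, uniformly initialized."""
    a = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        a[i, i] = a[i, i + 1] = 0.5
    a[-1, -1] = 1.0
    return a


def _stack(sequences: list[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    lengths = [s.shape[0] for s in sequences]
    return np.vstack(sequences), lengths


def _make_gmmhmm(n_states: int, n_mix: int, seed: int,
                 covars_prior: float = 1.0, params: str = "tmcw",
                 n_iter: int = BAUM_WELCH_ITER) -> GMMHMM:
    # the inverse-gamma covariance prior (strength ~2 pseudo-frames) keeps
    # mixture components from collapsing onto single frames
    return GMMHMM(n_components=n_states, n_mix=n_mix, covariance_type="diag",
                  n_iter=n_iter, tol=BAUM_WELCH_TOL,
                  random_state=seed, init_params="mcw", params=params,
                  min_covar=1e-3, covars_prior=covars_prior,
                  covars_weight=2.0)


def _segmented_means(sequences: list[np.ndarray], n_states: int,
                     n_mix: int, seed: int) -> np.ndarray:
    """Flat-start means for a left-right model by temporal segmentation.

    Each sequence is cut into n_states consecutive chunks; state s's mixture
    means are k-means centers of the pooled s-th chunks. This respects the
    temporal state order, which a global clustering init cannot (the
    left-right constraint forbids reordering states during reestimation).
    """
    from sklearn.cluster import KMeans

    k = sequences[0].shape[1]
    means = np.empty((n_states, n_mix, k))
    for s in range(n_states):
        pool = np.vstack([np.array_split(seq, n_states)[s]
                          for seq in sequences])
        if n_mix == 1 or pool.shape[0] < 2 * n_mix:
            means[s] = pool.mean(axis=0)[None]
        else:
            km = KMeans(n_clusters=n_mix, n_init=3, max_iter=50,
                        random_state=seed).fit(pool)
            means[s] = km.cluster_centers_
    return means


def train_class_hmm(sequences: list[np.ndarray], n_states: int = 3,
                    n_components: int = 2, seed: int = 0,
                    label: str | None = None,
                    n_iter: int = BAUM_WELCH_ITER) -> ActivityHMM:
    """Baum-Welch training of a left-right HMM on one class's sequences.

    Sequences shorter than ``n_states`` frames are skipped with a warning;
    emissions are diagonal-covariance GMMs with k-means-based
    initialization. Zero transitions of the left-right topology remain zero
    under every reestimation step.
    """
    usable = [np.atleast_2d(s) for s in sequences
              if np.atleast_2d(s).shape[0] > n_states]
    skipped = len(sequences) - len(usable)
    if skipped:
        logger.warning("train_class_hmm(%s): skipped %d sequence(s) shorter "
                       "than %d frames", label, skipped, n_states + 1)
    if not usable:
        raise ValueError(f"no usable sequences for class {label!r}")
    if len(usable) < 2:
        raise ValueError(f"need >= 2 sequences for class {label!r}")
    X, lengths = _stack(usable)
    hmm = _make_gmmhmm(n_states, n_components, seed,
                       covars_prior=float(X.var(axis=0).mean()),
                       n_iter=n_iter)
    hmm.init_params = "cw"  # means come from temporal segmentation below
    hmm.startprob_ = np.eye(n_states)[0]
    hmm.transmat_ = _left_right_transmat(n_states)
    hmm.means_ = _segmented_means(usable, n_states, n_components, seed)
    hmm.fit(X, lengths)
    return ActivityHMM(hmm, topology="left_right", label=label,
                       meta={"n_states": n_states, "n_mix": n_components,
                             "seed": seed})


def train_universal_hmm(sequences: list[np.ndarray], n_states: int = 5,
                        total_components: int = 64, seed: int = 0,
                        n_iter: int = BAUM_WELCH_ITER) -> ActivityHMM:
    """Ergodic background HMM trained on the pooled multi-class corpus.

    ``total_components`` is the overall emission complexity, distributed
    evenly across states (at least one component per state).
    """
    usable = [np.atleast_2d(s) for s in sequences
              if np.atleast_2d(s).shape[0] > n_states]
    if not usable:
        raise ValueError("no usable sequences for the universal model")
    n_mix = max(1, int(round(total_components / n_states)))
    X, lengths = _stack(usable)
    hmm = _make_gmmhmm(n_states, n_mix, seed,
                       covars_prior=float(X.var(axis=0).mean()),
                       params="stmcw", n_iter=n_iter)
    hmm.startprob_ = np.full(n_states, 1.0 / n_states)
    hmm.transmat_ = np.full((n_states, n_states), 1.0 / n_states)
    hmm.fit(X, lengths)
    return ActivityHMM(hmm, topology="ergodic", label=None,
                       meta={"n_states": n_states, "n_mix": n_mix,
                             "total_components": total_components,
                             "seed": seed})


def _mixture_log_density(model: GMMHMM, x: np.ndarray) -> np.ndarray:
    """Per-(frame, state, mixture) Gaussian log density, (T, S, M)."""
    mu = model.means_                      # (S, M, K)
    var = model.covars_                    # (S, M, K) diagonal
    diff = x[:, None, None, :] - mu[None]
    return -0.5 * ((diff ** 2 / var[None]).sum(-1)
                   + np.log(2 * np.pi * var).sum(-1)[None])


def adapt_universal(background: ActivityHMM,
                    sequences: list[np.ndarray],
                    relevance: float = DEFAULT_RELEVANCE,
                    label: str | None = None,
                    adapt_weights: bool = True) -> ActivityHMM:
    """MAP adaptation of emission means (and weights) toward one class's data.

    Responsibilities come from the background model's forward-backward state
    posteriors refined by within-state mixture posteriors. Each mean moves
    toward the class data's posterior mean with weight n/(n + relevance):
    infinite relevance leaves the background untouched; relevance -> 0 with
    abundant data converges to the data posterior means. Mixture weights are
    adapted the same way (emphasizing the components each class actually
    populates) and renormalized per state; transitions and covariances are
    inherited from the background.
    """
    import copy

    usable = [np.atleast_2d(s) for s in sequences]
    if not usable:
        logger.warning("adapt_universal(%s): no class data; returning "
                       "background copy", label)
        model = copy.deepcopy(background.model)
        return ActivityHMM(model, background.topology, label=label,
                           meta=dict(background.meta))

    model = copy.deepcopy(background.model)
    S, M, K = model.means_.shape
    n = np.zeros((S, M))
    ex = np.zeros((S, M, K))
    for seq in usable:
        gamma = model.predict_proba(seq)                    # (T, S)
        comp_log = _mixture_log_density(model, seq)         # (T, S, M)
        comp_log += np.log(np.maximum(model.weights_, 1e-300))[None]
        comp_log -= comp_log.max(axis=2, keepdims=True)
        post = np.exp(comp_log)
        post /= post.sum(axis=2, keepdims=True)
        resp = gamma[:, :, None] * post                     # (T, S, M)
        n += resp.sum(axis=0)
        ex += np.einsum("tsm,tk->smk", resp, seq)

    alpha = n / (n + relevance)                             # (S, M)
    data_mean = ex / np.maximum(n, 1e-12)[:, :, None]
    model.means_ = (alpha[:, :, None] * data_mean
                    + (1.0 - alpha[:, :, None]) * model.means_)
    if adapt_weights:
        state_n = np.maximum(n.sum(axis=1, keepdims=True), 1e-12)
        w = alpha * (n / state_n) + (1.0 - alpha) * model.weights_
        model.weights_ = w / w.sum(axis=1, keepdims=True)
    return ActivityHMM(model, background.topology, label=label,
                       meta={**background.meta, "relevance": relevance,
                             "adapted": True})


def classify(bundle: RecognizerBundle,
             values: np.ndarray) -> tuple[str, dict[str, float]]:
    """Maximum-likelihood classification of one feature sequence.

    Scores are forward log-likelihoods per frame; the argmax over classes
    (in sorted class-id order, so exact ties resolve to the lower index)
    is returned together with the full score table.
    """
    x = np.atleast_2d(values)
    scores: dict[str, float] = {}
    for label in bundle.classes:
        try:
            scores[label] = bundle.models[label].loglik(x)
        except (ValueError, np.linalg.LinAlgError):
            scores[label] = -np.inf
    if not np.isfinite(list(scores.values())).any():
        raise ValueError("sequence has non-finite likelihood under every model")
    arr = np.array([scores[c] for c in bundle.classes])
    # argmax returns the first of equal maxima: ties go to the lower class id
    best = bundle.classes[int(np.argmax(arr))]
    return best, scores


def select_model(candidates: dict[tuple[int, int], RecognizerBundle],
                 validation: list) -> tuple[int, int]:
    """Pick (n_states, n_components) maximizing validation accuracy.

    ``validation`` holds objects with ``.values`` and ``.label``. Ties are
    broken toward the smallest model: fewest states, then fewest components.
    """
    if not candidates:
        raise ValueError("no candidate models")
    if not validation:
        raise ValueError("validation set is empty")
    scores = {}
    for key, bundle in candidates.items():
        correct = sum(classify(bundle, fs.values)[0] == fs.label
                      for fs in validation)
        scores[key] = correct / len(validation)
    return min(sorted(scores), key=lambda k: (-scores[k], k[0], k[1]))


# ---------------------------------------------------------------------------
# Serialization: one directory per bundle, npz matrices + JSON metadata
# ---------------------------------------------------------------------------

def _save_hmm(path: str, ah: ActivityHMM) -> None:
    m = ah.model
    np.savez(path, startprob=m.startprob_, transmat=m.transmat_,
             means=m.means_, covars=m.covars_, weights=m.weights_)


def _load_hmm(path: str, topology: str, label: str | None,
              meta: dict) -> ActivityHMM:
    z = np.load(path)
    S, M, _ = z["means"].shape
    hmm = _make_gmmhmm(S, M, seed=0)
    hmm.startprob_ = z["startprob"]
    hmm.transmat_ = z["transmat"]
    hmm.means_ = z["means"]
    hmm.covars_ = z["covars"]
    hmm.weights_ = z["weights"]
    return ActivityHMM(hmm, topology, label=label, meta=meta)


def save_bundle(directory: str | os.PathLike, bundle: RecognizerBundle) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    index = {"mode": bundle.mode, "selection": bundle.selection,
             "classes": {}, "background": None}
    for label, ah in bundle.models.items():
        fname = f"class_{label}.npz"
        _save_hmm(os.path.join(directory, fname), ah)
        index["classes"][label] = {"file": fname, "topology": ah.topology,
                                   "meta": ah.meta}
    if bundle.background is not None:
        _save_hmm(os.path.join(directory, "background.npz"), bundle.background)
        index["background"] = {"file": "background.npz",
                               "topology": bundle.background.topology,
                               "meta": bundle.background.meta}
    with open(os.path.join(directory, "bundle.json"), "w") as fh:
        json.dump(index, fh, indent=1)


def load_bundle(directory: str | os.PathLike) -> RecognizerBundle:
    directory = os.fspath(directory)
    with open(os.path.join(directory, "bundle.json")) as fh:
        index = json.load(fh)
    models = {}
    for label, entry in index["classes"].items():
        models[label] = _load_hmm(os.path.join(directory, entry["file"]),
                                  entry["topology"], label, entry["meta"])
    background = None
    if index["background"]:
        e = index["background"]
        background = _load_hmm(os.path.join(directory, e["file"]),
                               e["topology"], None, e["meta"])
    return RecognizerBundle(mode=index["mode"], models=models,
                            background=background,
                            selection=index["selection"])
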