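"""End-to-end experiment orchestration with cross-validated evaluation.

One experiment = repeated stratified k-fold cross-validation of up to four
recognizer variants on one corpus:

* ``chmm``    — class-specific left-right HMMs,
* ``chmm_tl`` — the same after transfer-learning augmentation,
* ``uhmm``    — universal ergodic HMM with MAP-adapted class models,
* ``uhmm_tl`` — the universal scheme on the augmented training folds.

Per repetition and fold: the feature normalizer is fitted on the training
folds; class proximities, the reservoir transform and all synthetic material
are computed from training folds only (a programmatic leakage audit verifies
this every fold); the test fold is scored and aggregated into row-normalized
confusion matrices. The average recognition rate is the unweighted mean of
per-class recalls (the diagonal of the row-normalized confusion matrix).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import esn, hmm, proximity
from .audio import AudioClip
from .features import (FeatureNormalizer, FeatureSequence, extract_features)

logger = logging.getLogger(__name__)

SYSTEMS = ("chmm", "chmm_tl", "uhmm", "uhmm_tl")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    feature_set: str = "concatenated"
    normalize: bool = True
    systems: tuple[str, ...] = SYSTEMS
    folds: int = 3
    repetitions: int = 50
    seed: int = 0
    # class proximity
    gmm_components: int = proximity.DEFAULT_COMPONENTS
    kl_draws: int = proximity.DEFAULT_DRAWS
    max_gmm_frames: int = 20000        # per-class frame cap for density fits
    # transfer learning
    esn_grid: dict = field(default_factory=lambda: dict(esn.DEFAULT_GRID))
    washout: int = esn.DEFAULT_WASHOUT
    augment_target: str | int = "median"
    limited_fraction: float = 0.5      # limited if count < fraction * median
    # recognizers
    class_state_grid: tuple[int, ...] = hmm.CLASS_STATE_GRID
    class_component_grid: tuple[int, ...] = hmm.CLASS_COMPONENT_GRID
    universal_state_grid: tuple[int, ...] = hmm.UNIVERSAL_STATE_GRID
    universal_component_grid: tuple[int, ...] = hmm.UNIVERSAL_COMPONENT_GRID
    relevance: float = hmm.DEFAULT_RELEVANCE
    hmm_iterations: int = hmm.BAUM_WELCH_ITER

    def __post_init__(self) -> None:
        unknown = set(self.systems) - set(SYSTEMS)
        if unknown:
            raise ValueError(f"unknown systems: {sorted(unknown)}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @classmethod
    def scaled_down(cls, **overrides) -> "ExperimentConfig":
        """A reduced-problem-size configuration for desk-scale studies.

        MFCC features only, singleton recognizer grids and a small
        reservoir grid; the statistical structure of the experiment
        (stratified 3-fold CV, imbalance handling, all four systems) is
        unchanged.
        """
        base = dict(
            feature_set="mfcc", repetitions=10, max_gmm_frames=4000,
            esn_grid={"reservoir_size": (0, 100),
                      "spectral_radius": (0.9,),
                      "input_scaling": (0.5,),
                      "ridge": (1e-2,)},
            class_state_grid=(3,), class_component_grid=(2,),
            universal_state_grid=(4,), universal_component_grid=(8,),
            hmm_iterations=10,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["esn_grid"] = {k: list(v) for k, v in self.esn_grid.items()}
        for k in ("systems", "class_state_grid", "class_component_grid",
                  "universal_state_grid", "universal_component_grid"):
            d[k] = list(d[k])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for k in ("systems", "class_state_grid", "class_component_grid",
                  "universal_state_grid", "universal_component_grid"):
            if k in raw:
                raw[k] = tuple(raw[k])
        if "esn_grid" in raw:
            raw["esn_grid"] = {k: tuple(v) for k, v in raw["esn_grid"].items()}
        return cls(**raw)


@dataclass
class EvaluationReport:
    """Aggregated cross-validation outcome for every evaluated system."""

    classes: list[str]
    confusion: dict[str, pd.DataFrame]          # row-normalized %, per system
    average_rate: dict[str, float]              # mean of per-rep rates, %
    per_repetition: dict[str, list[float]]      # rate per repetition, %
    per_class_recall: dict[str, pd.Series]      # %, per system
    pairings: list[dict]
    predictions: pd.DataFrame
    config: dict
    config_hash: str
    leakage_checks: int = 0


class LeakageError(RuntimeError):
    """A test-fold clip leaked into a training-side computation."""


def stratified_folds(labels: list[str], k: int = 3,
                     seed: int = 0) -> np.ndarray:
    """Class-stratified fold assignment.

    Returns an integer array: entry i is the test fold of clip i, or -1 for
    clips of classes with fewer than ``k`` members, which stay in training
    for every fold (logged). Per class, fold sizes differ by at most one
    clip; folds are disjoint and exhaustive.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = list(labels)
    rng = np.random.default_rng(seed)
    assign = np.full(len(labels), -1, dtype=int)
    for cls in sorted(set(labels)):
        idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
        if idx.size < k:
            logger.warning("class %r has %d < %d clips; kept in training "
                           "for all folds", cls, idx.size, k)
            continue
        idx = rng.permutation(idx)
        # balanced remainder: first (n mod k) folds get the extra clip
        folds = np.arange(idx.size) % k
        assign[idx] = folds
    return assign


def _pooled_frames(seqs: list[FeatureSequence], cap: int,
                   rng: np.random.Generator) -> np.ndarray:
    x = np.vstack([s.values for s in seqs])
    if x.shape[0] > cap:
        x = x[rng.choice(x.shape[0], size=cap, replace=False)]
    return x


def compute_pairings(by_class: dict[str, list[FeatureSequence]],
                     limited: list[str], config: ExperimentConfig,
                     seed: int) -> dict[str, proximity.TransferPairing]:
    """Fit per-class GMMs on training frames and pair each limited class.

    Donor candidates are the classes with strictly more training clips than
    the limited class — a donor must actually have data to give. If no such
    class exists the search falls back to all other classes.
    """
    rng = np.random.default_rng(seed)
    models = {}
    for cls, seqs in by_class.items():
        frames = _pooled_frames(seqs, config.max_gmm_frames, rng)
        n_comp = min(config.gmm_components, max(1, frames.shape[0] // 10))
        models[cls] = proximity.fit_gmm(frames, n_comp, seed=seed,
                                        label=cls)
    counts = {c: len(s) for c, s in by_class.items()}
    pairings = {}
    for cls in limited:
        cands = {c: models[c] for c in models
                 if c == cls or counts[c] > counts[cls]}
        if len(cands) < 2:
            cands = models
        pairings[cls] = proximity.closest_class(cls, cands, config.kl_draws,
                                                seed)
    return pairings


def _limited_classes(by_class: dict[str, list[FeatureSequence]],
                     fraction: float = 0.5) -> list[str]:
    """Classes whose training count falls below ``fraction`` of the median.

    Augmentation only pays off for severely under-represented classes;
    classes near the median already have enough real material and synthetic
    frames would dilute their models.
    """
    counts = {c: len(s) for c, s in by_class.items()}
    med = float(np.median(list(counts.values())))
    return sorted(c for c, n in counts.items() if n < fraction * med)


def augment_training_set(train: list[FeatureSequence],
                         config: ExperimentConfig, seed: int
                         ) -> tuple[list[FeatureSequence], list[dict]]:
    """Transfer-learning augmentation of the training folds.

    Classes below the median training-fold size are raised to the median by
    appending reservoir-transformed donor clips. Returns the augmented set
    and the pairing records.
    """
    by_class: dict[str, list[FeatureSequence]] = {}
    for fs in train:
        by_class.setdefault(fs.label, []).append(fs)
    limited = _limited_classes(by_class, config.limited_fraction)
    if not limited:
        return list(train), []
    pairings = compute_pairings(by_class, limited, config, seed)
    counts = {c: len(s) for c, s in by_class.items()}
    if config.augment_target == "median":
        target_size = int(round(np.median(list(counts.values()))))
    else:
        target_size = int(config.augment_target)

    out = list(train)
    records = []
    for i, cls in enumerate(limited):
        pairing = pairings[cls]
        rt = esn.learn_transfer(by_class[pairing.donor_class],
                                by_class[cls], grid=config.esn_grid,
                                seed=(seed + 7919 * (i + 1)) % (2 ** 31),
                                washout=config.washout)
        n_new = max(0, target_size - counts[cls])
        plan = esn.AugmentationPlan(pairing, target_count=n_new,
                                    washout=config.washout)
        # synthesize from the original training folds, not from earlier
        # synthetic additions
        out.extend(esn.augment_class(train, plan, rt,
                                     rng=np.random.default_rng(seed + i)
                                     )[len(train):])
        records.append({"limited_class": cls,
                        "donor_class": pairing.donor_class,
                        "divergence": pairing.divergence,
                        "table": pairing.table,
                        "synthesized": n_new,
                        "reservoir_size": rt.reservoir_size,
                        "spectral_radius": rt.spectral_radius,
                        "input_scaling": rt.input_scaling})
    return out, records


def audit_no_leakage(train: list[FeatureSequence],
                     test: list[FeatureSequence]) -> None:
    """Raise LeakageError if any test clip fed a training-side computation.

    Checks that train/test clip ids are disjoint and that every synthetic
    clip's source is a training clip.
    """
    test_ids = {fs.clip_id for fs in test}
    train_ids = {fs.clip_id for fs in train if not fs.meta.get("synthetic")}
    overlap = test_ids & train_ids
    if overlap:
        raise LeakageError(f"test clips in training set: {sorted(overlap)[:5]}")
    for fs in train:
        if fs.meta.get("synthetic"):
            src = fs.meta.get("source_clip")
            if src in test_ids or src not in train_ids:
                raise LeakageError(
                    f"synthetic clip {fs.clip_id!r} sourced from non-training "
                    f"clip {src!r}")


def _train_chmm(by_class: dict[str, list[FeatureSequence]],
                config: ExperimentConfig, seed: int) -> hmm.RecognizerBundle:
    grids = [(s, m) for s in config.class_state_grid
             for m in config.class_component_grid]
    selection = grids[0]
    if len(grids) > 1:
        inner_train, inner_val = _inner_split(by_class, seed)
        candidates = {}
        for s, m in grids:
            try:
                candidates[(s, m)] = _fit_chmm_bundle(
                    inner_train, s, m, seed, config.hmm_iterations)
            except ValueError:
                continue
        selection = hmm.select_model(candidates, inner_val)
    bundle = _fit_chmm_bundle(by_class, *selection, seed,
                              config.hmm_iterations)
    bundle.selection = {"n_states": selection[0],
                        "n_components": selection[1]}
    return bundle


def _fit_chmm_bundle(by_class, n_states, n_comp, seed,
                     n_iter=hmm.BAUM_WELCH_ITER) -> hmm.RecognizerBundle:
    models = {cls: hmm.train_class_hmm([fs.values for fs in seqs], n_states,
                                       n_comp, seed=seed, label=cls,
                                       n_iter=n_iter)
              for cls, seqs in by_class.items()}
    return hmm.RecognizerBundle(mode="class_specific", models=models)


def _train_uhmm(by_class: dict[str, list[FeatureSequence]],
                config: ExperimentConfig, seed: int) -> hmm.RecognizerBundle:
    grids = [(s, m) for s in config.universal_state_grid
             for m in config.universal_component_grid]
    selection = grids[0]
    if len(grids) > 1:
        inner_train, inner_val = _inner_split(by_class, seed)
        candidates = {}
        for s, m in grids:
            try:
                candidates[(s, m)] = _fit_uhmm_bundle(inner_train, s, m,
                                                      config, seed)
            except ValueError:
                continue
        selection = hmm.select_model(candidates, inner_val)
    bundle = _fit_uhmm_bundle(by_class, *selection, config, seed)
    bundle.selection = {"n_states": selection[0],
                        "total_components": selection[1]}
    return bundle


def _fit_uhmm_bundle(by_class, n_states, total_comp, config,
                     seed) -> hmm.RecognizerBundle:
    pooled = [fs.values for seqs in by_class.values() for fs in seqs]
    background = hmm.train_universal_hmm(pooled, n_states, total_comp, seed,
                                         n_iter=config.hmm_iterations)
    models = {cls: hmm.adapt_universal(background,
                                       [fs.values for fs in seqs],
                                       config.relevance, label=cls)
              for cls, seqs in by_class.items()}
    return hmm.RecognizerBundle(mode="universal_adapted", models=models,
                                background=background)


def _inner_split(by_class, seed, val_fraction=0.25):
    """Stratified inner split for model selection inside the training folds."""
    rng = np.random.default_rng(seed)
    inner_train, inner_val = {}, []
    for cls, seqs in by_class.items():
        order = rng.permutation(len(seqs))
        n_val = max(1, int(round(val_fraction * len(seqs)))) \
            if len(seqs) > 2 else 0
        inner_val.extend(seqs[i] for i in order[:n_val])
        inner_train[cls] = [seqs[i] for i in order[n_val:]]
    return inner_train, inner_val


def run_experiment(config: ExperimentConfig,
                   corpus: list[AudioClip] | list[FeatureSequence],
                   ) -> EvaluationReport:
    """Run the full cross-validated evaluation on a corpus.

    ``corpus`` may hold audio clips (features are extracted once up front)
    or precomputed raw feature sequences. Each repetition re-randomizes the
    fold assignment and every training seed.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if isinstance(corpus[0], AudioClip):
        raw = [extract_features(c, config.feature_set) for c in corpus]
    else:
        raw = list(corpus)
    labels = [fs.label for fs in raw]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    conf_counts = {s: np.zeros((len(classes), len(classes)))
                   for s in config.systems}
    per_rep: dict[str, list[float]] = {s: [] for s in config.systems}
    pred_rows, pairing_records = [], []
    leakage_checks = 0

    for rep in range(config.repetitions):
        rep_seed = (config.seed * 1_000_003 + 97 * rep) % (2 ** 31)
        assign = stratified_folds(labels, config.folds, rep_seed)
        rep_counts = {s: np.zeros_like(conf_counts[s])
                      for s in config.systems}
        for fold in range(config.folds):
            fold_seed = (rep_seed + 31 * fold + 1) % (2 ** 31)
            train_raw = [raw[i] for i in range(len(raw)) if assign[i] != fold]
            test_raw = [raw[i] for i in range(len(raw)) if assign[i] == fold]
            if not test_raw:
                continue
            if config.normalize:
                norm = FeatureNormalizer.fit(train_raw)
                train = [norm.apply(fs) for fs in train_raw]
                test = [norm.apply(fs) for fs in test_raw]
            else:
                train, test = list(train_raw), list(test_raw)

            needs_tl = any(s.endswith("_tl") for s in config.systems)
            if needs_tl:
                augmented, records = augment_training_set(train, config,
                                                          fold_seed)
                if rep == 0 and fold == 0:
                    pairing_records = records
            else:
                augmented = train

            audit_no_leakage(train, test)
            audit_no_leakage(augmented, test)
            leakage_checks += 2

            bundles = {}
            for system in config.systems:
                pool = augmented if system.endswith("_tl") else train
                by_class: dict[str, list[FeatureSequence]] = {}
                for fs in pool:
                    by_class.setdefault(fs.label, []).append(fs)
                trainer = _train_chmm if system.startswith("c") else _train_uhmm
                bundles[system] = trainer(by_class, config, fold_seed)

            for fs in test:
                for system, bundle in bundles.items():
                    pred, scores = hmm.classify(bundle, fs.values)
                    i, j = classes.index(fs.label), classes.index(pred)
                    rep_counts[system][i, j] += 1
                    pred_rows.append({"repetition": rep, "fold": fold,
                                      "system": system, "clip_id": fs.clip_id,
                                      "true": fs.label, "predicted": pred,
                                      **{f"score_{c}": scores[c]
                                         for c in classes}})
        for system in config.systems:
            conf_counts[system] += rep_counts[system]
            per_rep[system].append(_average_rate(rep_counts[system]))

    confusion, rates, recalls = {}, {}, {}
    for system in config.systems:
        cm = _row_normalize(conf_counts[system])
        confusion[system] = pd.DataFrame(cm, index=classes, columns=classes)
        recalls[system] = pd.Series(np.diag(cm), index=classes)
        rates[system] = float(np.mean(per_rep[system]))

    return EvaluationReport(
        classes=classes, confusion=confusion, average_rate=rates,
        per_repetition=per_rep, per_class_recall=recalls,
        pairings=pairing_records,
        predictions=pd.DataFrame(pred_rows), config=config.to_dict(),
        config_hash=config.config_hash, leakage_checks=leakage_checks)


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    rows = counts.sum(axis=1, keepdims=True)
    return 100.0 * counts / np.maximum(rows, 1e-12)


def _average_rate(counts: np.ndarray) -> float:
    """Unweighted mean of per-class recalls, in percent."""
    rows = counts.sum(axis=1)
    ok = rows > 0
    recalls = np.diag(counts)[ok] / rows[ok]
    return float(100.0 * recalls.mean())


def write_report(rep: EvaluationReport, out_dir: str | os.PathLike,
                 fmt: str = "csv") -> None:
    """Emit confusion matrices, rates, pairings, predictions and config."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    lines = []
    for system, cm in rep.confusion.items():
        cm.round(2).to_csv(os.path.join(out, f"confusion_{system}.csv"))
        lines.append(f"== {system}: average recognition rate "
                     f"{rep.average_rate[system]:.1f}% ==")
        lines.append(cm.round(1).to_string())
        lines.append("")
    with open(os.path.join(out, "confusion.txt"), "w") as fh:
        fh.write("\n".join(lines))
    summary = {"average_rate_percent": rep.average_rate,
               "per_repetition_percent": rep.per_repetition,
               "per_class_recall_percent": {
                   s: r.round(3).to_dict()
                   for s, r in rep.per_class_recall.items()},
               "pairings": rep.pairings, "config": rep.config,
               "config_hash": rep.config_hash,
               "leakage_checks": rep.leakage_checks}
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    rep.predictions.to_csv(os.path.join(out, "predictions.csv"), index=False)
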