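"""Feed-forward classifier surrogate for voxelwise perfusion estimation.

Instead of deconvolving each voxel by iterative least squares, a small
fully connected network maps the raw 80-element input — 40 tissue-curve
samples concatenated with the study's 40 AIF samples — to a softmax
over 40 discretized perfusion values (10, 20, …, 400 ml·min⁻¹·100g⁻¹);
the estimate is the grid value of the most probable class.  Training
labels come from kinetic model fitting (multigrid by default), so the
network learns to *emulate the fit*, trading the quantization floor of
the 10-unit grid for near-instantaneous inference.

Architecture and training follow a deliberately plain recipe: seven
hidden layers of 70 ReLU units, Adam, cross-entropy on integer class
labels, 20 epochs, learning rate 0.001, batch size 32, no input
normalization by default.

Training runs through scikit-learn's multilayer perceptron; the fitted
weights are extracted immediately, and all inference is a plain numpy
forward pass, so serialized models need no training framework.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .kinetics import Curve

__all__ = [
    "PerfusionClassGrid",
    "TrainingSet",
    "PerfusionNetwork",
    "build_feature_vector",
    "discretize_perfusion",
    "class_to_perfusion",
    "assemble_training_set",
    "train_network",
    "predict_voxel",
    "predict_map",
    "save_model",
    "load_model",
]

N_CLASSES = 40
N_FEATURES = 80


@dataclass(frozen=True)
class PerfusionClassGrid:
    """The 40 discretized perfusion levels and the label<->value mapping.

    Default: linearly spaced 10 to 400 ml·min⁻¹·100g⁻¹ (step 10).
    """

    values: np.ndarray = field(
        default_factory=lambda: np.linspace(10.0, 400.0, N_CLASSES)
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_CLASSES,):
            raise ValueError(f"grid must have exactly {N_CLASSES} values")
        if np.any(np.diff(v) <= 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.values)))


DEFAULT_GRID = PerfusionClassGrid()


def discretize_perfusion(f, grid: PerfusionClassGrid = DEFAULT_GRID):
    """Nearest-grid class index for perfusion ``f``; ties round up.

    Values below the lowest grid level map to class 0, above the highest
    to class 39 (out-of-range references are clipped, they stay
    representable at the end classes).
    """
    f_arr = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f_arr)):
        raise ValueError("perfusion must be finite")
    mids = (grid.values[:-1] + grid.values[1:]) / 2.0
    idx = np.searchsorted(mids, f_arr, side="right")
    return int(idx) if f_arr.ndim == 0 else idx.astype(np.int64)


def class_to_perfusion(index, grid: PerfusionClassGrid = DEFAULT_GRID):
    """Grid perfusion value for class ``index`` (inverse of discretization)."""
    idx = np.asarray(index)
    if np.any((idx < 0) | (idx >= N_CLASSES)):
        raise ValueError(f"class index must be in [0, {N_CLASSES - 1}]")
    out = grid.values[idx]
    return float(out) if idx.ndim == 0 else out


def build_feature_vector(tc, aif) -> np.ndarray:
    """Concatenate 40 TC samples and 40 AIF samples into one input row.

    Elements 0-39 are the tissue curve in frame order, 40-79 the AIF;
    no normalization is applied.
    """
    tc_v = tc.values if isinstance(tc, Curve) else np.asarray(tc, dtype=float)
    aif_v = aif.values if isinstance(aif, Curve) else np.asarray(aif, dtype=float)
    if tc_v.shape != (40,) or aif_v.shape != (40,):
        raise ValueError("both curves must have exactly 40 frames")
    return np.concatenate([tc_v, aif_v])


def build_feature_matrix(tc_matrix: np.ndarray, aif: Curve) -> np.ndarray:
    """Feature rows for many voxels sharing one AIF."""
    tc_matrix = np.atleast_2d(np.asarray(tc_matrix, dtype=float))
    if tc_matrix.shape[1] != 40:
        raise ValueError("tissue curves must have exactly 40 frames")
    aif_block = np.tile(np.asarray(aif.values, dtype=float), (tc_matrix.shape[0], 1))
    return np.hstack([tc_matrix, aif_block])


@dataclass
class TrainingSet:
    """Per-voxel features and class labels assembled from fitted studies."""

    features: np.ndarray          # (n, 80)
    labels: np.ndarray            # (n,) int in [0, 39]
    provenance: list
    label_source: str = "multigrid"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (n, {N_FEATURES})")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("features and labels must have the same length")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError(f"labels must lie in [0, {N_CLASSES - 1}]")

    def __len__(self) -> int:
        return self.features.shape[0]

    @staticmethod
    def concatenate(sets: list["TrainingSet"]) -> "TrainingSet":
        """Merge cohorts (the combined-cohort training strategy)."""
        if not sets:
            raise ValueError("nothing to concatenate")
        src = {s.label_source for s in sets}
        if len(src) > 1:
            raise ValueError(f"mixed label sources: {sorted(src)}")
        return TrainingSet(
            features=np.vstack([s.features for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            provenance=[p for s in sets for p in s.provenance],
            label_source=sets[0].label_source,
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            features=self.features,
            labels=self.labels,
            provenance=json.dumps(self.provenance),
            label_source=self.label_source,
        )

    @classmethod
    def load(cls, path) -> "TrainingSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                features=z["features"],
                labels=z["labels"],
                provenance=json.loads(str(z["provenance"])),
                label_source=str(z["label_source"]),
            )


def assemble_training_set(studies, label_maps, aifs=None, label_source: str = "multigrid",
                          grid: PerfusionClassGrid = DEFAULT_GRID,
                          exclude_nonconverged: bool = False,
                          converged_maps=None) -> TrainingSet:
    """One training record per masked voxel of each fitted study.

    Parameters
    ----------
    studies : list of SimulatedStudy (or any object with ``masked_tc``,
        ``mask``, ``aif``, ``cohort``, ``study_id``)
    label_maps : list of (H, W) perfusion maps giving the reference F per
        voxel (typically the multigrid fit of each study).
    label_source : 'multigrid' or 'regular' — provenance tag only; the
        caller chooses which maps to pass.
    exclude_nonconverged : drop voxels whose fit did not converge
        (requires ``converged_maps``); off by default.
    """
    if len(label_maps) != len(studies):
        raise ValueError("need one label map per study")
    feats, labels, prov = [], [], []
    for i, (study, fmap) in enumerate(zip(studies, label_maps)):
        fmap = np.asarray(fmap, dtype=float)
        if fmap.shape != study.mask.shape:
            raise ValueError("label map shape does not match the study mask")
        ref = fmap[study.mask]
        if np.any(~np.isfinite(ref)):
            raise ValueError("label map has non-finite values inside the mask")
        keep = np.ones(ref.size, dtype=bool)
        if exclude_nonconverged:
            if converged_maps is None:
                raise ValueError("exclude_nonconverged requires converged_maps")
            keep = np.asarray(converged_maps[i])[study.mask].astype(bool)
        feats.append(build_feature_matrix(study.masked_tc[keep], study.aif))
        labels.append(discretize_perfusion(ref[keep], grid))
        prov.append({
            "cohort": study.cohort,
            "study_id": int(study.study_id),
            "n_voxels": int(keep.sum()),
        })
    return TrainingSet(
        features=np.vstack(feats),
        labels=np.concatenate(labels),
        provenance=prov,
        label_source=label_source,
    )


class PerfusionNetwork(ClassifierMixin, BaseEstimator):
    """Scikit-learn classifier: (TC, AIF) features -> discretized perfusion.

    Parameters mirror the plain training recipe; all have the defaults
    described in the module docstring.  ``standardize=True`` enables
    optional per-feature standardization (off by default: inputs are raw
    concatenated curves).

    Attributes (after :meth:`fit`)
    ------------------------------
    coefs_, intercepts_ : list of ndarray
        Layer weights; inference is a numpy forward pass over these.
    classes_ : ndarray (40,)
        All grid class indices 0..39.
    loss_curve_ : list of float
        Per-epoch training loss.
    """

    def __init__(self, n_hidden_layers: int = 7, nodes_per_layer: int = 70,
                 n_epochs: int = 20, learning_rate: float = 0.001,
                 batch_size: int = 32, random_state: int | None = None,
                 standardize: bool = False, grid: PerfusionClassGrid | None = None):
        self.n_hidden_layers = n_hidden_layers
        self.nodes_per_layer = nodes_per_layer
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state
        self.standardize = standardize
        self.grid = grid

    def fit(self, X, y):
        """Train for exactly ``n_epochs`` passes of Adam on cross-entropy."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"X must be (n, {N_FEATURES})")
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        if y.shape != (X.shape[0],):
            raise ValueError("y must be one class label per row of X")
        y = y.astype(np.int64)
        if y.min() < 0 or y.max() >= N_CLASSES:
            raise ValueError(f"labels must lie in [0, {N_CLASSES - 1}]")

        if self.standardize:
            self.feature_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.feature_scale_ = np.where(sd > 0, sd, 1.0)
            X = (X - self.feature_mean_) / self.feature_scale_
        else:
            self.feature_mean_ = None
            self.feature_scale_ = None

        mlp = MLPClassifier(
            hidden_layer_sizes=(self.nodes_per_layer,) * self.n_hidden_layers,
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=self.batch_size,
            max_iter=self.n_epochs,
            n_iter_no_change=self.n_epochs,  # no early stopping: fixed epochs
            shuffle=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            # stopping at the fixed epoch budget is intended
            warnings.simplefilter("ignore", ConvergenceWarning)
            mlp.fit(X, y)

        self.coefs_ = [w.copy() for w in mlp.coefs_]
        self.intercepts_ = [b.copy() for b in mlp.intercepts_]
        self.trained_classes_ = mlp.classes_.astype(np.int64)
        self.classes_ = np.arange(N_CLASSES)
        self.loss_curve_ = list(mlp.loss_curve_)
        self.grid_ = self.grid or DEFAULT_GRID
        self.n_features_in_ = N_FEATURES
        return self

    # -- inference: numpy forward pass, framework-free -----------------------

    def _forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        logits = a @ self.coefs_[-1] + self.intercepts_[-1]
        if logits.shape[1] == 1:  # degenerate single-class training set
            return np.ones((X.shape[0], 1))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities over the full 40-class grid.

        Classes absent from the training labels receive probability
        exactly 0 (the network has no output unit for them).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"X must have {N_FEATURES} features")
        if self.standardize:
            X = (X - self.feature_mean_) / self.feature_scale_
        p = self._forward(X)
        out = np.zeros((X.shape[0], N_CLASSES))
        out[:, self.trained_classes_] = p
        return out

    def predict(self, X) -> np.ndarray:
        """Most probable class index per row (ties break to lower index)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def predict_perfusion(self, X) -> np.ndarray:
        """Perfusion estimate: grid value of the argmax class."""
        return self.grid_.values[self.predict(X)]


def train_network(train: TrainingSet, config: PerfusionNetwork | dict | None = None,
                  random_state: int | None = None) -> PerfusionNetwork:
    """Train a :class:`PerfusionNetwork` on a :class:`TrainingSet`."""
    if isinstance(config, PerfusionNetwork):
        net = config
    else:
        net = PerfusionNetwork(**(config or {}), random_state=random_state)
    return net.fit(train.features, train.labels)


def predict_voxel(model: PerfusionNetwork, feature) -> tuple[np.ndarray, float]:
    """(40 class probabilities, perfusion estimate) for one feature vector."""
    feature = np.asarray(feature, dtype=float)
    if feature.shape != (N_FEATURES,):
        raise ValueError(f"feature vector must have {N_FEATURES} elements")
    proba = model.predict_proba(feature[None, :])[0]
    return proba, float(model.grid_.values[int(np.argmax(proba))])


def predict_map(model: PerfusionNetwork, dynamic_series: np.ndarray,
                mask: np.ndarray, aif: Curve) -> np.ndarray:
    """Grid-valued perfusion map by batched inference; NaN outside the mask."""
    series = np.asarray(dynamic_series, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if series.ndim != 3 or mask.shape != series.shape[:2]:
        raise ValueError("dynamic_series must be (H, W, T) with a matching mask")
    out = np.full(mask.shape, np.nan)
    if mask.any():
        X = build_feature_matrix(series[mask], aif)
        out[mask] = model.predict_perfusion(X)
    return out


# -- model serialization ------------------------------------------------------


def save_model(model: PerfusionNetwork, path) -> None:
    """Single-file model: weights as arrays plus a JSON header."""
    header = {
        "format": "muscleperf-perfusion-network",
        "version": 1,
        "grid_values": model.grid_.values.tolist(),
        "trained_classes": model.trained_classes_.tolist(),
        "params": model.get_params(deep=False) | {"grid": None},
        "loss_curve": model.loss_curve_,
        "standardize": bool(model.standardize),
    }
    arrays = {"header": json.dumps(header)}
    for i, (W, b) in enumerate(zip(model.coefs_, model.intercepts_)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if model.standardize:
        arrays["feature_mean"] = model.feature_mean_
        arrays["feature_scale"] = model.feature_scale_
    np.savez_compressed(path, **arrays)


def load_model(path) -> PerfusionNetwork:
    """Rebuild a trained network for inference from :func:`save_model` output."""
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header.get("format") != "muscleperf-perfusion-network":
            raise ValueError(f"{path} is not a perfusion-network model file")
        params = header["params"]
        net = PerfusionNetwork(**params)
        n_layers = params["n_hidden_layers"] + 1
        net.coefs_ = [z[f"W{i}"] for i in range(n_layers)]
        net.intercepts_ = [z[f"b{i}"] for i in range(n_layers)]
        net.trained_classes_ = np.asarray(header["trained_classes"], dtype=np.int64)
        net.classes_ = np.arange(N_CLASSES)
        net.loss_curve_ = list(header["loss_curve"])
        net.grid_ = PerfusionClassGrid(values=np.asarray(header["grid_values"]))
        net.n_features_in_ = N_FEATURES
        if header["standardize"]:
            net.feature_mean_ = z["feature_mean"]
            net.feature_scale_ = z["feature_scale"]
        else:
            net.feature_mean_ = None
            net.feature_scale_ = None
    return net
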