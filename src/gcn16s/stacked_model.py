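"""The stacked-ensemble 16S copy-number regressor.

Two base learners read the 6-mer count vector of a sequence: a multi-layer
perceptron trained on the raw counts with an RMSE loss, and an RBF-kernel
support vector regressor on the top-100 PCA scores of the counts. A ridge
meta-learner then aggregates [mlp_prediction, svr_prediction, 100 PCA scores]
into the final copies/genome estimate. Defaults reproduce the published
architecture: hidden layers 489-926-645-929-582-82 with activations
GELU/ReLU/ReLU/ELU/GELU/Linear plus a linear output unit, SVR C=11 with
gamma='auto', ridge alpha=49.

The MLP is implemented directly in numpy (per-layer activation schedules are
part of the model), with an Adam optimizer and early stopping on a held-out
validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import erf
from sklearn.decomposition import PCA
from sklearn.svm import SVR

from .kmer_features import KmerVocabulary, build_vocabulary, count_matrix
from .sequence_prep import SeqRecord

# ---------------------------------------------------------------------------
# activations

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _gelu(x: np.ndarray) -> np.ndarray:
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "elu": (
        lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))),
        lambda x: np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0))),
    ),
    "gelu": (_gelu, _gelu_grad),
    "selu": (
        lambda x: _SELU_LAMBDA
        * np.where(x > 0, x, _SELU_ALPHA * np.expm1(np.minimum(x, 0.0))),
        lambda x: _SELU_LAMBDA
        * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0))),
    ),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


def activation(name: str, x) -> np.ndarray:
    """Apply a named activation elementwise (relu, elu, gelu, selu, linear)."""
    try:
        fn = _ACTIVATIONS[name.lower()][0]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None
    return fn(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# MLP

DEFAULT_LAYER_SIZES = (489, 926, 645, 929, 582, 82)
DEFAULT_ACTIVATIONS = ("gelu", "relu", "relu", "elu", "gelu", "linear")


@dataclass
class MLPSpec:
    """Hidden-layer architecture plus (once trained) weights and biases.

    A single linear output unit is appended after the last hidden layer.
    """

    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    activations: tuple[str, ...] = DEFAULT_ACTIVATIONS
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != len(self.activations):
            raise ValueError("one activation per hidden layer required")
        for a in self.activations:
            if a.lower() not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")


def _init_mlp(spec: MLPSpec, n_features: int, rng: np.random.Generator) -> MLPSpec:
    sizes = [n_features, *spec.layer_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)  # He init suits the ReLU-family schedule
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPSpec(spec.layer_sizes, spec.activations, weights, biases)


def mlp_forward(x: np.ndarray, spec: MLPSpec) -> np.ndarray:
    """Forward pass; accepts one vector or a (n, d) batch, returns (n,) or scalar."""
    if not spec.weights:
        raise ValueError("MLP has no trained weights")
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != spec.weights[0].shape[0]:
        raise ValueError(
            f"input dimension {X.shape[1]} != expected {spec.weights[0].shape[0]}"
        )
    h = X
    acts = [*spec.activations, "linear"]
    for W, b, name in zip(spec.weights, spec.biases, acts):
        h = _ACTIVATIONS[name.lower()][0](h @ W + b)
    out = h[:, 0]
    return out if np.ndim(x) == 2 else float(out[0])


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    spec: MLPSpec,
    learning_rate: float = 1e-3,
    epochs: int = 200,
    batch_size: int = 32,
    seed: int = 0,
    validation_fraction: float = 0.1,
    patience: int = 20,
) -> tuple[MLPSpec, list[float]]:
    """Train the MLP by Adam on the RMSE loss; returns (spec, loss trace).

    A validation split (``validation_fraction`` of the data) drives early
    stopping: training halts after ``patience`` epochs without improvement
    and the best weights are restored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 training samples")
    rng = np.random.Generator(np.random.PCG64(seed))
    model = _init_mlp(spec, X.shape[1], rng)
    model.biases[-1][:] = y.mean()  # start the output head at the label mean

    n_val = int(round(validation_fraction * len(X)))
    perm = rng.permutation(len(X))
    val_idx, trn_idx = perm[:n_val], perm[n_val:]
    Xt, yt = X[trn_idx], y[trn_idx]
    Xv, yv = X[val_idx], y[val_idx]

    params = [*model.weights, *model.biases]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    acts = [*model.activations, "linear"]
    trace: list[float] = []
    best_val = np.inf
    best_params = [p.copy() for p in params]
    stale = 0

    for epoch in range(epochs):
        order = rng.permutation(len(Xt))
        epoch_losses = []
        for start in range(0, len(Xt), batch_size):
            idx = order[start : start + batch_size]
            xb, yb = Xt[idx], yt[idx]
            # forward, caching pre-activations
            h = xb
            pre, post = [], [h]
            for W, b, name in zip(model.weights, model.biases, acts):
                z = h @ W + b
                h = _ACTIVATIONS[name.lower()][0](z)
                pre.append(z)
                post.append(h)
            pred = h[:, 0]
            resid = pred - yb
            rmse = float(np.sqrt(np.mean(resid**2)))
            epoch_losses.append(rmse)
            if not np.isfinite(rmse):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning rate"
                )
            if rmse == 0.0:
                continue
            # backward: dL/dpred for L = sqrt(mean(r^2))
            delta = (resid / (len(yb) * rmse))[:, None]
            grads_w, grads_b = [], []
            for li in range(len(model.weights) - 1, -1, -1):
                dz = delta * _ACTIVATIONS[acts[li].lower()][1](pre[li])
                grads_w.append(post[li].T @ dz)
                grads_b.append(dz.sum(axis=0))
                if li > 0:
                    delta = dz @ model.weights[li].T
            grads = [*reversed(grads_w), *reversed(grads_b)]
            t += 1
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= b1
                mi += (1 - b1) * g
                vi *= b2
                vi += (1 - b2) * g * g
                mhat = mi / (1 - b1**t)
                vhat = vi / (1 - b2**t)
                p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        trace.append(float(np.mean(epoch_losses)))
        if len(Xv):
            val_pred = mlp_forward(Xv, model) if Xv.ndim == 2 else None
            val_rmse = float(np.sqrt(np.mean((np.asarray(val_pred) - yv) ** 2)))
            if val_rmse < best_val - 1e-6:
                best_val = val_rmse
                best_params = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if len(Xv):
        n_w = len(model.weights)
        model.weights = best_params[:n_w]
        model.biases = best_params[n_w:]
    return model, trace


# ---------------------------------------------------------------------------
# PCA + SVR + ridge

def fit_pca(X: np.ndarray, n_components: int = 100) -> PCA:
    X = np.asarray(X, dtype=float)
    n_max = min(X.shape)
    if n_components > n_max:
        raise ValueError(f"n_components={n_components} > min(n_samples, n_features)={n_max}")
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    pca.fit(X)
    return pca


def train_svr(
    Z: np.ndarray, y: np.ndarray, C: float = 11.0, gamma="auto",
    kernel: str = "rbf", epsilon: float = 0.1,
) -> SVR:
    if len(Z) < 2:
        raise ValueError("need at least 2 training samples")
    svr = SVR(kernel=kernel, C=C, gamma=gamma, epsilon=epsilon)
    svr.fit(np.asarray(Z, dtype=float), np.asarray(y, dtype=float))
    return svr


def train_meta(
    mlp_preds: np.ndarray,
    svr_preds: np.ndarray,
    pca_scores: np.ndarray,
    y: np.ndarray,
    alpha: float = 49.0,
) -> tuple[np.ndarray, float]:
    """Closed-form ridge on the stacked design [mlp, svr, scores].

    beta = (F'F + alpha*I)^-1 F'y after centering, leaving the intercept
    unpenalized; returns (coefficients, intercept).
    """
    F = np.column_stack([mlp_preds, svr_preds, np.asarray(pca_scores, dtype=float)])
    y = np.asarray(y, dtype=float)
    f_mean = F.mean(axis=0)
    y_mean = y.mean()
    Fc = F - f_mean
    p = F.shape[1]
    beta = np.linalg.solve(Fc.T @ Fc + alpha * np.eye(p), Fc.T @ (y - y_mean))
    intercept = y_mean - f_mean @ beta
    return beta, float(intercept)


# ---------------------------------------------------------------------------
# the stacked ensemble

@dataclass
class SEMConfig:
    """Hyperparameters of the stacked ensemble.

    Defaults are the published values; the desk-scale preset
    (``SEMConfig.desk()``) shrinks the MLP and epoch budget for laptop-sized
    synthetic runs without changing the architecture's shape.
    """

    K: int = 6
    pca_components: int = 100
    svr_kernel: str = "rbf"
    svr_gamma: object = "auto"
    svr_c: float = 11.0
    svr_epsilon: float = 0.1
    ridge_alpha: float = 49.0
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    activations: tuple[str, ...] = DEFAULT_ACTIVATIONS
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    train_fraction: float = 0.75
    out_of_fold_stacking: bool = False
    clamp_min: float = 1.0

    @staticmethod
    def desk(seed: int = 0, **overrides) -> "SEMConfig":
        cfg = SEMConfig(
            layer_sizes=(128, 64),
            activations=("gelu", "relu"),
            epochs=80,
            seed=seed,
        )
        for k, val in overrides.items():
            setattr(cfg, k, val)
        return cfg


@dataclass
class SEMModel:
    vocabulary: KmerVocabulary
    pca: PCA
    mlp: MLPSpec
    svr: SVR
    ridge_coef: np.ndarray  # length 2 + pca_components
    ridge_intercept: float
    config: SEMConfig
    loss_trace: list[float] = field(default_factory=list)


def _records_to_counts(
    records: Sequence, vocabulary: KmerVocabulary, strict: bool = True
) -> tuple[np.ndarray, list[int]]:
    """Count matrix for records; returns (counts, indices that produced no
    k-mers). ``strict`` raises on such records instead."""
    seqs = [r.seq if isinstance(r, SeqRecord) else str(r) for r in records]
    ids = [r.id if isinstance(r, SeqRecord) else f"seq{i}" for i, r in enumerate(records)]
    table = count_matrix(seqs, ids, vocabulary)
    bad = [i for i in range(len(seqs)) if len(seqs[i]) < vocabulary.K]
    if bad and strict:
        raise ValueError(
            f"sequences shorter than K={vocabulary.K}: {[ids[i] for i in bad[:5]]}")
    return table.counts.astype(float), bad


def sem_train(records: Sequence, labels: Sequence[float], config: SEMConfig | None = None) -> SEMModel:
    """Fit vocabulary -> counts -> (MLP, PCA->SVR) -> ridge meta-learner."""
    cfg = config or SEMConfig()
    labels = np.asarray(labels, dtype=float)
    if len(records) != len(labels):
        raise ValueError("records and labels must align")
    if np.any(labels < 1):
        raise ValueError("copy-number labels must be >= 1")
    seqs = [r.seq if isinstance(r, SeqRecord) else str(r) for r in records]
    vocab = build_vocabulary(seqs, cfg.K)
    X, _ = _records_to_counts(records, vocab)

    n_comp = min(cfg.pca_components, min(X.shape) - 1)
    pca = fit_pca(X, n_comp)
    Z = pca.transform(X)

    mlp_spec = MLPSpec(cfg.layer_sizes, cfg.activations)
    mlp, trace = train_mlp(
        X, labels, mlp_spec,
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, seed=cfg.seed,
    )
    svr = train_svr(Z, labels, C=cfg.svr_c, gamma=cfg.svr_gamma,
                    kernel=cfg.svr_kernel, epsilon=cfg.svr_epsilon)

    if cfg.out_of_fold_stacking:
        mlp_base, svr_base = _out_of_fold_base_outputs(X, Z, labels, cfg)
    else:
        mlp_base = np.asarray(mlp_forward(X, mlp))
        svr_base = svr.predict(Z)
    beta, intercept = train_meta(mlp_base, svr_base, Z, labels, alpha=cfg.ridge_alpha)
    return SEMModel(vocab, pca, mlp, svr, beta, intercept, cfg, trace)


def _out_of_fold_base_outputs(X, Z, y, cfg: SEMConfig, folds: int = 5):
    """Out-of-fold base-model outputs for leakage-free stacking."""
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    assign = rng.permutation(len(y)) % folds
    mlp_oof = np.zeros(len(y))
    svr_oof = np.zeros(len(y))
    for f in range(folds):
        trn, tst = assign != f, assign == f
        mlp, _ = train_mlp(X[trn], y[trn], MLPSpec(cfg.layer_sizes, cfg.activations),
                           learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                           batch_size=cfg.batch_size, seed=cfg.seed + f)
        mlp_oof[tst] = np.asarray(mlp_forward(X[tst], mlp))
        svr = train_svr(Z[trn], y[trn], C=cfg.svr_c, gamma=cfg.svr_gamma,
                        kernel=cfg.svr_kernel, epsilon=cfg.svr_epsilon)
        svr_oof[tst] = svr.predict(Z[tst])
    return mlp_oof, svr_oof


def _base_outputs(model: SEMModel, records: Sequence, strict: bool = True):
    X, bad = _records_to_counts(records, model.vocabulary, strict=strict)
    Z = model.pca.transform(X)
    mlp_pred = np.asarray(mlp_forward(X, model.mlp))
    svr_pred = model.svr.predict(Z)
    return mlp_pred, svr_pred, Z, bad


def sem_predict(model: SEMModel, records: Sequence, clamp: bool = True) -> np.ndarray:
    """Predict copies/genome; real-valued, clamped to >= 1 (a detected genome
    carries at least one 16S copy), never rounded.

    A record too short to yield any k-mer gets NaN (with a warning) rather
    than failing the whole batch.
    """
    import warnings

    mlp_pred, svr_pred, Z, bad = _base_outputs(model, records, strict=False)
    F = np.column_stack([mlp_pred, svr_pred, Z])
    final = F @ model.ridge_coef + model.ridge_intercept
    if clamp:
        final = np.maximum(final, model.config.clamp_min)
    if bad:
        warnings.warn(f"{len(bad)} record(s) shorter than K={model.vocabulary.K}; "
                      "predictions set to NaN")
        final[bad] = np.nan
    return final


def contribution_fractions(model: SEMModel, record) -> dict[str, float]:
    """Share of the (pre-clamp) output owed to each feature extractor.

    mlp% + svr% + pca% + intercept% = 1 exactly.
    """
    mlp_pred, svr_pred, Z, _ = _base_outputs(model, [record])
    beta = model.ridge_coef
    final = float(mlp_pred[0] * beta[0] + svr_pred[0] * beta[1]
                  + Z[0] @ beta[2:] + model.ridge_intercept)
    if final == 0.0:
        raise ZeroDivisionError("final prediction is zero; fractions undefined")
    return {
        "mlp": float(beta[0] * mlp_pred[0] / final),
        "svr": float(beta[1] * svr_pred[0] / final),
        "pca": float(Z[0] @ beta[2:] / final),
        "intercept": float(model.ridge_intercept / final),
    }


# ---------------------------------------------------------------------------
# persistence

def save_model(model: SEMModel, path) -> None:
    """Persist a trained model: JSON manifest + array archive in a directory."""
    import joblib

    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(model.config).items()},
        "vocabulary_size": len(model.vocabulary),
        "K": model.vocabulary.K,
        "layer_sizes": list(model.mlp.layer_sizes),
        "activations": list(model.mlp.activations),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(d / "vocabulary.txt", "w") as fh:
        fh.write(f"#K={model.vocabulary.K}\n")
        fh.writelines(k + "\n" for k in model.vocabulary.kmers)
    joblib.dump(
        {"pca": model.pca, "svr": model.svr,
         "mlp_weights": model.mlp.weights, "mlp_biases": model.mlp.biases,
         "ridge_coef": model.ridge_coef, "ridge_intercept": model.ridge_intercept},
        d / "arrays.joblib",
    )


def load_model(path) -> SEMModel:
    import joblib

    d = Path(path)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg_raw = manifest["config"]
    cfg = SEMConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in cfg_raw.items()})
    from .kmer_features import load_vocabulary

    vocab = load_vocabulary(d / "vocabulary.txt")
    blobs = joblib.load(d / "arrays.joblib")
    mlp = MLPSpec(tuple(manifest["layer_sizes"]), tuple(manifest["activations"]),
                  blobs["mlp_weights"], blobs["mlp_biases"])
    return SEMModel(vocab, blobs["pca"], mlp, blobs["svr"],
                    blobs["ridge_coef"], blobs["ridge_intercept"], cfg)


# ---------------------------------------------------------------------------
# evaluation

def evaluate_rmse(predictions, truth) -> float:
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return float(np.sqrt(np.mean((predictions - truth) ** 2)))


def crossvalidate(
    records: Sequence,
    labels: Sequence[float],
    folds: int = 5,
    config: SEMConfig | None = None,
    seed: int = 0,
) -> dict:
    """K-fold CV with label-quantile stratification; returns per-fold RMSE."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.asarray(labels, dtype=float)
    n = len(labels)
    if n < 2 * folds:
        raise ValueError("too few samples for the requested fold count")
    rng = np.random.Generator(np.random.PCG64(seed))
    # stratify: sort by label, deal consecutive quantile blocks across folds
    order = np.argsort(labels, kind="stable")
    assign = np.empty(n, dtype=int)
    for block_start in range(0, n, folds):
        block = order[block_start : block_start + folds]
        assign[block] = rng.permutation(folds)[: len(block)]
    fold_rmse = []
    for f in range(folds):
        tst = np.where(assign == f)[0]
        trn = np.where(assign != f)[0]
        model = sem_train([records[i] for i in trn], labels[trn], config)
        preds = sem_predict(model, [records[i] for i in tst])
        fold_rmse.append(evaluate_rmse(preds, labels[tst]))
    return {
        "per_fold_rmse": fold_rmse,
        "mean_rmse": float(np.mean(fold_rmse)),
        "sd_rmse": float(np.std(fold_rmse, ddof=1)),
    }
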