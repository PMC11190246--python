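"""Model interpretation: Kernel SHAP on k-mer features, positional mapping,
per-locus mutation rates, and the ELU upper-bound fit of SHAP vs insertion
rate.

Each k-mer count is a player in a cooperative game whose payoff is the model
prediction; Shapley values split the prediction minus a background baseline
among the k-mers (local accuracy). Attributions are mapped back onto aligned
reference coordinates to ask which loci of the gene the model relies on, and
compared with per-position substitution/deletion/insertion rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, factorial
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .kmer_features import count_vector
from .stacked_model import SEMModel, mlp_forward


@dataclass
class AttributionRecord:
    """SHAP values for one prediction: phi_0 + sum(phi) = f(x)."""

    id: str
    feature_indices: np.ndarray  # columns attributed (the active features)
    phi: np.ndarray  # one value per active feature, copies/genome units
    phi0: float  # expected prediction over the background
    prediction: float


@dataclass
class EluFit:
    """Fitted ŷ = a * ELU(b * (x - x0)) + c (ELU alpha = 1)."""

    a: float
    b: float
    x0: float
    c: float
    r_squared: float
    learning_rate: float = 0.01
    iterations: int = 2000

    def predict(self, x) -> np.ndarray:
        u = self.b * (np.asarray(x, dtype=float) - self.x0)
        return self.a * np.where(u > 0, u, np.expm1(np.minimum(u, 0.0))) + self.c


# ---------------------------------------------------------------------------
# Kernel SHAP

def _coalition_value(predict_fn, x, background, active, mask_matrix):
    """v(S) for each coalition row: active\\S replaced by background values,
    averaged over background rows."""
    n_coal = mask_matrix.shape[0]
    n_bg = background.shape[0]
    X = np.repeat(background, n_coal, axis=0)  # (n_bg*n_coal, d) blocks by bg row
    inactive = np.setdiff1d(np.arange(x.size), active)
    X[:, inactive] = x[inactive]
    tiled_mask = np.tile(mask_matrix, (n_bg, 1)).astype(bool)
    for j, f in enumerate(active):
        col = X[:, f]
        col[tiled_mask[:, j]] = x[f]
        X[:, f] = col
    preds = np.asarray(predict_fn(X), dtype=float)
    if not np.all(np.isfinite(preds)):
        raise FloatingPointError("predict_fn returned non-finite values")
    return preds.reshape(n_bg, n_coal).mean(axis=0)


def kernel_shap(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    active: Optional[Sequence[int]] = None,
    n_samples: int = 2048,
    exact_limit: int = 12,
    seed: int = 0,
    record_id: str = "",
) -> AttributionRecord:
    """Shapley attribution of ``predict_fn`` at ``x`` over ``active`` features.

    Masked-out features take background values (averaged over background
    rows); features outside ``active`` stay at their x values. With at most
    ``exact_limit`` active features all 2^M coalitions are enumerated and the
    exact Shapley formula applied; otherwise coalitions are sampled with the
    Shapley kernel weights and solved as a constrained weighted least squares.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background set is empty")
    if active is None:
        active = np.arange(x.size)
    active = np.asarray(sorted(active), dtype=int)
    M = len(active)
    fx = float(np.asarray(predict_fn(x[None, :]))[0])
    if M == 0:
        phi0 = float(_coalition_value(predict_fn, x, background, active,
                                      np.zeros((1, 0)))[0])
        return AttributionRecord(record_id, active, np.zeros(0), phi0, fx)

    if M <= exact_limit:
        masks = np.array(
            [[(c >> j) & 1 for j in range(M)] for c in range(2**M)], dtype=float
        )
        vals = _coalition_value(predict_fn, x, background, active, masks)
        v = {tuple(np.flatnonzero(m)): vals[i] for i, m in enumerate(masks)}
        phi = np.zeros(M)
        for i in range(M):
            others = [j for j in range(M) if j != i]
            for r in range(M):
                w = factorial(r) * factorial(M - r - 1) / factorial(M)
                for S in combinations(others, r):
                    phi[i] += w * (v[tuple(sorted((*S, i)))] - v[S])
        phi0 = v[()]
        return AttributionRecord(record_id, active, phi, float(phi0), fx)

    # sampling mode: kernel-weighted linear regression on coalitions
    rng = np.random.Generator(np.random.PCG64(seed))
    sizes = np.arange(1, M)
    size_weights = (M - 1) / (sizes * (M - sizes))
    size_p = size_weights / size_weights.sum()
    n_samples = max(n_samples, M + 2)
    masks = np.zeros((n_samples, M))
    for row in range(n_samples):
        s = rng.choice(sizes, p=size_p)
        masks[row, rng.choice(M, size=s, replace=False)] = 1.0
    empty = np.zeros((1, M))
    full = np.ones((1, M))
    vals = _coalition_value(
        predict_fn, x, background, active, np.vstack([empty, full, masks])
    )
    phi0, v_full = float(vals[0]), float(vals[1])
    y = vals[2:] - phi0
    # enforce efficiency: substitute phi_{M-1} = (v_full - phi0) - sum(others)
    total = v_full - phi0
    Z = masks[:, :-1] - masks[:, -1:]
    yy = y - masks[:, -1] * total
    W = np.ones(len(yy))  # per-size weight already matched by sampling frequency
    ZtWZ = Z.T @ (Z * W[:, None]) + 1e-10 * np.eye(M - 1)
    phi_head = np.linalg.solve(ZtWZ, Z.T @ (yy * W))
    phi = np.append(phi_head, total - phi_head.sum())
    return AttributionRecord(record_id, active, phi, phi0, fx)


def sample_and_attribute(
    model: SEMModel,
    records: Sequence,
    fraction: float = 0.10,
    seed: int = 0,
    background_size: int = 100,
    n_samples: int = 2048,
    exact_limit: int = 12,
) -> list[AttributionRecord]:
    """Attribute a seeded random subsample of records (default 10%).

    Each record is attributed over its own non-zero k-mer features against a
    background of seeded training count vectors; the attributed output is the
    pre-clamp ensemble prediction.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    n_pick = int(round(fraction * len(records)))
    picked = sorted(rng.choice(len(records), size=n_pick, replace=False))

    vocab = model.vocabulary
    counts = np.stack([count_vector(_seq(r), vocab)[0] for r in records]).astype(float)
    bg_idx = rng.choice(len(records), size=min(background_size, len(records)),
                        replace=False)
    background = counts[bg_idx]

    def predict_fn(X):
        Z = model.pca.transform(X)
        mlp_pred = np.asarray(mlp_forward(X, model.mlp))
        svr_pred = model.svr.predict(Z)
        F = np.column_stack([mlp_pred, svr_pred, Z])
        return F @ model.ridge_coef + model.ridge_intercept

    out = []
    for i in picked:
        x = counts[i]
        active = np.flatnonzero(x)
        out.append(
            kernel_shap(predict_fn, x, background, active=active,
                        n_samples=n_samples, exact_limit=exact_limit,
                        seed=seed + int(i), record_id=_rid(records[i], i))
        )
    return out


def _seq(record) -> str:
    return record.seq if hasattr(record, "seq") else str(record)


def _rid(record, i) -> str:
    return record.id if hasattr(record, "id") else f"seq{i}"


# ---------------------------------------------------------------------------
# positional mapping

def _reference_coordinates(alignment: Mapping[str, str], reference_id: str):
    """For each alignment column, the 1-based reference position it belongs
    to: non-gap reference columns map to themselves; reference-gap columns
    (insertions) attach to the preceding reference position (position 1 for
    a leading insertion)."""
    ref = alignment[reference_id]
    col_to_ref = np.zeros(len(ref), dtype=int)
    is_ref_col = np.zeros(len(ref), dtype=bool)
    p = 0
    for c, ch in enumerate(ref):
        if ch != "-":
            p += 1
            is_ref_col[c] = True
        col_to_ref[c] = max(p, 1)
    n_ref = p
    if n_ref == 0:
        raise ValueError("reference row is all gaps")
    return col_to_ref, is_ref_col, n_ref


def map_shap_to_positions(
    attribution: AttributionRecord,
    record,
    alignment: Mapping[str, str],
    reference_id: str,
    kmer_names: Sequence[str],
    split: bool = False,
) -> np.ndarray:
    """Project one record's k-mer SHAP values onto reference positions.

    Every occurrence of an attributed k-mer at ungapped positions [i, i+K)
    adds its phi to each covered position (``split`` divides phi by K
    instead); positions translate through the alignment to 1-based reference
    coordinates. Returns a length-n_ref vector of summed contributions.
    """
    rid = _rid(record, 0)
    if rid not in alignment:
        raise ValueError(f"record {rid!r} absent from alignment")
    row = alignment[rid]
    seq = _seq(record).upper()
    ungapped = row.replace("-", "").upper()
    if ungapped != seq:
        raise ValueError(f"record {rid!r}: alignment row does not match sequence")
    col_to_ref, _, n_ref = _reference_coordinates(alignment, reference_id)
    # ungapped index -> alignment column
    cols = np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord("-"))
    K = len(kmer_names[attribution.feature_indices[0]]) if len(attribution.feature_indices) else 0
    out = np.zeros(n_ref)
    phi_by_kmer = {
        kmer_names[f]: attribution.phi[j]
        for j, f in enumerate(attribution.feature_indices)
    }
    if not phi_by_kmer:
        return out
    for i in range(len(seq) - K + 1):
        phi = phi_by_kmer.get(seq[i : i + K])
        if phi is None:
            continue
        value = phi / K if split else phi
        for pos in range(i, i + K):
            out[col_to_ref[cols[pos]] - 1] += value
    return out


def aggregate_positions(per_record: Sequence[np.ndarray]) -> pd.DataFrame:
    """Aggregate per-record positional contributions across records.

    Emits both the mean absolute per-position sum and its RMS counterpart
    sqrt(mean(phi^2)).
    """
    mat = np.stack(per_record)
    return pd.DataFrame({
        "position": np.arange(1, mat.shape[1] + 1),
        "mean_abs_shap": np.mean(np.abs(mat), axis=0),
        "rms_shap": np.sqrt(np.mean(mat**2, axis=0)),
    })


# ---------------------------------------------------------------------------
# mutation rates

def mutation_rates(alignment: Mapping[str, str], reference_id: str) -> pd.DataFrame:
    """Per-reference-position substitution, deletion and insertion rates.

    Computed over the N non-reference rows: substitution rate = differing
    bases / non-gap bases at the column; deletion rate = gaps / N; insertion
    rate at position p = fraction of sequences with at least one residue in
    the reference-gap columns following p.
    """
    if reference_id not in alignment:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    ids = [k for k in alignment if k != reference_id]
    if not ids:
        raise ValueError("alignment has no non-reference rows")
    width = {len(v) for v in alignment.values()}
    if len(width) != 1:
        raise ValueError("alignment rows differ in length")
    ref = alignment[reference_id].upper()
    rows = np.array([list(alignment[i].upper()) for i in ids])
    N = len(ids)
    col_to_ref, is_ref_col, n_ref = _reference_coordinates(alignment, reference_id)

    sub = np.zeros(n_ref)
    dele = np.zeros(n_ref)
    ins = np.zeros(n_ref)
    for c in np.flatnonzero(is_ref_col):
        p = col_to_ref[c] - 1
        col = rows[:, c]
        nongap = col != "-"
        n_nongap = int(nongap.sum())
        sub[p] = (np.sum(col[nongap] != ref[c]) / n_nongap) if n_nongap else 0.0
        dele[p] = np.sum(~nongap) / N
    insert_cols = np.flatnonzero(~is_ref_col)
    if insert_cols.size:
        for p in np.unique(col_to_ref[insert_cols]):
            cols_here = insert_cols[col_to_ref[insert_cols] == p]
            has_residue = np.any(rows[:, cols_here] != "-", axis=1)
            ins[p - 1] = has_residue.sum() / N
    return pd.DataFrame({
        "position": np.arange(1, n_ref + 1),
        "sub_rate": sub,
        "del_rate": dele,
        "ins_rate": ins,
    })


# ---------------------------------------------------------------------------
# rank clustering + ELU fit

def rank_cluster_upper_bound(
    insertion_rates, shap_values, k: int = 50, seed: int = 0
) -> pd.DataFrame:
    """1-D k-means of insertion rates into k ranks; per rank the mean rate and
    the max SHAP value (the empirical upper bound)."""
    rates = np.asarray(insertion_rates, dtype=float)
    shap = np.asarray(shap_values, dtype=float)
    if rates.shape != shap.shape:
        raise ValueError("rates and SHAP vectors must align")
    n_distinct = len(np.unique(rates))
    if k > n_distinct:
        import warnings
        warnings.warn(f"k={k} > {n_distinct} distinct rates; reducing")
        k = n_distinct
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(rates.reshape(-1, 1))
    recs = []
    for lab in np.unique(labels):
        sel = labels == lab
        recs.append({"mean_rate": float(rates[sel].mean()),
                     "max_shap": float(shap[sel].max())})
    return pd.DataFrame(recs).sort_values("mean_rate").reset_index(drop=True)


def fit_elu(
    x, y, learning_rate: float = 0.01, iterations: int = 2000,
    seed: int = 0, restarts: int = 5,
) -> EluFit:
    """Fit ŷ = a*ELU(b*(x - x0)) + c by Adam on the MSE.

    Runs a few seeded restarts from data-scaled initializations and keeps the
    best; reports R^2 = 1 - SS_res/SS_tot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.Generator(np.random.PCG64(seed))
    xs, ys = np.std(x) or 1.0, np.std(y) or 1.0
    best = None
    for _ in range(restarts):
        params = np.array([
            ys * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0),
            rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0) / xs,
            np.median(x) + rng.normal(0, xs),
            np.mean(y) + rng.normal(0, ys),
        ])
        params, mse = _adam_elu(x, y, params, learning_rate, iterations)
        if best is None or mse < best[1]:
            best = (params, mse)
    a, b, x0, c = best[0]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - (best[1] * len(y)) / ss_tot if ss_tot > 0 else 0.0
    return EluFit(float(a), float(b), float(x0), float(c), float(r2),
                  learning_rate, iterations)


def _adam_elu(x, y, params, lr, iters):
    m = np.zeros(4)
    v = np.zeros(4)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, iters + 1):
        a, b, x0, c = params
        u = b * (x - x0)
        e = np.where(u > 0, u, np.expm1(np.minimum(u, 0.0)))
        de = np.where(u > 0, 1.0, np.exp(np.minimum(u, 0.0)))
        pred = a * e + c
        r = pred - y
        n = len(y)
        g = np.array([
            2.0 * np.mean(r * e),
            2.0 * np.mean(r * a * de * (x - x0)),
            2.0 * np.mean(r * a * de * (-b)),
            2.0 * np.mean(r),
        ])
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient in ELU fit")
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        params = params - lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
    a, b, x0, c = params
    u = b * (x - x0)
    pred = a * np.where(u > 0, u, np.expm1(np.minimum(u, 0.0))) + c
    return params, float(np.mean((pred - y) ** 2))
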