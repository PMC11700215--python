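"""PCA-LDA benchmark arm: PCA, PC-count selection, Fisher LDA, LOOV.

PCA is covariance-based on centred (not autoscaled) spectra — they are
already area-normalised.  The discriminant is the two-class Fisher linear
discriminant function (LDF) on the leading PC scores,
LDF = w1*PC1 + ... + wn*PCn, with classification by nearest group mean on
the one-dimensional LDF axis (equal priors).  Leave-one-out cross-validation
refits PCA and LDA for every held-out observation; plain LOOV is
deterministic, so repeats with shuffled presentation order serve as a
numerical-stability check and their mean is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .spectra import SpectrumSet

__all__ = [
    "PCAModel", "LDAModel", "LOOVResult", "fit_pca", "select_n_pcs",
    "fit_lda", "loov_accuracy", "sum_weighted_loadings", "PCALDA",
    "PCALDAResults",
]


@dataclass
class PCAModel:
    loadings: np.ndarray                # (n_pcs, n_points), orthonormal rows
    scores: np.ndarray                  # (n_obs, n_pcs)
    explained_variance_pct: np.ndarray  # non-increasing, sums to <= 100
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings.T


@dataclass
class LDAModel:
    n_pcs: int
    weights: np.ndarray                 # LDF coefficients, unit Euclidean norm
    classes: np.ndarray
    group_means_ldf: np.ndarray         # per class, on the 1-D LDF axis
    between_within_ratio: np.ndarray    # per included PC
    regularized: bool = False

    def project(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores)[:, : self.n_pcs] @ self.weights

    def classify(self, scores: np.ndarray) -> np.ndarray:
        z = self.project(scores)
        d = np.abs(z[:, None] - self.group_means_ldf[None, :])
        return self.classes[np.argmin(d, axis=1)]


@dataclass
class LOOVResult:
    accuracy_pct: float                 # mean over repeats
    per_repeat_pct: np.ndarray
    n_pcs: int

    @property
    def sd_pct(self) -> float:
        if self.per_repeat_pct.size < 2:
            return 0.0
        return float(self.per_repeat_pct.std(ddof=1))


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectrumSet):
        return data.intensities
    return np.asarray(data, float)


def fit_pca(data, n_components: int | None = None) -> PCAModel:
    """Centred PCA of a SpectrumSet or matrix (full SVD)."""
    X = _as_matrix(data)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two observations")
    total_var = X.var(axis=0, ddof=1).sum()
    if total_var == 0:
        raise np.linalg.LinAlgError("constant data: no variance to decompose")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = _SkPCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAModel(loadings=pca.components_, scores=scores,
                    explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
                    mean=pca.mean_)


def select_n_pcs(model: PCAModel, strategy: str = "fixed", k: int = 7) -> int:
    """PC count by strategy: "fixed" (default k=7), "kaiser", or "elbow".

    Kaiser keeps components whose variance exceeds the average component
    variance; the elbow is the interior point of maximum discrete curvature
    (second difference) of the explained-variance sequence.
    """
    v = model.explained_variance_pct
    if strategy == "fixed":
        return int(min(k, v.size))
    if strategy == "kaiser":
        return int(max(1, (v > v.mean()).sum()))
    if strategy == "elbow":
        if v.size < 3:
            return 1
        curv = v[:-2] - 2.0 * v[1:-1] + v[2:]
        return int(np.argmax(curv) + 2)  # 1-based index of the interior point
    raise ValueError(f"unknown strategy {strategy!r}")


def fit_lda(scores: np.ndarray, labels: np.ndarray, n_pcs: int) -> LDAModel:
    """Two-class Fisher discriminant on the first ``n_pcs`` score columns."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("LDA here is two-class; got "
                         f"{classes.size} classes")
    if n_pcs < 1 or n_pcs > scores.shape[1]:
        raise ValueError("n_pcs outside the available PC range")
    S = scores[:, :n_pcs]
    groups = [S[labels == c] for c in classes]
    means = np.array([g.mean(axis=0) for g in groups])
    sw = np.zeros((n_pcs, n_pcs))
    for g, m in zip(groups, means):
        d = g - m
        sw += d.T @ d
    regularized = False
    try:
        w = np.linalg.solve(sw, means[1] - means[0])
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        regularized = True
        ridge = 1e-8 * max(np.trace(sw) / n_pcs, 1.0)
        w = np.linalg.solve(sw + ridge * np.eye(n_pcs), means[1] - means[0])
    w = w / np.linalg.norm(w)

    pooled_within = np.zeros(n_pcs)
    for g, m in zip(groups, means):
        pooled_within += ((g - m) ** 2).sum(axis=0)
    pooled_within /= max(S.shape[0] - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (means[1] - means[0]) ** 2 / pooled_within
    return LDAModel(n_pcs=n_pcs, weights=w, classes=classes,
                    group_means_ldf=means @ w, between_within_ratio=ratio,
                    regularized=regularized)


def loov_accuracy(data, labels: np.ndarray, n_pcs: int = 7, repeats: int = 1,
                  seed: int = 0) -> LOOVResult:
    """Leave-one-out accuracy of the PCA-LDA classifier, in percent.

    Each held-out observation is classified by a PCA+LDA refit on the
    remaining rows.  ``repeats`` re-runs the loop with shuffled presentation
    order — LOOV itself is deterministic, so the spread across repeats
    measures numerical stability only.

    The per-holdout PCA refit runs on the observation Gram matrix (the
    kernel form of centred PCA): with n observations of p >> n wavenumber
    variables, the leading score columns are recovered from the top
    eigenpairs of the doubly-centred n x n Gram block, and the held-out
    spectrum is projected through the same eigenbasis, so no step inside
    the loop touches the p-dimensional space.
    """
    from scipy.linalg import eigh

    X = _as_matrix(data)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOV needs at least three observations")
    gram = X @ X.T
    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for r in range(repeats):
        order = np.arange(n) if repeats == 1 else rng.permutation(n)
        correct = 0
        for i in order:
            keep = np.flatnonzero(np.arange(n) != i)
            m = keep.size
            sub = gram[np.ix_(keep, keep)]
            row_mean = sub.mean(axis=1)
            grand = row_mean.mean()
            centred = sub - row_mean[:, None] - row_mean[None, :] + grand
            k = min(n_pcs, m - 1)
            vals, vecs = eigh(centred, subset_by_index=[m - k, m - 1])
            idx = np.argsort(vals)[::-1]
            svals = np.sqrt(np.clip(vals[idx], 0.0, None))
            vecs = vecs[:, idx]
            scores = vecs * svals
            lda = fit_lda(scores, labels[keep], k)
            a = gram[i, keep] - gram[i, keep].mean() - row_mean + grand
            z = (a @ vecs) / np.where(svals > 0, svals, 1.0)
            pred = lda.classify(z[None, :])[0]
            correct += pred == labels[i]
        accs[r] = 100.0 * correct / n
    return LOOVResult(accuracy_pct=float(accs.mean()), per_repeat_pct=accs,
                      n_pcs=n_pcs)


def sum_weighted_loadings(pca: PCAModel, lda: LDAModel) -> np.ndarray:
    """LDF-weighted loadings summation over the included PCs."""
    if lda.n_pcs > pca.n_components:
        raise ValueError("LDA uses more PCs than the PCA model provides")
    return lda.weights @ pca.loadings[: lda.n_pcs]


class PCALDA:
    """Model object: spectra + class labels -> PCA-LDA classification arm.

    Parameters
    ----------
    data : SpectrumSet or (n_obs, n_points) array
    labels : per-observation class labels (two classes); taken from the
        SpectrumSet when omitted.
    """

    def __init__(self, data, labels: np.ndarray | None = None):
        self.X = _as_matrix(data)
        if labels is None and isinstance(data, SpectrumSet):
            labels = data.labels
        if labels is None:
            raise ValueError("class labels are required")
        self.labels = np.asarray(labels)
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("labels must match the number of observations")

    def fit(self, n_pcs: int | None = None, strategy: str = "fixed",
            k: int = 7) -> "PCALDAResults":
        pca = fit_pca(self.X)
        if n_pcs is None:
            n_pcs = select_n_pcs(pca, strategy=strategy, k=k)
        lda = fit_lda(pca.scores, self.labels, n_pcs)
        return PCALDAResults(model=self, pca=pca, lda=lda)


@dataclass
class PCALDAResults:
    """Fitted PCA-LDA arm: scores/loadings, LDF weights, diagnostics."""

    model: PCALDA
    pca: PCAModel
    lda: LDAModel
    _loov: LOOVResult | None = field(default=None, repr=False)

    def loov(self, repeats: int = 1, seed: int = 0) -> LOOVResult:
        res = loov_accuracy(self.model.X, self.model.labels,
                            n_pcs=self.lda.n_pcs, repeats=repeats, seed=seed)
        self._loov = res
        return res

    def sum_weighted_loadings(self) -> np.ndarray:
        return sum_weighted_loadings(self.pca, self.lda)

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pc": np.arange(1, self.pca.n_components + 1),
            "explained_variance_pct": self.pca.explained_variance_pct,
        })

    def report(self) -> dict:
        out = {
            "n_pcs": int(self.lda.n_pcs),
            "ldf_weights": self.lda.weights.tolist(),
            "between_within_ratio": self.lda.between_within_ratio.tolist(),
            "explained_variance_pct":
                self.pca.explained_variance_pct[: self.lda.n_pcs].tolist(),
            "classes": self.lda.classes.tolist(),
            "regularized": bool(self.lda.regularized),
        }
        if self._loov is not None:
            out["loov_accuracy_pct"] = self._loov.accuracy_pct
            out["loov_sd_pct"] = self._loov.sd_pct
            out["loov_repeats"] = int(self._loov.per_repeat_pct.size)
        return out

    def summary(self) -> str:
        lines = ["PCA-LDA summary", "=" * 56,
                 f"{'PC':>4} {'var %':>8} {'B/W ratio':>12} {'LDF weight':>12}"]
        for i in range(self.lda.n_pcs):
            lines.append(
                f"{i + 1:4d} {self.pca.explained_variance_pct[i]:8.2f} "
                f"{self.lda.between_within_ratio[i]:12.4g} "
                f"{self.lda.weights[i]:12.4g}")
        if self._loov is not None:
            lines.append(f"LOOV accuracy: {self._loov.accuracy_pct:.2f}% "
                         f"(SD {self._loov.sd_pct:.3f} over "
                         f"{self._loov.per_repeat_pct.size} repeats)")
        return "\n".join(lines)
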