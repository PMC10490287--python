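"""Classifier-ready features from cleaned epochs.

Stages, fitted on training data only and reusable on held-out epochs:

1. xDawn-style spatial filtering — per class, the filters maximize the
   Rayleigh quotient of evoked-prototype variance against total signal
   variance (generalized eigenvectors).
2. Super-trial covariance augmentation — each epoch is stacked under the
   filtered class prototypes of every class, and the shrunk spatial
   covariance of the stack is taken.  With K classes and ``nfilter`` filters
   per class the matrices are 2*K*nfilter square (48 x 48 for K=4,
   nfilter=6).
3. Tangent-space mapping at the Frechet mean of the training covariances,
   giving n(n+1)/2 features per epoch (1176 for n=48).
4. Fisher geodesic discriminant filtering — a Fisher discriminant basis in
   tangent coordinates; features are projected onto the basis and back,
   which keeps dimensionality but discards directions that carry no
   between-class variance.
5. PCA followed by one-way ANOVA F-score selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif

from .geometry import covariance, riemannian_mean, tangent_space
from .preprocess import STATES, EpochSet

__all__ = [
    "XdawnModel",
    "FGDAModel",
    "SelectionModel",
    "FeatureExtractor",
    "fit_xdawn",
    "augment_covariances",
    "fit_fgda",
    "select_features",
]


def _class_order(labels) -> list:
    present = set(np.asarray(labels).tolist())
    ordered = [s for s in STATES if s in present]
    return ordered + sorted(present - set(ordered))


@dataclass
class XdawnModel:
    classes: list
    prototypes: dict  # class -> (channels, L) mean epoch
    filters: dict  # class -> (nfilter, channels), unit-norm rows
    nfilter: int


def fit_xdawn(eps: EpochSet, nfilter: int = 6) -> XdawnModel:
    """Fit per-class spatial filters from epoch prototypes.

    For class c with prototype P_c (the mean epoch) the filters are the top
    generalized eigenvectors of (P_c P_c^T / L, C_x) where C_x is the total
    signal covariance — directions maximizing evoked response variance
    relative to overall variance.
    """
    labels = np.asarray(eps.labels)
    classes = _class_order(labels)
    if len(classes) == 0:
        raise ValueError("no labels")
    X = eps.data
    n_ch, L = X.shape[1], X.shape[2]
    if nfilter > n_ch:
        raise ValueError("nfilter cannot exceed channel count")
    flat = X.transpose(1, 0, 2).reshape(n_ch, -1)
    Cx = covariance(flat, shrinkage=0.01)
    prototypes, filters = {}, {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size < nfilter + 1:
            raise ValueError(
                f"class {c} has {idx.size} epochs; need at least {nfilter + 1}"
            )
        P = X[idx].mean(axis=0)
        Ce = P @ P.T / L
        w, V = linalg.eigh(0.5 * (Ce + Ce.T), Cx)
        W = V[:, ::-1][:, :nfilter].T  # rows = filters, descending eigenvalue
        W = W / np.linalg.norm(W, axis=1, keepdims=True)
        prototypes[c] = P
        filters[c] = W
    return XdawnModel(classes, prototypes, filters, nfilter)


def augment_covariances(
    eps: EpochSet | np.ndarray, model: XdawnModel, shrinkage: float = 0.05
) -> list:
    """Super-trial covariances: filtered prototypes of every class stacked
    over the filtered epoch signal, then the shrunk covariance of the stack.

    Output matrices have side 2 * K * nfilter.
    """
    X = eps.data if isinstance(eps, EpochSet) else np.asarray(eps)
    proto_block = np.vstack(
        [model.filters[c] @ model.prototypes[c] for c in model.classes]
    )
    out = []
    for epoch in X:
        if epoch.shape[1] != proto_block.shape[1]:
            raise ValueError(
                f"epoch length {epoch.shape[1]} != prototype length "
                f"{proto_block.shape[1]}"
            )
        sig_block = np.vstack([model.filters[c] @ epoch for c in model.classes])
        out.append(covariance(np.vstack([proto_block, sig_block]), shrinkage))
    return out


@dataclass
class FGDAModel:
    """Fisher discriminant filter in tangent coordinates."""

    basis: np.ndarray  # (d, r), orthonormal columns
    grand_mean: np.ndarray  # (d,)

    def filter(self, V: np.ndarray) -> np.ndarray:
        """Project rows onto the discriminant subspace and back (idempotent)."""
        Vc = np.atleast_2d(V) - self.grand_mean
        return self.grand_mean + (Vc @ self.basis) @ self.basis.T


def fit_fgda(V: np.ndarray, labels, shrinkage: float = 0.9) -> FGDAModel:
    """Fit the Fisher basis: top K-1 generalized eigenvectors of the
    between-class scatter against the regularized within-class scatter,
    orthonormalized.

    The within-class scatter is shrunk toward a scaled identity,
    ``(1 - shrinkage) * Sw + shrinkage * (tr(Sw)/d) * I``.  Tangent feature
    dimension d is typically far larger than the training-set size, where the
    raw Sw inverse is hopelessly overfit; heavy shrinkage (default 0.9) keeps
    the discriminant directions dominated by the well-estimated class means.
    With ``shrinkage = 0`` a singular Sw raises.
    """
    V = np.asarray(V, dtype=float)
    labels = np.asarray(labels)
    classes = _class_order(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if V.shape[0] <= len(classes):
        raise ValueError("need more rows than classes")
    d = V.shape[1]
    mu = V.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Vc = V[labels == c]
        mc = Vc.mean(axis=0)
        Sw += (Vc - mc).T @ (Vc - mc)
        Sb += len(Vc) * np.outer(mc - mu, mc - mu)
    Sw /= len(V)
    Sb /= len(V)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    if shrinkage == 0 and np.linalg.matrix_rank(Sw) < d:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; use shrinkage > 0"
        )
    reg = (1.0 - shrinkage) * Sw + shrinkage * (np.trace(Sw) / d) * np.eye(d)
    w, U = linalg.eigh(0.5 * (Sb + Sb.T), 0.5 * (reg + reg.T))
    r = len(classes) - 1
    directions = U[:, ::-1][:, :r]
    basis = np.linalg.qr(directions)[0]  # same span, orthonormal columns
    return FGDAModel(basis=basis, grand_mean=mu)


@dataclass
class SelectionModel:
    """Centering + PCA projection + ANOVA-F top-k component selection."""

    pca: PCA
    f_scores: np.ndarray  # F per retained PCA component
    kept: np.ndarray  # indices into PCA components, sorted ascending

    def transform(self, V: np.ndarray) -> np.ndarray:
        return self.pca.transform(np.atleast_2d(V))[:, self.kept]


def select_features(
    V: np.ndarray, labels, n_pca: int = 60, k_anova: int = 40
) -> tuple[SelectionModel, np.ndarray]:
    """Reduce tangent features: top ``n_pca`` principal components, then keep
    the ``k_anova`` components with the largest one-way ANOVA F across
    classes.  Returns the fitted transform and the reduced training matrix.
    """
    V = np.asarray(V, dtype=float)
    n_pca = min(n_pca, min(V.shape))
    if k_anova > n_pca:
        raise ValueError("k_anova cannot exceed n_pca")
    pca = PCA(n_components=n_pca, svd_solver="full")
    Z = pca.fit_transform(V)
    F, _ = f_classif(Z, np.asarray(labels))
    F = np.nan_to_num(F, nan=0.0)
    kept = np.sort(np.argsort(F)[::-1][:k_anova])
    model = SelectionModel(pca=pca, f_scores=F, kept=kept)
    return model, Z[:, kept]


@dataclass
class FeatureExtractor:
    """End-to-end feature transform, fitted on training epochs only.

    fit() learns the xDawn filters, the Frechet reference mean, the Fisher
    basis and the PCA/ANOVA selection; transform() applies them to held-out
    epochs without touching their labels.
    """

    nfilter: int = 6
    shrinkage: float = 0.05
    n_pca: int = 60
    k_anova: int = 40
    use_fgda: bool = True
    xdawn: XdawnModel = field(default=None, repr=False)
    base: np.ndarray = field(default=None, repr=False)
    fgda: FGDAModel = field(default=None, repr=False)
    selection: SelectionModel = field(default=None, repr=False)

    def fit(self, eps: EpochSet) -> np.ndarray:
        """Fit all stages on labelled epochs; returns the training features."""
        self.xdawn = fit_xdawn(eps, nfilter=self.nfilter)
        covs = augment_covariances(eps, self.xdawn, self.shrinkage)
        self.base = riemannian_mean(covs)
        V, _ = tangent_space(covs, base=self.base)
        if self.use_fgda:
            self.fgda = fit_fgda(V, eps.labels)
            V = self.fgda.filter(V)
        self.selection, Z = select_features(
            V, eps.labels, n_pca=self.n_pca, k_anova=self.k_anova
        )
        return Z

    def transform(self, eps: EpochSet | np.ndarray) -> np.ndarray:
        if self.xdawn is None:
            raise RuntimeError("FeatureExtractor is not fitted")
        covs = augment_covariances(eps, self.xdawn, self.shrinkage)
        V, _ = tangent_space(covs, base=self.base)
        if self.use_fgda:
            V = self.fgda.filter(V)
        return self.selection.transform(V)
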