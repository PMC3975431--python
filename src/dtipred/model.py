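"""Pair-vector assembly, standardization and the RBF-kernel classifier.

A drug-protein pair is represented by the orthogonal sum (concatenation) of
the drug's 256-component fingerprint and the protein's 500-component PseAAC:
a 756-component raw vector x. Each component is standardized to
y_i = (x_i - <x_i>) / SD(x_i) with mean and standard deviation taken over the
training vectors, and the standardized vectors are classified by a
soft-margin support vector machine with the radial basis function kernel
k(u, v) = exp(-gamma * ||u - v||^2).

Two layers are provided:

* free functions (:func:`combine`, :func:`fit_standardizer`,
  :func:`apply_standardizer`, :func:`train`, :func:`predict`,
  :func:`grid_search`) operating on arrays;
* a model/results pair (:class:`InteractionModel` /
  :class:`InteractionResults`) that wraps a :class:`~dtipred.io.Dataset`,
  caches protein encodings, and exposes ``fit``, ``jackknife``,
  ``grid_search`` and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import ValidationError
from .io import Dataset, DrugFingerprint, LabeledPair
from .protein import N_PSEAAC, encode_protein

N_DRUG = 256
N_PAIR = N_DRUG + N_PSEAAC  # 756

#: Operating point found by the original 2-D grid search: C = 2^3, gamma = 2^-9.
DEFAULT_C = 2.0**3
DEFAULT_GAMMA = 2.0**-9

#: Default power-of-two grids for the 2-D search; they contain the
#: operating point above.
DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-15, 4, 2))


def combine(drug: DrugFingerprint, protein_psi: np.ndarray) -> np.ndarray:
    """Concatenate drug fingerprint then protein PseAAC into the raw
    756-component pair vector."""
    psi = np.asarray(protein_psi, dtype=float).ravel()
    if psi.shape != (N_PSEAAC,):
        raise ValidationError(
            f"expected a {N_PSEAAC}-component protein vector, got {psi.size}"
        )
    return np.concatenate([drug.values, psi])


@dataclass(frozen=True)
class Standardizer:
    """Componentwise mean/SD transform fitted on training pair vectors."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: int

    def __post_init__(self) -> None:
        if self.fitted_on < 1:
            raise ValidationError("standardizer must be fitted on >= 1 vector")
        if np.any(self.sd < 0):
            raise ValidationError("standard deviations must be non-negative")


def fit_standardizer(training_raws: np.ndarray | Sequence[np.ndarray], ddof: int = 0) -> Standardizer:
    """Fit componentwise mean and standard deviation.

    ``ddof=0`` (the default) is the population SD with divisor n;
    ``ddof=1`` gives the sample SD.
    """
    x = np.atleast_2d(np.asarray(training_raws, dtype=float))
    if x.shape[0] < 1 or x.size == 0:
        raise ValidationError("cannot fit a standardizer on an empty training set")
    if x.shape[0] == 1 and ddof >= 1:
        raise ValidationError("sample SD needs >= 2 training vectors")
    return Standardizer(mean=x.mean(axis=0), sd=x.std(axis=0, ddof=ddof), fitted_on=x.shape[0])


def apply_standardizer(std: Standardizer, raw: np.ndarray) -> np.ndarray:
    """Standardize raw vectors; components with SD = 0 map to 0 (an
    information-free feature has no meaningful z-score)."""
    x = np.asarray(raw, dtype=float)
    centered = x - std.mean
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(std.sd > 0, centered / std.sd, 0.0)
    return y


@dataclass
class ClassifierModel:
    """A fitted RBF-kernel classifier plus its training metadata."""

    svc: SVC
    C: float
    gamma: float
    seed: int
    n_samples: int
    standardizer: Standardizer | None = None

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.svc.n_features_in_:
            raise ValidationError(
                f"expected {self.svc.n_features_in_}-component vectors, "
                f"got {x.shape[1]}"
            )
        return self.svc.decision_function(x)


def train(
    samples: np.ndarray,
    labels: Sequence[int],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    class_weight: Mapping[int, float] | str | None = None,
) -> ClassifierModel:
    """Fit the soft-margin RBF-kernel classifier on standardized vectors.

    Both classes must be present; ``C`` and ``gamma`` must be positive. The
    fit is deterministic given the seed (the underlying solver is itself
    deterministic for fixed data).
    """
    if C <= 0:
        raise ValidationError(f"penalty parameter C must be > 0, got {C}")
    if gamma <= 0:
        raise ValidationError(f"kernel parameter gamma must be > 0, got {gamma}")
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != y.size:
        raise ValidationError("sample and label counts differ")
    present = set(y.tolist())
    if present != {1, -1}:
        raise ValidationError(
            f"training needs both classes {{+1, -1}}, got labels {sorted(present)}"
        )
    svc = SVC(C=C, kernel="rbf", gamma=gamma, class_weight=class_weight, random_state=seed)
    svc.fit(x, y)
    return ClassifierModel(svc=svc, C=C, gamma=gamma, seed=seed, n_samples=x.shape[0])


def predict(model: ClassifierModel, vector: np.ndarray) -> tuple[int, float]:
    """Predict one standardized pair vector.

    Returns ``(label, decision_value)``; the label is the sign of the
    decision value, with an exact zero mapped to +1.
    """
    dv = float(model.decision_values(np.atleast_2d(vector))[0])
    return (1 if dv >= 0 else -1), dv


def predict_many(model: ClassifierModel, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dvs = model.decision_values(vectors)
    labels = np.where(dvs >= 0, 1, -1)
    return labels, dvs


# ---------------------------------------------------------------------------
# model / results layer
# ---------------------------------------------------------------------------


class InteractionModel:
    """Drug-protein interaction classifier over a :class:`Dataset`.

    Parameters
    ----------
    dataset
        Labeled pairs plus the protein sequences, PSSMs and drug
        fingerprints they reference.
    C, gamma
        SVM penalty and RBF kernel width; default to the grid-search
        operating point (2^3, 2^-9).
    standardize
        ``"fold"`` refits the standardizer on each training fold inside
        cross-validation (leakage-free, the default); ``"global"`` fits it
        once on the full dataset before any split.
    sd_ddof
        0 for population SD (default), 1 for sample SD.
    class_weight
        Passed to the SVM; ``None`` (default) applies no weighting despite
        the 1:2 class imbalance of the benchmark construction.
    grey_weights
        The three grey-feature weight factors of the protein encoding.
    """

    def __init__(
        self,
        dataset: Dataset,
        C: float = DEFAULT_C,
        gamma: float = DEFAULT_GAMMA,
        standardize: str = "fold",
        sd_ddof: int = 0,
        class_weight: Mapping[int, float] | str | None = None,
        grey_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> None:
        if standardize not in ("fold", "global"):
            raise ValidationError(
                f"standardize must be 'fold' or 'global', got {standardize!r}"
            )
        self.dataset = dataset
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.sd_ddof = sd_ddof
        self.class_weight = class_weight
        self.grey_weights = grey_weights
        self._protein_cache: dict[str, np.ndarray] = {}

    # -- encoding ----------------------------------------------------------

    def protein_vector(self, protein_id: str) -> np.ndarray:
        """The (cached) 500-component PseAAC vector of one protein."""
        if protein_id not in self._protein_cache:
            seq = self.dataset.proteins[protein_id]
            pssm = self.dataset.pssms[protein_id]
            self._protein_cache[protein_id] = encode_protein(seq, pssm, self.grey_weights)
        return self._protein_cache[protein_id]

    def pair_vector(self, pair: LabeledPair) -> np.ndarray:
        """The raw 756-component vector of one pair."""
        drug = self.dataset.fingerprints[pair.drug_id]
        return combine(drug, self.protein_vector(pair.protein_id))

    def design_matrix(self, pairs: Sequence[LabeledPair] | None = None) -> np.ndarray:
        """Raw pair vectors stacked into an (n, 756) matrix."""
        pairs = self.dataset.pairs if pairs is None else pairs
        if not pairs:
            raise ValidationError("no pairs to encode")
        return np.vstack([self.pair_vector(p) for p in pairs])

    def labels(self) -> np.ndarray:
        y = np.array([p.label if p.label is not None else 0 for p in self.dataset.pairs])
        if np.any(y == 0):
            raise ValidationError("dataset contains unlabeled pairs; cannot fit")
        return y

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> "InteractionResults":
        """Fit the standardizer and classifier on all labeled pairs."""
        x_raw = self.design_matrix()
        y = self.labels()
        std = fit_standardizer(x_raw, ddof=self.sd_ddof)
        clf = train(
            apply_standardizer(std, x_raw),
            y,
            C=self.C,
            gamma=self.gamma,
            seed=seed,
            class_weight=self.class_weight,
        )
        clf.standardizer = std
        return InteractionResults(model=self, classifier=clf, standardizer=std, seed=seed)

    def jackknife(self, seed: int = 0):
        """Leave-one-out evaluation; see :func:`dtipred.evaluation.jackknife`."""
        from .evaluation import jackknife

        return jackknife(
            self.dataset,
            C=self.C,
            gamma=self.gamma,
            standardize_mode=self.standardize,
            seed=seed,
            sd_ddof=self.sd_ddof,
            class_weight=self.class_weight,
            grey_weights=self.grey_weights,
        )

    def grid_search(
        self,
        C_grid: Sequence[float] = DEFAULT_C_GRID,
        gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
        seed: int = 0,
    ) -> "GridSearchResult":
        return grid_search(self.dataset, C_grid, gamma_grid, seed=seed,
                           standardize_mode=self.standardize, sd_ddof=self.sd_ddof,
                           class_weight=self.class_weight, grey_weights=self.grey_weights)


@dataclass
class InteractionResults:
    """A fitted interaction classifier bound to its standardizer."""

    model: InteractionModel
    classifier: ClassifierModel
    standardizer: Standardizer
    seed: int

    def predict_pairs(self, pairs: Sequence[LabeledPair], dataset: Dataset | None = None):
        """Predict labels and decision values for pairs, returned as a
        DataFrame with columns drug_id, protein_id, decision_value, label."""
        import pandas as pd

        source = self.model if dataset is None else InteractionModel(
            dataset, C=self.model.C, gamma=self.model.gamma,
            grey_weights=self.model.grey_weights,
        )
        x_raw = source.design_matrix(pairs)
        labels, dvs = predict_many(self.classifier, apply_standardizer(self.standardizer, x_raw))
        return pd.DataFrame(
            {
                "drug_id": [p.drug_id for p in pairs],
                "protein_id": [p.protein_id for p in pairs],
                "decision_value": dvs,
                "label": labels,
            }
        )

    def summary(self) -> str:
        counts = self.model.dataset.describe()
        n_sv = int(self.classifier.svc.n_support_.sum())
        lines = [
            "Drug-protein interaction model (RBF-kernel SVM)",
            "=" * 48,
            f"Pairs fitted:        {counts['n_pairs']} "
            f"({counts['n_positive']} interactive, {counts['n_negative']} non-interactive)",
            f"Distinct drugs:      {counts['n_drugs']}",
            f"Distinct proteins:   {counts['n_proteins']}",
            f"Feature vector:      {N_PAIR} = {N_DRUG} (fingerprint) + {N_PSEAAC} (PseAAC)",
            f"C (penalty):         {self.classifier.C:g}",
            f"gamma (kernel):      {self.classifier.gamma:g}",
            f"Standardization:     {self.model.standardize} "
            f"({'population' if self.model.sd_ddof == 0 else 'sample'} SD)",
            f"Support vectors:     {n_sv}",
        ]
        return "\n".join(lines)


@dataclass
class GridSearchResult:
    """Outcome of the 2-D (C, gamma) grid search by jackknife accuracy."""

    best_C: float
    best_gamma: float
    best_accuracy: float
    surface: "object"  # pandas DataFrame: columns C, gamma, accuracy

    def plot_surface(self, path: str | None = None):
        """3-D surface of jackknife accuracy over log2 C and log2 gamma."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.surface
        fig = plt.figure(figsize=(7, 5))
        ax = fig.add_subplot(projection="3d")
        ax.plot_trisurf(np.log2(df["C"]), np.log2(df["gamma"]), df["accuracy"],
                        cmap="viridis")
        ax.set_xlabel("log2 C")
        ax.set_ylabel("log2 gamma")
        ax.set_zlabel("jackknife accuracy")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def grid_search(
    dataset: Dataset,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
    standardize_mode: str = "fold",
    sd_ddof: int = 0,
    class_weight: Mapping[int, float] | str | None = None,
    grey_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> GridSearchResult:
    """Exhaustive 2-D grid search maximizing jackknife overall accuracy.

    Ties are broken toward the smaller C, then the smaller gamma. The full
    accuracy surface is returned for inspection and plotting.
    """
    import pandas as pd

    from .evaluation import jackknife

    if not len(C_grid) or not len(gamma_grid):
        raise ValidationError("C and gamma grids must be non-empty")
    rows = []
    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            metrics, _ = jackknife(
                dataset, C=C, gamma=gamma, standardize_mode=standardize_mode,
                seed=seed, sd_ddof=sd_ddof, class_weight=class_weight,
                grey_weights=grey_weights,
            )
            rows.append({"C": C, "gamma": gamma, "accuracy": metrics.acc})
            if best is None or metrics.acc > best[0]:
                best = (metrics.acc, C, gamma)
    assert best is not None
    return GridSearchResult(
        best_C=best[1], best_gamma=best[2], best_accuracy=best[0],
        surface=pd.DataFrame(rows),
    )
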