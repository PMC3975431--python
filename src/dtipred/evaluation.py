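"""Benchmark construction and evaluation: negative-pair sampling, jackknife
(leave-one-out) cross-validation, and the Chou-form metric set.

With N+ interactive pairs of which fn are mispredicted, and N- non-interactive
pairs of which fp are mispredicted, the metrics are

    Sn  = 1 - fn/N+
    Sp  = 1 - fp/N-
    Acc = 1 - (fn + fp)/(N+ + N-)
    MCC = (1 - (fn/N+ + fp/N-)) /
          sqrt( (1 + (fp - fn)/N+) * (1 + (fn - fp)/N-) )

This rearrangement is algebraically identical to the textbook
sensitivity/specificity/accuracy/Matthews-correlation formulas with
TP = N+ - fn, FN = fn, TN = N- - fp, FP = fp, but reads directly off the two
misprediction counts: fn = fp = 0 gives all four metrics 1, and half-errors
in both classes (fn = N+/2, fp = N-/2) give MCC = 0, chance level. MCC is
undefined when a predicted class is empty (zero factor under the square
root); that case is flagged rather than coerced to a number.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import Dataset, LabeledPair
from .model import (
    apply_standardizer,
    combine,
    fit_standardizer,
    predict,
    train,
)
from .protein import encode_protein


@dataclass(frozen=True)
class ConfusionCounts:
    """Class totals and misprediction counts of a binary evaluation.

    ``fn`` is the number of interactive pairs predicted non-interactive;
    ``fp`` the number of non-interactive pairs predicted interactive.
    """

    n_pos: int
    n_neg: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if not (0 <= self.fn <= self.n_pos):
            raise ValidationError(f"fn must lie in [0, n_pos]: fn={self.fn}, n_pos={self.n_pos}")
        if not (0 <= self.fp <= self.n_neg):
            raise ValidationError(f"fp must lie in [0, n_neg]: fp={self.fp}, n_neg={self.n_neg}")


@dataclass(frozen=True)
class MetricsResult:
    """Sensitivity, specificity, overall accuracy and Matthews correlation.

    ``mcc`` is NaN when undefined (``mcc_defined`` False), which happens only
    when the classifier predicts a single class for everything.
    """

    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_defined: bool = True

    def as_percent(self) -> dict[str, str]:
        """Metrics as percent strings rounded half-up to 2 decimals."""
        out = {}
        for name in ("sn", "sp", "acc", "mcc"):
            value = getattr(self, name)
            if name == "mcc" and not self.mcc_defined:
                out[name] = "undefined"
            else:
                out[name] = f"{percent_round(value)}%"
        return out

    def summary(self) -> str:
        pct = self.as_percent()
        return "\n".join(
            [
                "Prediction quality",
                "-" * 30,
                f"Sensitivity (Sn):   {pct['sn']:>10}",
                f"Specificity (Sp):   {pct['sp']:>10}",
                f"Accuracy    (Acc):  {pct['acc']:>10}",
                f"Matthews    (MCC):  {pct['mcc']:>10}",
            ]
        )


def percent_round(fraction: float, digits: int = 2) -> float:
    """Fraction -> percentage rounded half-up to ``digits`` decimals."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(fraction * 100)).quantize(quantum, rounding=ROUND_HALF_UP))


def confusion(predictions: Sequence[int], truths: Sequence[int]) -> ConfusionCounts:
    """Tally misprediction counts from parallel label sequences in {+1, -1}."""
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truths, dtype=int)
    if pred.shape != true.shape:
        raise ValidationError(
            f"prediction and truth lengths differ: {pred.size} vs {true.size}"
        )
    for arr, what in ((pred, "prediction"), (true, "truth")):
        bad = set(arr.tolist()) - {1, -1}
        if bad:
            raise ValidationError(f"{what} labels must be +1/-1, got {sorted(bad)}")
    n_pos = int(np.sum(true == 1))
    n_neg = int(np.sum(true == -1))
    fn = int(np.sum((true == 1) & (pred == -1)))
    fp = int(np.sum((true == -1) & (pred == 1)))
    return ConfusionCounts(n_pos=n_pos, n_neg=n_neg, fn=fn, fp=fp)


def chou_metrics(c: ConfusionCounts) -> MetricsResult:
    """Compute Sn, Sp, Acc and MCC in the misprediction-count form above."""
    if c.n_pos <= 0 or c.n_neg <= 0:
        raise ValidationError(
            f"metrics need both classes present: n_pos={c.n_pos}, n_neg={c.n_neg}"
        )
    fn_rate = c.fn / c.n_pos
    fp_rate = c.fp / c.n_neg
    sn = 1.0 - fn_rate
    sp = 1.0 - fp_rate
    acc = 1.0 - (c.fn + c.fp) / (c.n_pos + c.n_neg)
    factor_pos = 1.0 + (c.fp - c.fn) / c.n_pos
    factor_neg = 1.0 + (c.fn - c.fp) / c.n_neg
    denom_sq = factor_pos * factor_neg
    if denom_sq <= 0.0:
        return MetricsResult(sn=sn, sp=sp, acc=acc, mcc=float("nan"), mcc_defined=False)
    mcc = (1.0 - (fn_rate + fp_rate)) / np.sqrt(denom_sq)
    return MetricsResult(sn=sn, sp=sp, acc=acc, mcc=float(mcc))


# ---------------------------------------------------------------------------
# negative-pair construction
# ---------------------------------------------------------------------------


def sample_negative_pairs(
    positives: Sequence[LabeledPair],
    ratio: int = 2,
    seed: int = 0,
    drugs: Sequence[str] | None = None,
    proteins: Sequence[str] | None = None,
) -> list[LabeledPair]:
    """Build the non-interactive set by re-coupling the entities of the
    interactive pairs.

    Every drug from the positive set is crossed with every protein from the
    positive set; combinations already present as positives are excluded;
    ``ratio * len(positives)`` pairs are drawn uniformly without replacement
    from the remainder and labeled -1. Reproducible per seed.

    ``drugs`` / ``proteins`` widen the candidate entity sets beyond those
    appearing in the positives (used by the synthetic generator, where every
    generated entity is a legitimate candidate).
    """
    if not positives:
        raise ValidationError("cannot sample negatives from an empty positive set")
    drugs = sorted(drugs) if drugs is not None else sorted({p.drug_id for p in positives})
    prots = sorted(proteins) if proteins is not None else sorted({p.protein_id for p in positives})
    positive_keys = {p.key for p in positives}
    pool = [
        (d, pr)
        for d, pr in itertools.product(drugs, prots)
        if (d, pr) not in positive_keys
    ]
    n_needed = ratio * len(positives)
    if len(pool) < n_needed:
        raise ValidationError(
            f"candidate pool has only {len(pool)} non-interactive combinations; "
            f"{n_needed} needed"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_needed, replace=False)
    return [LabeledPair(pool[i][0], pool[i][1], -1) for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# jackknife cross-validation
# ---------------------------------------------------------------------------


def jackknife(
    dataset: Dataset,
    C: float,
    gamma: float,
    standardize_mode: str = "fold",
    seed: int = 0,
    sd_ddof: int = 0,
    class_weight: Mapping[int, float] | str | None = None,
    grey_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[MetricsResult, "object"]:
    """Leave-one-out evaluation of the pair classifier.

    Each of the n pairs is predicted by a classifier trained on the other
    n - 1. With ``standardize_mode="fold"`` the standardizer is refitted on
    each training fold (no information from the held-out pair leaks into the
    scaling); with ``"global"`` it is fitted once on all n pairs first.
    Returns the metric set over the n held-out predictions plus a DataFrame
    of per-pair predictions (drug_id, protein_id, truth, prediction,
    decision_value).
    """
    import pandas as pd

    if standardize_mode not in ("fold", "global"):
        raise ValidationError(
            f"standardize_mode must be 'fold' or 'global', got {standardize_mode!r}"
        )
    pairs = dataset.pairs
    n = len(pairs)
    if n < 2:
        raise ValidationError("jackknife needs at least 2 pairs")
    labels = np.array([p.label for p in pairs])
    if any(lbl is None for lbl in labels.tolist()):
        raise ValidationError("jackknife needs fully labeled pairs")
    labels = labels.astype(int)

    protein_vectors = {
        pid: encode_protein(dataset.proteins[pid], dataset.pssms[pid], grey_weights)
        for pid in sorted({p.protein_id for p in pairs})
    }
    x_raw = np.vstack(
        [combine(dataset.fingerprints[p.drug_id], protein_vectors[p.protein_id]) for p in pairs]
    )

    global_std = (
        fit_standardizer(x_raw, ddof=sd_ddof) if standardize_mode == "global" else None
    )

    preds = np.empty(n, dtype=int)
    dvs = np.empty(n, dtype=float)
    idx = np.arange(n)
    for i in range(n):
        train_idx = idx[idx != i]
        y_train = labels[train_idx]
        if len(set(y_train.tolist())) < 2:
            raise ValidationError(
                f"fold {i}: training split contains a single class"
            )
        std = global_std if global_std is not None else fit_standardizer(
            x_raw[train_idx], ddof=sd_ddof
        )
        clf = train(
            apply_standardizer(std, x_raw[train_idx]),
            y_train,
            C=C,
            gamma=gamma,
            seed=seed,
            class_weight=class_weight,
        )
        preds[i], dvs[i] = predict(clf, apply_standardizer(std, x_raw[i]))

    metrics = chou_metrics(confusion(preds, labels))
    detail = pd.DataFrame(
        {
            "drug_id": [p.drug_id for p in pairs],
            "protein_id": [p.protein_id for p in pairs],
            "truth": labels,
            "prediction": preds,
            "decision_value": dvs,
        }
    )
    return metrics, detail


def permutation_null_mcc(
    dataset: Dataset,
    C: float,
    gamma: float,
    n_replicates: int = 20,
    seed: int = 0,
    standardize_mode: str = "fold",
) -> list[float]:
    """Jackknife MCC under label permutation, one value per replicate.

    Shuffles the pair labels (preserving class counts), reruns the jackknife
    and records the MCC. Values concentrated near 0 indicate the learning
    signal on the unshuffled data is real. Undefined MCCs (single predicted
    class) are recorded as 0: a degenerate constant predictor carries no
    class information, which is the quantity this null measures.
    """
    rng = np.random.default_rng(seed)
    labels = np.array([p.label for p in dataset.pairs], dtype=int)
    out = []
    for _ in range(n_replicates):
        perm = rng.permutation(len(labels))
        shuffled = [
            LabeledPair(p.drug_id, p.protein_id, int(labels[perm[i]]))
            for i, p in enumerate(dataset.pairs)
        ]
        shuffled_ds = Dataset(
            pairs=shuffled,
            proteins=dataset.proteins,
            pssms=dataset.pssms,
            fingerprints=dataset.fingerprints,
            metadata=dataset.metadata,
        )
        metrics, _ = jackknife(
            shuffled_ds, C=C, gamma=gamma, standardize_mode=standardize_mode, seed=0
        )
        out.append(metrics.mcc if metrics.mcc_defined else 0.0)
    return out
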