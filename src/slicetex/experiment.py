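"""Repeated train/test discriminant classification across slice thicknesses.

For one ROI pair, sequence and thickness design (train thickness -> test
thickness), the cohort's (subject, level) keys are randomly partitioned into
train and test halves one hundred times.  Per repetition the three features
with the highest Fisher coefficient *on the training rows* are selected, a
linear or quadratic discriminant is fitted, and accuracy is measured on the
test rows at the test thickness.  The median over repetitions is the
reported accuracy.  No (subject, level) key ever appears on both sides of a
split — asserted at run time on the actual rows, which subsumes the
cross-thickness leakage constraint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .features.names import FEATURE_NAMES
from .discriminant import train_lda, train_nda
from .stats import fisher_rank

__all__ = ["SplitScheme", "ClassificationSummary", "make_splits", "run_design"]

CLASSIFIERS = {"lda": train_lda, "nda": train_nda}


@dataclass(frozen=True)
class SplitScheme:
    repetition: int
    train_keys: tuple
    test_keys: tuple
    train_thickness: str
    test_thickness: str

    def __post_init__(self) -> None:
        if set(self.train_keys) & set(self.test_keys):
            raise ValueError("train and test keys overlap")
        if not self.train_keys or not self.test_keys:
            raise ValueError("train and test sets must both be non-empty")


@dataclass(eq=False)
class ClassificationSummary:
    roi_pair: tuple[str, str]
    sequence: str
    train_thickness: str
    test_thickness: str
    classifier: str
    median_accuracy: float           # percent
    interval: tuple[float, float]    # percentile interval, percent
    accuracies: np.ndarray           # per-repetition accuracies, percent
    feature_tally: Counter
    n_reps: int
    skipped_features: list = field(default_factory=list)


def make_splits(
    keys,
    n_reps: int = 100,
    train_fraction: float = 0.5,
    seed: int = 0,
    train_thickness: str = "1mm",
    test_thickness: str = "1mm",
) -> list[SplitScheme]:
    """n_reps random key-level partitions, deterministic under seed."""
    keys = sorted(set(keys))
    if len(keys) < 4:
        raise ValueError(f"need at least 4 distinct keys, got {len(keys)}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * len(keys)))
    n_train = min(max(n_train, 2), len(keys) - 2)
    rng = default_rng(SeedSequence(seed))
    schemes = []
    for rep in range(1, n_reps + 1):
        perm = rng.permutation(len(keys))
        train = tuple(keys[i] for i in sorted(perm[:n_train]))
        test = tuple(keys[i] for i in sorted(perm[n_train:]))
        schemes.append(
            SplitScheme(
                repetition=rep,
                train_keys=train,
                test_keys=test,
                train_thickness=train_thickness,
                test_thickness=test_thickness,
            )
        )
    return schemes


def _arm_frame(table: pd.DataFrame, sequence: str, thickness: str, kind: str) -> pd.DataFrame:
    sub = table[
        (table["sequence"] == sequence)
        & (table["thickness"] == thickness)
        & (table["roi_kind"] == kind)
    ]
    sub = sub.set_index(["subject", "level"])
    if sub.index.has_duplicates:
        raise ValueError(
            f"multiple rows per (subject, level) for {kind}/{sequence}/{thickness}"
        )
    return sub


def _select_features(ranking, feats_train, feats_test, n_features, skipped):
    """Top-ranked features that are defined in both train and test rows."""
    ordered = sorted(
        (n for n in ranking.f_values.index if not np.isnan(ranking.f_values[n])),
        key=lambda n: (-ranking.f_values[n], n),
    )
    chosen = []
    for name in ordered:
        if feats_train[name].isna().any() or feats_test[name].isna().any():
            skipped.append(name)
            continue
        chosen.append(name)
        if len(chosen) == n_features:
            break
    return chosen


def run_design(
    table: pd.DataFrame,
    roi_pair: tuple[str, str],
    sequence: str,
    train_thickness: str,
    test_thickness: str,
    classifier: str = "lda",
    n_reps: int = 100,
    train_fraction: float = 0.5,
    seed: int = 0,
    interval: tuple[float, float] = (2.5, 97.5),
    n_features: int = 3,
) -> ClassificationSummary:
    """One cell of the accuracy tables: median accuracy over repeated splits."""
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r} (use 'lda' or 'nda')")
    feats = [f for f in FEATURE_NAMES if f in table.columns]
    if not feats:  # non-canonical feature columns: use everything non-metadata
        meta = {"subject", "level", "sequence", "thickness", "roi_kind",
                "roi_pixels", "roi_mu", "roi_sigma"}
        feats = [c for c in table.columns if c not in meta]
    kind_a, kind_b = roi_pair
    arms = {
        (th, kind): _arm_frame(table, sequence, th, kind)
        for th in {train_thickness, test_thickness}
        for kind in roi_pair
    }
    keys = None
    for sub in arms.values():
        keys = sub.index if keys is None else keys.intersection(sub.index)
    keys = sorted(keys)
    splits = make_splits(
        keys,
        n_reps=n_reps,
        train_fraction=train_fraction,
        seed=seed,
        train_thickness=train_thickness,
        test_thickness=test_thickness,
    )
    accuracies = np.empty(n_reps)
    tally: Counter = Counter()
    skipped: list[str] = []
    for i, scheme in enumerate(splits):
        tr_a = arms[(train_thickness, kind_a)].loc[list(scheme.train_keys)]
        tr_b = arms[(train_thickness, kind_b)].loc[list(scheme.train_keys)]
        te_a = arms[(test_thickness, kind_a)].loc[list(scheme.test_keys)]
        te_b = arms[(test_thickness, kind_b)].loc[list(scheme.test_keys)]
        train_keys_seen = set(tr_a.index) | set(tr_b.index)
        test_keys_seen = set(te_a.index) | set(te_b.index)
        if train_keys_seen & test_keys_seen:  # leakage guard on actual rows
            raise AssertionError("(subject, level) key present in both train and test rows")
        x_train = pd.concat([tr_a[feats], tr_b[feats]])
        y_train = np.array([kind_a] * len(tr_a) + [kind_b] * len(tr_b))
        x_test = pd.concat([te_a[feats], te_b[feats]])
        y_test = np.array([kind_a] * len(te_a) + [kind_b] * len(te_b))
        ranking = fisher_rank(x_train, y_train, top_k=n_features)
        chosen = _select_features(ranking, x_train, x_test, n_features, skipped)
        if not chosen:
            raise ValueError("no defined feature available for classification")
        rule = CLASSIFIERS[classifier](x_train[chosen].to_numpy(), y_train)
        pred = rule.predict(x_test[chosen].to_numpy())
        accuracies[i] = 100.0 * float((pred == y_test).mean())
        tally.update(chosen)
    lo, hi = np.percentile(accuracies, interval)
    return ClassificationSummary(
        roi_pair=roi_pair,
        sequence=sequence,
        train_thickness=train_thickness,
        test_thickness=test_thickness,
        classifier=classifier,
        median_accuracy=float(np.median(accuracies)),
        interval=(float(lo), float(hi)),
        accuracies=accuracies,
        feature_tally=tally,
        n_reps=n_reps,
        skipped_features=skipped,
    )
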