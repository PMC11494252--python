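"""Labeled-dataset assembly: activity filter, label attachment, train/test
split and leakage-safe z-score normalization.

The unit of splitting is one (patient, session, game) activity row, so one
patient's activities can land on both sides of the split; a patient-grouped
split is available behind a flag for stricter generalization estimates.
Normalization statistics are fitted on the training partition only and then
applied unchanged to the test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_ORDER

#: ordinal severity coding
CLASS_CODES = {"no": 0, "low": 1, "high": 2}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}

#: default minimum movement count for a row to represent meaningful therapy
MIN_MOVEMENTS = 3

#: columns the models consume, in canonical dictionary order
MODEL_FEATURES = list(FEATURE_ORDER)


def filter_low_activity(rows: pd.DataFrame, min_movements: int = MIN_MOVEMENTS) -> pd.DataFrame:
    """Drop activities with too few movements to be meaningful exercise.

    Keeps exactly the rows with N_mov >= min_movements, preserving order.
    """
    if "N_mov" not in rows.columns:
        raise KeyError("rows must carry an N_mov column")
    return rows[rows["N_mov"] >= min_movements].copy()


def attach_labels(rows: pd.DataFrame, assessments: pd.DataFrame) -> pd.DataFrame:
    """Attach each patient's clinician severity class to their rows.

    ``assessments`` needs ``patient_id`` and ``label`` columns with exactly
    one assessment per patient appearing in ``rows``.  The label is encoded
    ordinally (no=0, low=1, high=2) in a new ``Class`` column.
    """
    counts = assessments["patient_id"].value_counts()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValueError(f"duplicate assessment for patient(s) {sorted(dupes.index)}")
    mapping = dict(zip(assessments["patient_id"], assessments["label"]))
    missing = sorted(set(rows["patient_id"]) - set(mapping))
    if missing:
        raise ValueError(f"missing assessment for patient(s) {missing}")
    bad = sorted({v for v in mapping.values() if v not in CLASS_CODES})
    if bad:
        raise ValueError(f"unknown severity label(s) {bad}")
    out = rows.copy()
    out["Class"] = out["patient_id"].map(mapping).map(CLASS_CODES).astype(int)
    return out


@dataclass
class Normalization:
    """Per-feature z-score parameters fitted on the training partition."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: list[str] = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return list(self.mean.index)


def fit_normalizer(train_rows: pd.DataFrame, features: list[str] | None = None) -> Normalization:
    """Fit per-feature mean/SD on the training rows only.

    Zero-variance features get SD 1 so their transform maps to 0.
    """
    if len(train_rows) == 0:
        raise ValueError("cannot fit a normalizer on an empty training set")
    feats = list(features) if features is not None else MODEL_FEATURES
    x = train_rows[feats].astype(float)
    mean = x.mean()
    sd = x.std(ddof=0)
    zero_var = list(sd.index[sd == 0.0])
    sd = sd.mask(sd == 0.0, 1.0)
    return Normalization(mean=mean, sd=sd, zero_variance=zero_var)


def apply_normalizer(norm: Normalization, rows: pd.DataFrame) -> pd.DataFrame:
    """z = (x − mean_train) / SD_train, feature-wise; other columns pass through."""
    out = rows.copy()
    feats = norm.features
    out[feats] = (rows[feats].astype(float) - norm.mean) / norm.sd
    return out


@dataclass
class SplitDataset:
    """Train/test partition plus the train-fitted normalizer."""

    train: pd.DataFrame
    test: pd.DataFrame
    normalization: Normalization
    split_meta: dict

    @property
    def train_normalized(self) -> pd.DataFrame:
        return apply_normalizer(self.normalization, self.train)

    @property
    def test_normalized(self) -> pd.DataFrame:
        return apply_normalizer(self.normalization, self.test)


def _stratified_train_counts(labels: np.ndarray, n_train: int) -> dict:
    """Largest-remainder apportionment of n_train across classes."""
    values, counts = np.unique(labels, return_counts=True)
    target = counts * n_train / counts.sum()
    base = np.floor(target).astype(int)
    rem = n_train - base.sum()
    order = np.argsort(-(target - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(values, base))


def split_dataset(
    rows: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
    group_by_patient: bool = False,
    features: list[str] | None = None,
) -> SplitDataset:
    """Random train/test split with a train-fitted z-score normalizer.

    |train| = round(fraction × n); when stratified, each class's training
    share is within one row of the fraction.  ``group_by_patient`` instead
    assigns whole patients to a side (approximate fraction).  The split is
    reproducible from the seed.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    n = len(rows)
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))

    if group_by_patient:
        patients = rows["patient_id"].unique()
        patients = rng.permutation(patients)
        take = max(1, int(round(train_fraction * len(patients)))) if n else 0
        train_pat = set(patients[:take])
        in_train = rows["patient_id"].isin(train_pat).to_numpy()
        train_idx = np.where(in_train)[0]
        test_idx = np.where(~in_train)[0]
    elif stratified and "Class" in rows.columns and n > 0:
        labels = rows["Class"].to_numpy()
        per_class = _stratified_train_counts(labels, n_train)
        train_mask = np.zeros(n, dtype=bool)
        for cls, k in per_class.items():
            idx = np.where(labels == cls)[0]
            chosen = rng.permutation(idx)[:k]
            train_mask[chosen] = True
        train_idx = np.where(train_mask)[0]
        test_idx = np.where(~train_mask)[0]
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])

    train = rows.iloc[np.sort(train_idx)].copy()
    test = rows.iloc[np.sort(test_idx)].copy()
    norm = fit_normalizer(train, features=features)
    meta = {
        "train_fraction": train_fraction,
        "seed": seed,
        "stratified": bool(stratified),
        "group_by_patient": bool(group_by_patient),
        "n_train": len(train),
        "n_test": len(test),
    }
    return SplitDataset(train=train, test=test, normalization=norm, split_meta=meta)
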