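"""Feature-redundancy and dimensionality diagnostics on the training set.

Pearson correlation matrix with a |r| > 0.9 exclusion rule (strict
inequality, so a pair at exactly 0.9 is retained), plus the PCA
explained-variance profile.  The flexion/extension force pair ships as a
default keep-override: those two features are strongly anti-correlated yet
both clinically informative, since recovery of downward and upward pushing
strength can progress independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataset import MODEL_FEATURES

#: correlation magnitude above which one of a feature pair is dropped
CORRELATION_THRESHOLD = 0.9

#: pairs flagged by the threshold that are nevertheless kept, with reason
DEFAULT_KEEP_OVERRIDES = {
    frozenset(("F_flex", "F_ext")): (
        "flexion and extension strength recover independently in neuromotor "
        "rehabilitation; both retained despite strong anti-correlation"
    ),
}


@dataclass
class CorrelationReport:
    features: list[str]
    matrix: pd.DataFrame  # symmetric, unit diagonal
    zero_variance: list[str] = field(default_factory=list)
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    kept_overrides: list[tuple[str, str, float, str]] = field(default_factory=list)


def correlation_matrix(rows: pd.DataFrame, features: list[str] | None = None) -> CorrelationReport:
    """Pearson correlation matrix over the feature columns.

    Zero-variance features have undefined correlations; those entries are
    reported as 0 and the feature is flagged.  The diagonal is exactly 1.
    """
    feats = list(features) if features is not None else [
        f for f in MODEL_FEATURES if f in rows.columns
    ]
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    x = rows[feats].astype(float)
    sd = x.std(ddof=0)
    zero_var = list(sd.index[sd == 0.0])
    mat = x.corr(method="pearson")
    mat = mat.fillna(0.0)
    np.fill_diagonal(mat.values, 1.0)
    return CorrelationReport(features=feats, matrix=mat, zero_variance=zero_var)


def redundancy_filter(
    report: CorrelationReport,
    threshold: float = CORRELATION_THRESHOLD,
    keep_overrides: dict | None = None,
) -> list[str]:
    """Drop one member of every pair with |r| strictly above the threshold.

    Pairs are visited in canonical feature order and the later feature of a
    pair is the one dropped (deterministic tie-break); pairs where one
    member is already dropped are skipped.  Overridden pairs are recorded
    as kept with their reason.  Results are stored on the report and the
    dropped list returned.
    """
    overrides = DEFAULT_KEEP_OVERRIDES if keep_overrides is None else keep_overrides
    feats = report.features
    mat = report.matrix
    flagged: list[tuple[str, str, float]] = []
    dropped: list[str] = []
    kept: list[tuple[str, str, float, str]] = []
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            r = float(mat.loc[a, b])
            if abs(r) > threshold:
                flagged.append((a, b, r))
                key = frozenset((a, b))
                if key in overrides:
                    kept.append((a, b, r, overrides[key]))
                elif a not in dropped and b not in dropped:
                    dropped.append(b)
    report.flagged_pairs = flagged
    report.dropped = dropped
    report.kept_overrides = kept
    return dropped


def pca_explained_variance(rows, features: list[str] | None = None) -> np.ndarray:
    """Explained-variance ratios of all principal components.

    Expects z-scored input rows; ratios are nonnegative, nonincreasing and
    sum to 1.
    """
    if isinstance(rows, pd.DataFrame):
        feats = list(features) if features is not None else [
            f for f in MODEL_FEATURES if f in rows.columns
        ]
        x = rows[feats].to_numpy(dtype=float)
    else:
        x = np.asarray(rows, dtype=float)
    if x.ndim != 2 or x.shape[0] <= 1:
        raise ValueError("need a 2-D array with more than one row")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more rows than features for a full PCA")
    return PCA().fit(x).explained_variance_ratio_
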