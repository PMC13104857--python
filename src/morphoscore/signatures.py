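"""Derivation of on-/off-morphology signatures from two control populations.

Given a reference state (e.g. diseased cells under vehicle control) and a
target state (e.g. healthy cells), each morphology feature is tested with a
two-sample KS test and the p-values are FDR-corrected (Benjamini-Hochberg)
across the full feature space in a single family.  Features whose corrected
p-value falls below alpha form the on-morphology signature — the axis along
which a successful perturbation must move cells; the remainder form the
off-morphology signature, where perturbation-induced change indicates
off-target activity.

Also provides the two negative-control transforms used in evaluation:
column-wise permutation of feature values (destroys covariance while
preserving per-feature marginals and all labels) and random reassignment of
features between the two signatures at fixed sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import ProfileTable
from .stats import bh_adjust, ks_two_sample

logger = logging.getLogger(__name__)

__all__ = ["SignatureResult", "derive_signatures", "shuffle_feature_assignment", "shuffle_feature_values"]


@dataclass
class SignatureResult:
    """Per-feature test results and the disjoint on/off feature partition."""

    per_feature: pd.DataFrame  # columns: feature, ks_statistic, p_value, p_adjusted
    on_features: list[str]
    off_features: list[str]
    alpha: float
    reference_n: int
    target_n: int

    def __post_init__(self):
        tested = set(self.per_feature["feature"])
        on, off = set(self.on_features), set(self.off_features)
        if on & off:
            raise ValueError(f"on/off signatures overlap: {sorted(on & off)}")
        if on | off != tested:
            raise ValueError("on/off partition does not cover the tested features")

    @property
    def n_features(self) -> int:
        return len(self.per_feature)

    def save(self, directory: str | Path) -> None:
        """Write the per-feature table (CSV) and a JSON sidecar with the partition."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_feature.to_csv(directory / "per_feature.csv", index=False)
        sidecar = {
            "alpha": self.alpha,
            "reference_n": self.reference_n,
            "target_n": self.target_n,
            "on_features": list(self.on_features),
            "off_features": list(self.off_features),
        }
        (directory / "signature.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SignatureResult":
        directory = Path(directory)
        per_feature = pd.read_csv(directory / "per_feature.csv")
        sidecar = json.loads((directory / "signature.json").read_text())
        return cls(
            per_feature=per_feature,
            on_features=list(sidecar["on_features"]),
            off_features=list(sidecar["off_features"]),
            alpha=float(sidecar["alpha"]),
            reference_n=int(sidecar["reference_n"]),
            target_n=int(sidecar["target_n"]),
        )


def derive_signatures(
    reference: ProfileTable,
    target: ProfileTable,
    alpha: float = 0.05,
    min_cells: int = 2,
    ks_method: str = "asymp",
) -> SignatureResult:
    """Partition the feature space into on- and off-morphology signatures.

    Runs a two-sample KS test per feature between the reference and target
    populations, BH-corrects over all features jointly, and assigns features
    with corrected p < alpha to the on-signature, the rest to the
    off-signature.  Deterministic for fixed inputs and invariant to row
    order of either population.

    Constant features (zero spread in both populations) are degenerate for
    the KS test; they receive statistic 0 and p = 1 — hence land in the
    off-signature — with a logged warning.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    ref_feats, tgt_feats = reference.feature_columns, target.feature_columns
    if set(ref_feats) != set(tgt_feats):
        missing = sorted(set(ref_feats) ^ set(tgt_feats))
        raise ValueError(f"feature schema mismatch between populations: {missing}")
    if reference.n_cells < min_cells or target.n_cells < min_cells:
        raise ValueError(
            f"population below minimum size {min_cells}: "
            f"reference={reference.n_cells}, target={target.n_cells}"
        )

    features = ref_feats  # reference order defines output order
    stats_, pvals = [], []
    n_constant = 0
    for feat in features:
        x = reference.data[feat].to_numpy(dtype=float)
        y = target.data[feat].to_numpy(dtype=float)
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            n_constant += 1
            stats_.append(0.0)
            pvals.append(1.0)
            continue
        res = ks_two_sample(x, y, method=ks_method)
        stats_.append(res.statistic)
        pvals.append(res.p_value)
    if n_constant:
        logger.warning("%d constant feature(s) assigned to the off-signature", n_constant)

    adjusted, reject = bh_adjust(pvals, alpha=alpha)
    per_feature = pd.DataFrame(
        {
            "feature": features,
            "ks_statistic": stats_,
            "p_value": pvals,
            "p_adjusted": adjusted,
        }
    )
    on = [f for f, r in zip(features, reject) if r]
    off = [f for f, r in zip(features, reject) if not r]
    return SignatureResult(
        per_feature=per_feature,
        on_features=on,
        off_features=off,
        alpha=alpha,
        reference_n=reference.n_cells,
        target_n=target.n_cells,
    )


def shuffle_feature_assignment(signature: SignatureResult, seed: int) -> SignatureResult:
    """Randomly reassign features between the signatures, preserving sizes.

    A negative control: membership of the on- and off-signatures is redrawn
    uniformly at random (under ``seed``) while |on| and |off| — and all
    per-feature statistics — are kept unchanged.
    """
    n_on = len(signature.on_features)
    all_features = list(signature.per_feature["feature"])
    if n_on == 0 or len(signature.off_features) == 0:
        return signature
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(all_features))
    on = [all_features[i] for i in sorted(perm[:n_on])]
    off = [all_features[i] for i in sorted(perm[n_on:])]
    return replace(signature, on_features=on, off_features=off)


def shuffle_feature_values(table: ProfileTable, seed: int) -> ProfileTable:
    """Permute each feature column independently across rows.

    Destroys cross-feature covariance while preserving every per-column
    multiset of values and all metadata (labels, wells, plates untouched).
    """
    if table.n_cells == 0:
        raise ValueError("cannot shuffle an empty table")
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    n = len(df)
    for col in table.feature_columns:
        df[col] = df[col].to_numpy()[rng.permutation(n)]
    return ProfileTable(df, validate=False)
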