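"""The 12-member heterogeneous voting ensemble, statsmodels-style.

:class:`HairpinVoteClassifier` is the model object: it is built from a
labeled feature table (one row per hairpin, columns from the feature
registry) and a configuration (base-classifier specs, rebalancing, selected
features).  ``fit()`` runs modified-SMOTEbagging and trains one SVM, one
kNN and one random forest per balanced subset — 3 algorithms × 4 subsets =
12 members under the defaults — and returns a
:class:`VoteEnsembleResults` carrying the fitted members, scaling and
selection metadata, prediction methods, a ``summary()`` table and archive
round-tripping.

Prediction is by hard majority vote: the reported "probability" of a
candidate is the fraction of members voting positive (multiples of 1/12),
and the label is positive iff that fraction exceeds 0.5 (an exact tie is
called negative, favoring a low false-positive rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import CATALOG_VERSION, resolve_feature_name
from .rebalance import RebalanceConfig, SubsetBundle, build_subsets
from .selection import DEFAULT_SELECTED_FEATURES

_ALGORITHMS = ("svm", "knn", "rf")

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class BaseClassifierSpec:
    """One base-classifier family and its hyperparameters."""

    algorithm: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}")

    def build(self, seed: int):
        p = dict(self.params)
        if self.algorithm == "svm":
            return SVC(kernel="rbf", C=p.get("C", 1.0), gamma=p.get("gamma", "auto"))
        if self.algorithm == "knn":
            return KNeighborsClassifier(n_neighbors=p.get("k", 5))
        return RandomForestClassifier(
            n_estimators=p.get("n_trees", 100), random_state=seed
        )


def default_specs() -> tuple[BaseClassifierSpec, ...]:
    """SVM (RBF, C=1, gamma=1/d), kNN (k=5), RF (100 trees)."""
    return (
        BaseClassifierSpec("svm"),
        BaseClassifierSpec("knn"),
        BaseClassifierSpec("rf"),
    )


@dataclass(frozen=True)
class EnsembleMember:
    algorithm: str
    subset_index: int
    neg_source: str
    estimator: object


@dataclass(frozen=True)
class Prediction:
    """One candidate's vote outcome."""

    votes: tuple[int, ...]
    vote_fraction: float
    label: int

    @classmethod
    def from_votes(cls, votes: Sequence[int]) -> "Prediction":
        votes = tuple(int(v) for v in votes)
        frac = sum(votes) / len(votes)
        return cls(votes=votes, vote_fraction=frac, label=POSITIVE if frac > 0.5 else NEGATIVE)


def train_members(
    bundle: SubsetBundle,
    specs: Sequence[BaseClassifierSpec] = (),
    seed: int = 0,
) -> tuple[EnsembleMember, ...]:
    """Fit every (algorithm, subset) pair of the product grid.

    Feature matrices in the bundle are expected already standardized; the
    caller owns the scaler.  Raises on a degenerate (single-class) subset.
    """
    specs = tuple(specs) or default_specs()
    members = []
    rng = np.random.default_rng(seed)
    for s_idx, sub in enumerate(bundle.subsets):
        if len(sub.X_pos) == 0 or len(sub.X_neg) == 0:
            raise ValueError(f"subset {s_idx} ({sub.neg_source}) is single-class")
        X = np.vstack([sub.X_pos, sub.X_neg])
        y = np.concatenate(
            [np.full(len(sub.X_pos), POSITIVE), np.full(len(sub.X_neg), NEGATIVE)]
        )
        for spec in specs:
            est = spec.build(seed=int(rng.integers(2**31)))
            est.fit(X, y)
            members.append(
                EnsembleMember(
                    algorithm=spec.algorithm,
                    subset_index=s_idx,
                    neg_source=sub.neg_source,
                    estimator=est,
                )
            )
    return tuple(members)


class HairpinVoteClassifier:
    """Heterogeneous voting-ensemble model for pre-miRNA hairpins.

    Parameters
    ----------
    features
        Feature table, rows = hairpins, columns = feature names (registry
        spellings or their common variants).
    labels
        Binary labels (1 = pre-miRNA, 0 = negative), aligned with rows.
    neg_tags
        Per-row negative-source tags ('ncrna' / 'pseudo'); positives may
        carry anything.  When absent, both negative pools fall back to the
        full negative set (warned at fit time via the manifest).
    selected_features
        Feature subset used by every member; defaults to the shipped
        20-feature CFS+GA selection when those columns are present,
        otherwise to all columns.
    rebalance
        Modified-SMOTEbagging configuration, or ``None`` to train the three
        algorithms once on the raw (possibly imbalanced) table — the
        'imbalanced ensemble' baseline.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[int],
        neg_tags: Optional[Sequence[str]] = None,
        selected_features: Optional[Sequence[str]] = None,
        specs: Sequence[BaseClassifierSpec] = (),
        rebalance: Optional[RebalanceConfig] = RebalanceConfig(),
        seed: int = 0,
    ) -> None:
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        self.neg_tags = None if neg_tags is None else np.asarray(neg_tags, dtype=object)
        if selected_features is None:
            canonical = {}
            for c in features.columns:
                try:
                    canonical[resolve_feature_name(str(c))] = c
                except KeyError:
                    pass
            if all(n in canonical for n in DEFAULT_SELECTED_FEATURES):
                selected_features = DEFAULT_SELECTED_FEATURES
            else:
                selected_features = tuple(str(c) for c in features.columns)
        self.selected_features = tuple(str(c) for c in selected_features)
        self.specs = tuple(specs) or default_specs()
        self.rebalance = rebalance
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_col: str = "label",
        tag_col: Optional[str] = "tag",
        **kwargs,
    ) -> "HairpinVoteClassifier":
        """Build from a single table holding features plus a label column
        (and optionally a negative-source tag column)."""
        labels = frame[label_col].to_numpy()
        if labels.dtype.kind in "OU":
            labels = (labels == "positive").astype(int)
        drop = [label_col]
        tags = None
        if tag_col is not None and tag_col in frame.columns:
            tags = frame[tag_col].to_numpy()
            drop.append(tag_col)
        return cls(frame.drop(columns=drop), labels, neg_tags=tags, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _selected_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        cols = []
        lookup = {}
        for c in frame.columns:
            try:
                lookup[resolve_feature_name(str(c))] = c
            except KeyError:
                lookup[str(c)] = c
        for name in self.selected_features:
            try:
                canon = resolve_feature_name(name)
            except KeyError:
                canon = name
            if canon not in lookup:
                raise KeyError(f"missing feature {name!r} in table")
            cols.append(lookup[canon])
        return frame[cols].to_numpy(dtype=float)

    def fit(self) -> "VoteEnsembleResults":
        rng = np.random.default_rng(self.seed)
        X = self._selected_matrix(self.features)
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        pos = Xs[self.labels == POSITIVE]
        neg = Xs[self.labels == NEGATIVE]
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("training data must contain both classes")

        if self.rebalance is None:
            bundle = None
            members = self._fit_imbalanced(pos, neg, rng)
        else:
            if self.neg_tags is not None:
                tags = self.neg_tags[self.labels == NEGATIVE]
                neg_ncrna = neg[tags == "ncrna"]
                neg_pseudo = neg[tags == "pseudo"]
            else:
                neg_ncrna = neg_pseudo = neg
            if len(neg_ncrna) == 0:
                neg_ncrna = neg
            if len(neg_pseudo) == 0:
                neg_pseudo = neg
            bundle = build_subsets(pos, neg_ncrna, neg_pseudo, self.rebalance, rng)
            members = train_members(bundle, self.specs, seed=int(rng.integers(2**31)))

        manifest = {
            "catalog_version": CATALOG_VERSION,
            "n_members": len(members),
            "algorithms": [s.algorithm for s in self.specs],
            "n_subsets": len(bundle) if bundle is not None else 1,
            "selected_features": list(self.selected_features),
            "rebalance": None
            if self.rebalance is None
            else {
                "smote_rate": self.rebalance.smote_rate,
                "k_neighbors": self.rebalance.k_neighbors,
                "n_pseudo_subsets": self.rebalance.n_pseudo_subsets,
            },
            "seed": self.seed,
            "n_train": len(self.features),
            "n_positive": int((self.labels == POSITIVE).sum()),
        }
        return VoteEnsembleResults(
            model=self, members=members, scaler=scaler, manifest=manifest
        )

    def _fit_imbalanced(self, pos, neg, rng) -> tuple[EnsembleMember, ...]:
        X = np.vstack([pos, neg])
        y = np.concatenate([np.full(len(pos), POSITIVE), np.full(len(neg), NEGATIVE)])
        members = []
        for spec in self.specs:
            est = spec.build(seed=int(rng.integers(2**31)))
            est.fit(X, y)
            members.append(
                EnsembleMember(
                    algorithm=spec.algorithm, subset_index=0, neg_source="all",
                    estimator=est,
                )
            )
        return tuple(members)


class VoteEnsembleResults:
    """Fitted ensemble: members, scaling, metadata, prediction and I/O."""

    def __init__(
        self,
        model: Optional[HairpinVoteClassifier],
        members: Sequence[EnsembleMember],
        scaler: StandardScaler,
        manifest: Mapping,
    ) -> None:
        self.model = model
        self.members = tuple(members)
        self.scaler = scaler
        self.manifest = dict(manifest)

    @property
    def selected_features(self) -> tuple[str, ...]:
        return tuple(self.manifest["selected_features"])

    # -- prediction ---------------------------------------------------------

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        lookup = {}
        for c in features.columns:
            try:
                lookup[resolve_feature_name(str(c))] = c
            except KeyError:
                lookup[str(c)] = c
        cols = []
        for name in self.selected_features:
            try:
                canon = resolve_feature_name(name)
            except KeyError:
                canon = name
            if canon not in lookup:
                raise KeyError(f"prediction input is missing feature {name!r}")
            cols.append(lookup[canon])
        return self.scaler.transform(features[cols].to_numpy(dtype=float))

    def member_votes(self, features: pd.DataFrame) -> np.ndarray:
        """(n_samples, n_members) hard votes."""
        X = self._matrix(features)
        votes = np.column_stack(
            [m.estimator.predict(X) for m in self.members]
        ).astype(int)
        return votes

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Vote fraction and label per row.

        Returns a DataFrame with columns ``vote_fraction`` (multiples of
        1/n_members), ``label`` (1 positive / 0 negative; a tie at exactly
        0.5 is negative) and one ``vote_<algorithm><subset>`` column per
        member.
        """
        votes = self.member_votes(features)
        frac = votes.mean(axis=1)
        out = pd.DataFrame(
            {
                "vote_fraction": frac,
                "label": (frac > 0.5).astype(int),
            },
            index=features.index,
        )
        for k, m in enumerate(self.members):
            out[f"vote_{m.algorithm}{m.subset_index}"] = votes[:, k]
        return out

    def predict_one(self, vector: pd.Series | Mapping[str, float]) -> Prediction:
        frame = pd.DataFrame([dict(vector)])
        votes = self.member_votes(frame)[0]
        return Prediction.from_votes(votes)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Heterogeneous voting ensemble (pre-miRNA hairpin classifier)",
            "=" * 60,
            f"members:            {len(self.members)}"
            f" ({' + '.join(self.manifest['algorithms'])} x {self.manifest['n_subsets']} subsets)",
            f"selected features:  {len(self.selected_features)}",
            f"training rows:      {self.manifest['n_train']}"
            f" ({self.manifest['n_positive']} positive)",
            f"rebalancing:        {self.manifest['rebalance']}",
            f"seed:               {self.manifest['seed']}",
            "-" * 60,
        ]
        for m in self.members:
            lines.append(
                f"  member {m.algorithm:>4s}  subset {m.subset_index}  vs {m.neg_source}"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Archive manifest + members + scaler (joblib)."""
        joblib.dump(
            {"manifest": self.manifest, "members": self.members, "scaler": self.scaler},
            path,
            compress=3,
        )

    @classmethod
    def load(cls, path) -> "VoteEnsembleResults":
        try:
            payload = joblib.load(path)
            manifest = payload["manifest"]
            members = payload["members"]
            scaler = payload["scaler"]
        except Exception as exc:
            raise IOError(f"corrupt or unreadable model archive: {path}") from exc
        if manifest.get("catalog_version") != CATALOG_VERSION:
            raise IOError(
                f"model archive catalog version {manifest.get('catalog_version')!r} "
                f"does not match installed catalog {CATALOG_VERSION!r}"
            )
        return cls(model=None, members=members, scaler=scaler, manifest=manifest)
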