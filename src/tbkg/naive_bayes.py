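"""Bernoulli naive-Bayes relation model and the importance measure.

For a fixed target entity :math:`y_j` (say a tumor) and candidate
feature entities :math:`x_i` of one node type (say biomarkers), the
model treats each document as an independent draw of binary indicators
and estimates, by (optionally Laplace-smoothed) maximum likelihood,

.. math::

    \\hat p(x_i = 1 \\mid y_j = v) =
        \\frac{\\#\\{x_i = 1, y_j = v\\} + \\alpha}
             {\\#\\{y_j = v\\} + 2\\alpha}, \\qquad v \\in \\{0, 1\\}.

The strength of the candidate relation is the importance measure

.. math::

    \\mathrm{IMP}(x_i, y_j) = \\log_2 p(x_i=1 \\mid y_j=1)
                            - \\log_2 p(x_i=1 \\mid y_j=0),

a base-2 log ratio: importance 1 means the feature is twice as likely
to be mentioned when the target is present.  Pairs whose importance
exceeds a threshold become weighted edges of the knowledge graph.

The module follows the model/results convention: build
:class:`EntityRelationNB` from a document-entity matrix, call
:meth:`~EntityRelationNB.fit`, and read estimates off the returned
:class:`EntityRelationNBResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import DocEntityMatrix, NODE_TYPES
from .exceptions import (
    ConfigurationError,
    DegenerateTargetError,
    UndefinedImportanceError,
)


def importance_value(p_present: float, p_absent: float) -> float:
    """The base-2 log-ratio importance of a feature for a target.

    Raises :class:`UndefinedImportanceError` when either conditional is
    zero (possible only in unsmoothed fits).
    """
    if p_present <= 0.0 or p_absent <= 0.0:
        raise UndefinedImportanceError(
            f"importance undefined for p_present={p_present}, p_absent={p_absent}; "
            "use a positive smoothing pseudo-count"
        )
    return math.log2(p_present) - math.log2(p_absent)


@dataclass(frozen=True)
class ImportanceScore:
    """A scored candidate relation between a target and a feature entity."""

    target_id: str
    target_type: str
    feature_id: str
    feature_type: str
    value: float
    p_present: float
    p_absent: float


class EntityRelationNB:
    """Bernoulli naive-Bayes model of one target entity against all
    features of one node type.

    Parameters
    ----------
    matrix
        Binary document-entity incidence matrix.
    target
        Concept id of the target entity (the :math:`y_j`).
    feature_type
        Node type of the candidate features (the :math:`x_i`); must
        differ from the target's type.
    alpha
        Laplace pseudo-count.  ``alpha=0`` is the pure maximum-likelihood
        fit and may yield zero conditionals, for which importance is
        undefined.
    """

    def __init__(
        self,
        matrix: DocEntityMatrix,
        target: str,
        feature_type: str,
        alpha: float = 1.0,
    ):
        if feature_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {feature_type!r}")
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.matrix = matrix
        self.target = target
        self.target_type = str(
            matrix.entities.loc[matrix.column_index(target), "node_type"]
        )
        if self.target_type == feature_type:
            raise ValueError(
                f"feature_type {feature_type!r} equals the target's own type; "
                "relations connect distinct types"
            )
        self.feature_type = feature_type
        self.alpha = float(alpha)
        feats = matrix.columns_of_type(feature_type)
        if len(feats) == 0:
            raise ValueError(f"matrix has no {feature_type!r} columns")
        self._feature_index = feats.index.to_numpy()
        self.feature_ids = list(feats["concept_id"])

    def fit(self) -> "EntityRelationNBResults":
        """Estimate the prior and per-feature conditionals by counting."""
        y = self.matrix.column(self.target)
        n = y.size
        n1 = int(y.sum())
        if n1 == 0:
            raise DegenerateTargetError(
                f"target {self.target!r} has zero positive documents"
            )
        n0 = n - n1
        Xf = self.matrix.X[:, self._feature_index]
        c1 = np.asarray(Xf[y, :].sum(axis=0)).ravel().astype(float)
        c0 = np.asarray(Xf[~y, :].sum(axis=0)).ravel().astype(float)
        a = self.alpha
        p1 = (c1 + a) / (n1 + 2 * a)
        with np.errstate(divide="ignore", invalid="ignore"):
            p0 = (c0 + a) / (n0 + 2 * a) if (n0 + 2 * a) > 0 else np.full_like(c0, np.nan)
        params = pd.DataFrame(
            {"p_present": p1, "p_absent": p0},
            index=pd.Index(self.feature_ids, name="concept_id"),
        )
        return EntityRelationNBResults(self, prior=n1 / n, params=params, counts=(n1, n0))


class EntityRelationNBResults:
    """Fitted conditionals, prior, importance scores and prediction."""

    def __init__(
        self,
        model: EntityRelationNB,
        prior: float,
        params: pd.DataFrame,
        counts: tuple[int, int],
    ):
        self.model = model
        self.prior = prior
        self.params = params
        self.n_present, self.n_absent = counts

    def importance(self, feature: str) -> ImportanceScore:
        """Importance score of one fitted feature."""
        row = self.params.loc[feature]
        return ImportanceScore(
            target_id=self.model.target,
            target_type=self.model.target_type,
            feature_id=feature,
            feature_type=self.model.feature_type,
            value=importance_value(float(row["p_present"]), float(row["p_absent"])),
            p_present=float(row["p_present"]),
            p_absent=float(row["p_absent"]),
        )

    def importance_table(self) -> pd.DataFrame:
        """All features' importances, descending (ties by concept id)."""
        tbl = self.params.copy()
        if (tbl[["p_present", "p_absent"]] <= 0).to_numpy().any():
            raise UndefinedImportanceError(
                "zero conditional probability in unsmoothed fit"
            )
        tbl["importance"] = np.log2(tbl["p_present"]) - np.log2(tbl["p_absent"])
        return tbl.sort_values(
            ["importance", "concept_id"], ascending=[False, True],
            kind="mergesort",
        )

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        """Predict target presence per document by posterior odds > 1.

        ``X`` is a dense 0/1 array over this model's feature columns (in
        ``model.feature_ids`` order); by default the training matrix's
        feature block is used.  Ties at odds exactly 1 predict 0.
        """
        if X is None:
            X = np.asarray(
                self.model.matrix.X[:, self.model._feature_index].todense()
            )
        X = np.asarray(X, dtype=float)
        p1 = self.params["p_present"].to_numpy()
        p0 = self.params["p_absent"].to_numpy()
        if self.prior <= 0:
            return np.zeros(X.shape[0], dtype=bool)
        if self.prior >= 1:
            return np.ones(X.shape[0], dtype=bool)
        with np.errstate(divide="ignore"):
            w_on = np.log(p1) - np.log(p0)
            w_off = np.log1p(-p1) - np.log1p(-p0)
            log_odds = (
                math.log(self.prior) - math.log1p(-self.prior)
                + X @ w_on + (1.0 - X) @ w_off
            )
        return log_odds > 0.0

    def summary(self, top: int = 10) -> str:
        """Readable fit summary: prior, counts, strongest features."""
        tbl = self.importance_table().head(top)
        lines = [
            "Bernoulli naive-Bayes relation model",
            "=" * 52,
            f"target:        {self.model.target} ({self.model.target_type})",
            f"feature type:  {self.model.feature_type}"
            f"   features: {len(self.params)}",
            f"documents:     {self.n_present + self.n_absent}"
            f"   target present: {self.n_present}",
            f"prior p(y=1):  {self.prior:.4f}   alpha: {self.model.alpha:g}",
            "-" * 52,
            f"{'feature':<20}{'importance':>12}{'p(x|y=1)':>10}{'p(x|y=0)':>10}",
        ]
        for cid, row in tbl.iterrows():
            lines.append(
                f"{cid:<20}{row['importance']:>12.3f}"
                f"{row['p_present']:>10.4f}{row['p_absent']:>10.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# convenience functions over many targets


def fit_nb(
    matrix: DocEntityMatrix, target: str, feature_type: str, alpha: float = 1.0
) -> EntityRelationNBResults:
    """Fit one target's naive-Bayes model (shorthand for the model class)."""
    return EntityRelationNB(matrix, target, feature_type, alpha=alpha).fit()


def discover_relations(
    matrix: DocEntityMatrix,
    type_pair: tuple[str, str],
    threshold: float = 1.0,
    alpha: float = 1.0,
) -> list[ImportanceScore]:
    """Score every (target, feature) pair of a type pair; keep those with
    importance strictly above *threshold*.

    One model is fitted per target entity of ``type_pair[0]``; targets
    with zero positive documents are skipped with a warning.  Output is
    ordered by score descending, ties broken by concept ids.
    """
    target_type, feature_type = type_pair
    targets = matrix.columns_of_type(target_type)
    if len(targets) == 0 or len(matrix.columns_of_type(feature_type)) == 0:
        raise ValueError(f"matrix lacks columns for type pair {type_pair!r}")
    scores: list[ImportanceScore] = []
    for cid in targets["concept_id"]:
        try:
            res = fit_nb(matrix, cid, feature_type, alpha=alpha)
        except DegenerateTargetError:
            warnings.warn(f"skipping degenerate target {cid!r} (no positive documents)")
            continue
        tbl = res.importance_table()
        for fid, row in tbl.iterrows():
            if row["importance"] > threshold:
                scores.append(
                    ImportanceScore(
                        target_id=cid,
                        target_type=target_type,
                        feature_id=str(fid),
                        feature_type=feature_type,
                        value=float(row["importance"]),
                        p_present=float(row["p_present"]),
                        p_absent=float(row["p_absent"]),
                    )
                )
    scores.sort(key=lambda s: (-s.value, s.target_id, s.feature_id))
    return scores


def relations_to_frame(scores: Sequence[ImportanceScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.target_id, s.target_type, s.feature_id, s.feature_type,
             s.value, s.p_present, s.p_absent)
            for s in scores
        ],
        columns=["target_id", "target_type", "feature_id", "feature_type",
                 "importance", "p_present", "p_absent"],
    )


def cross_validate(
    matrix: DocEntityMatrix,
    target_type: str,
    feature_type: str,
    k: int = 3,
    alpha: float = 1.0,
    seed: int | None = None,
) -> float:
    """Mean k-fold classification accuracy of the naive-Bayes models.

    For each target entity of *target_type*, documents are split into
    *k* random folds; the classifier (predict present iff posterior odds
    exceed 1) is trained on k-1 folds and tested on the held-out fold.
    The returned accuracy is averaged over folds, then over targets.

    Folds are assigned by permuting the sorted document-id list, so the
    result does not depend on row order, only on the seed.
    """
    if k < 2:
        raise ConfigurationError("cross-validation needs k >= 2 folds")
    n = matrix.n_docs
    if k > n:
        raise ConfigurationError(f"k={k} folds but only {n} documents")
    rng = np.random.default_rng(seed)
    sorted_ids = sorted(matrix.doc_ids)
    perm = rng.permutation(len(sorted_ids))
    fold_of_doc = {sorted_ids[int(p)]: f for f, chunk in
                   enumerate(np.array_split(np.arange(n), k))
                   for p in perm[chunk]}
    fold = np.array([fold_of_doc[d] for d in matrix.doc_ids])
    if any((fold == f).sum() == 0 for f in range(k)):  # pragma: no cover
        raise ConfigurationError("a fold has zero test documents")

    targets = matrix.columns_of_type(target_type)
    feats = matrix.columns_of_type(feature_type)
    if len(targets) == 0 or len(feats) == 0:
        raise ValueError("both types must be present in the matrix")
    Xf = np.asarray(matrix.X[:, feats.index.to_numpy()].todense(), dtype=float)

    target_accs: list[float] = []
    for cid in targets["concept_id"]:
        y = matrix.column(cid)
        fold_accs: list[float] = []
        for f in range(k):
            test = fold == f
            train = ~test
            ytr = y[train]
            n1 = int(ytr.sum())
            n0 = int(train.sum()) - n1
            if n1 == 0 or n0 == 0:
                # degenerate training fold: constant prediction
                pred = np.full(int(test.sum()), n1 > 0)
            else:
                c1 = Xf[train][ytr].sum(axis=0)
                c0 = Xf[train][~ytr].sum(axis=0)
                a = alpha if alpha > 0 else 1e-12  # guard log(0) in CV
                p1 = (c1 + a) / (n1 + 2 * a)
                p0 = (c0 + a) / (n0 + 2 * a)
                prior = n1 / (n1 + n0)
                w_on = np.log(p1) - np.log(p0)
                w_off = np.log1p(-p1) - np.log1p(-p0)
                log_odds = (
                    math.log(prior) - math.log1p(-prior)
                    + Xf[test] @ w_on + (1.0 - Xf[test]) @ w_off
                )
                pred = log_odds > 0.0
            fold_accs.append(float((pred == y[test]).mean()))
        target_accs.append(float(np.mean(fold_accs)))
    return float(np.mean(target_accs))
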