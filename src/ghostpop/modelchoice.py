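"""Random-forest scenario choice on simulated reference tables.

A classification forest is trained on the summary statistics of a
reference table (optionally augmented with linear-discriminant axes fit
on the scenario labels).  For an observed statistic vector the forest's
per-tree votes are tallied; the prior error rate is the out-of-bag (OOB)
misclassification rate; and the posterior probability of the selected
scenario is estimated by a regression forest trained on the OOB
classification-success indicator, following the ABC-random-forest
construction.

Scenario comparison can be organised as a sequential tournament: each
preliminary round compares a subset of scenarios and advances those
receiving strictly more than ``n_trees / k`` votes (the average), and
the advanced scenarios meet in a final round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import GhostpopError
from .simulate import ReferenceTable
from .sumstats import SummaryStatVector


@dataclass
class ModelChoiceResult:
    votes: Dict[str, int]
    selected: str
    posterior_probability: float
    oob_error: float
    n_trees: int
    lda_axes_used: bool


@dataclass
class TournamentPlan:
    """Ordered preliminary rounds (lists of scenario labels); winners of
    all rounds meet in a final round.  A plan with a single round is
    equivalent to one direct comparison."""

    rounds: List[List[str]]

    def all_scenarios(self) -> List[str]:
        out: List[str] = []
        for r in self.rounds:
            for s in r:
                if s not in out:
                    out.append(s)
        return out


class ModelChoiceForest:
    """Trained scenario classifier (random forest + optional LDA axes)."""

    def __init__(
        self,
        classifier,
        regressor,
        lda,
        feature_mask: np.ndarray,
        classes: List[str],
        oob_error: float,
        n_trees: int,
    ):
        self._clf = classifier
        self._reg = regressor
        self._lda = lda
        self._mask = feature_mask
        self.classes = classes
        self.oob_error = oob_error
        self.n_trees = n_trees

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self._mask]
        if self._lda is not None:
            X = np.hstack([X, self._lda.transform(X)])
        return X

    def vote_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n_obs, n_classes) per-tree vote counts."""
        F = self._features(X)
        votes = np.zeros((F.shape[0], len(self.classes)), dtype=int)
        for tree in self._clf.estimators_:
            pred = np.argmax(tree.predict_proba(F), axis=1)
            for i, c in enumerate(pred):
                votes[i, c] += 1
        return votes

    def posterior_probability(self, X: np.ndarray) -> np.ndarray:
        """P(selected scenario | observed), one value per row of X."""
        return np.clip(self._reg.predict(self._features(X)), 0.0, 1.0)


def train_model_choice(
    reftable: ReferenceTable,
    n_trees: int = 1000,
    use_lda: bool = True,
    seed: Optional[int] = None,
) -> ModelChoiceForest:
    """Fit the scenario-choice forest and report its OOB error.

    Constant statistic columns carry no information and break the LDA
    whitening, so they are dropped with a warning.  Needs at least two
    scenarios.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import (
        RandomForestClassifier,
        RandomForestRegressor,
    )

    labels = reftable.labels
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise GhostpopError("model choice needs at least two scenarios")
    X = reftable.stats
    # exact range test: axis-wise std of a constant column can round off
    # to a tiny non-zero value
    mask = (X.max(axis=0) - X.min(axis=0)) > 0
    if not mask.all():
        warnings.warn(
            f"dropping {int((~mask).sum())} constant statistic column(s)"
        )
    X = X[:, mask]
    lda = None
    if use_lda:
        lda = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(X, labels)
        X = np.hstack([X, lda.transform(X)])
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=None if seed is None else int(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rows never out of bag at small n
        clf.fit(X, labels)
    oob_votes = clf.oob_decision_function_
    has_oob = oob_votes.sum(axis=1) > 0
    oob_pred = clf.classes_[np.argmax(oob_votes, axis=1)]
    correct = (oob_pred == labels) & has_oob
    oob_error = float(1.0 - correct[has_oob].mean())
    reg = RandomForestRegressor(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=None if seed is None else int(seed) + 1,
        n_jobs=1,
    )
    reg.fit(X, correct.astype(float))
    return ModelChoiceForest(
        classifier=clf,
        regressor=reg,
        lda=lda,
        feature_mask=mask,
        classes=list(clf.classes_),
        oob_error=oob_error,
        n_trees=n_trees,
    )


def classify_observed(
    forest: ModelChoiceForest, observed
) -> ModelChoiceResult:
    """Tally per-tree votes for one observed summary-statistic vector."""
    x = observed.values if isinstance(observed, SummaryStatVector) else observed
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != len(forest._mask):
        raise GhostpopError(
            f"observed vector length {x.shape} does not match the "
            f"reference schema ({len(forest._mask)} statistics)"
        )
    votes = forest.vote_matrix(x[None, :])[0]
    sel = int(np.argmax(votes))
    post = float(forest.posterior_probability(x[None, :])[0])
    return ModelChoiceResult(
        votes={c: int(v) for c, v in zip(forest.classes, votes)},
        selected=forest.classes[sel],
        posterior_probability=post,
        oob_error=forest.oob_error,
        n_trees=forest.n_trees,
        lda_axes_used=forest._lda is not None,
    )


def advance(votes: Dict[str, int], n_trees: int) -> List[str]:
    """Scenarios advancing from one round: strictly more votes than the
    round average ``n_trees / k``.  Ties at the threshold do not advance.
    If none clears the bar the single top-voted scenario advances with a
    warning (keeps noisy small-table tournaments runnable)."""
    k = len(votes)
    threshold = n_trees / k
    winners = [s for s, v in votes.items() if v > threshold]
    if not winners:
        top = max(votes, key=lambda s: votes[s])
        warnings.warn(
            f"no scenario exceeded the vote threshold {threshold:.1f}; "
            f"advancing top-voted {top!r}"
        )
        winners = [top]
    return winners


@dataclass
class TournamentAudit:
    round_results: List[ModelChoiceResult] = field(default_factory=list)
    round_subsets: List[List[str]] = field(default_factory=list)
    advanced: List[List[str]] = field(default_factory=list)
    final: Optional[ModelChoiceResult] = None


def run_tournament(
    reftable: ReferenceTable,
    plan: TournamentPlan,
    observed,
    n_trees: int = 1000,
    use_lda: bool = True,
    seed: Optional[int] = None,
    forest_cache: Optional[Dict] = None,
) -> TournamentAudit:
    """Run the sequential comparison for one observed dataset.

    Each round trains a forest on the reference rows of its scenario
    subset (forests are memoised in ``forest_cache`` keyed by subset, so
    classifying many observed datasets against one reference table does
    not retrain).  Winners of all preliminary rounds meet in the final
    round; a single-round plan degenerates to one direct comparison.
    """
    audit = TournamentAudit()
    cache = forest_cache if forest_cache is not None else {}

    def forest_for(subset: Sequence[str]) -> ModelChoiceForest:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = train_model_choice(
                reftable.restrict(list(key)),
                n_trees=n_trees,
                use_lda=use_lda,
                seed=seed,
            )
        return cache[key]

    finalists: List[str] = []
    for subset in plan.rounds:
        if len(set(subset)) < 2:
            raise GhostpopError("each round needs at least two scenarios")
        res = classify_observed(forest_for(subset), observed)
        audit.round_results.append(res)
        audit.round_subsets.append(list(subset))
        adv = advance(res.votes, n_trees)
        audit.advanced.append(adv)
        for s in adv:
            if s not in finalists:
                finalists.append(s)
    if len(plan.rounds) == 1:
        audit.final = audit.round_results[0]
        return audit
    if len(finalists) == 1:
        # only one scenario survived; it wins by default
        audit.final = ModelChoiceResult(
            votes={finalists[0]: n_trees},
            selected=finalists[0],
            posterior_probability=float("nan"),
            oob_error=float("nan"),
            n_trees=n_trees,
            lda_axes_used=use_lda,
        )
        return audit
    audit.final = classify_observed(forest_for(finalists), observed)
    return audit
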