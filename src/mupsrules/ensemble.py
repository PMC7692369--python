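"""Rule ensembles, voting classification and repeated stratified CV.

Variable-consistency bagging (VC-bagging) draws bootstrap samples whose
per-object inclusion probabilities are proportional to each object's
dominance-cone consistency, so that inconsistent (boundary) formulations
enter fewer bags; one rule set per class union is induced from every bag.
Classification is by strength-weighted voting of all rules whose premise
the new object satisfies, with a conservative tie/no-match policy
(predict the worse class, i.e. a changed release profile, on a tie;
training-majority class when no rule fires).

Predictive accuracy is assessed with k-fold stratified cross-validation
repeated R times; all randomness flows from one root seed through
deterministic per-repeat / per-bag counters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .approximations import consistency_by_object, own_union
from .information_system import DecisionTable
from .rules import RuleSet, induce_rules

logger = logging.getLogger(__name__)


@dataclass
class RuleEnsemble:
    """Bagged rule sets plus the training information needed for voting."""

    bags: list[list[RuleSet]]
    sample_ids: list[np.ndarray]
    default_class: int
    classes: list[int]

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    def iter_rules(self):
        for rulesets in self.bags:
            for rs in rulesets:
                yield from rs


@dataclass
class CVReport:
    """Per-repeat, per-fold outcome counts of repeated stratified CV."""

    k: int
    repeats: int
    seed: int
    fold_records: pd.DataFrame = field(repr=False)

    @property
    def n_objects(self) -> int:
        per_repeat = self.fold_records.groupby("repeat")["n_test"].sum()
        return int(per_repeat.iloc[0])

    @property
    def avg_correct(self) -> float:
        """Average number of correctly classified objects per repeat."""
        return float(self.fold_records.groupby("repeat")["n_correct"].sum().mean())

    @property
    def avg_incorrect(self) -> float:
        return float(self.n_objects - self.avg_correct)

    @property
    def accuracy(self) -> float:
        """Average classification accuracy in %, over repeats."""
        per_repeat = self.fold_records.groupby("repeat").apply(
            lambda g: g["n_correct"].sum() / g["n_test"].sum(), include_groups=False
        )
        return float(per_repeat.mean() * 100.0)

    def precision(self, average: str = "macro") -> float:
        """Average precision in % (macro over classes by default)."""
        recs = self.fold_records
        classes = sorted(
            int(c.split("_", 2)[2])
            for c in recs.columns
            if c.startswith("pred_tp_")
        )
        per_repeat = []
        for _, g in recs.groupby("repeat"):
            if average == "macro":
                vals = []
                for c in classes:
                    tp = g[f"pred_tp_{c}"].sum()
                    fp = g[f"pred_fp_{c}"].sum()
                    if tp + fp > 0:
                        vals.append(tp / (tp + fp))
                per_repeat.append(float(np.mean(vals)) if vals else float("nan"))
            elif average == "micro":
                per_repeat.append(g["n_correct"].sum() / g["n_test"].sum())
            else:
                raise ValueError(f"unknown averaging {average!r}")
        return float(np.nanmean(per_repeat) * 100.0)

    def to_dataframe(self) -> pd.DataFrame:
        return self.fold_records.copy()

    def summary(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "correctly_classified_avg": self.avg_correct,
            "incorrectly_classified_avg": self.avg_incorrect,
            "accuracy_pct": self.accuracy,
            "precision_macro_pct": self.precision("macro"),
        }


# -- fold construction -----------------------------------------------------


def stratified_folds(
    table_or_labels, k: int = 5, repeats: int = 100, seed: int = 0
) -> list[list[np.ndarray]]:
    """Fold plan for repeated stratified k-fold CV.

    Returns ``plan[repeat][fold]`` = array of test positions.  Class
    proportions are preserved within one object per fold; the plan is a
    deterministic function of ``seed``.
    """
    if isinstance(table_or_labels, DecisionTable):
        y = np.asarray(table_or_labels.decision, dtype=int)
    else:
        y = np.asarray(table_or_labels, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot build {k} folds"
        )
    plan = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_derive_seed(seed, r))
        plan.append([test for _, test in skf.split(np.zeros(len(y)), y)])
    return plan


def _derive_seed(seed: int, counter: int) -> int:
    # deterministic per-repeat / per-bag streams below 2**31
    return int(np.random.SeedSequence([seed, counter]).generate_state(1)[0] % (2**31))


# -- VC-bagging ------------------------------------------------------------


def vc_bagging_train(
    table: DecisionTable,
    n_bags: int = 30,
    consistency: float = 1.0,
    seed: int = 0,
    bootstrap: bool = True,
    measure: str = "s",
) -> RuleEnsemble:
    """Train a VC-bagged rule ensemble on a decision table.

    Each bag is a bootstrap sample of size ``n_objects`` drawn with
    replacement with probabilities proportional to each object's
    dominance-cone consistency (fully consistent objects are favoured,
    boundary objects down-weighted).  With ``bootstrap=False`` every bag
    is the full table, so ``n_bags=1`` reduces to plain induction.
    Bags degenerating to a single class are skipped with a warning.
    """
    classes = table.classes
    weights = consistency_by_object(table)
    probs = weights / weights.sum()
    n = table.n_objects
    labels = np.asarray(table.decision, dtype=int)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    default = max(classes, key=lambda c: (counts[c], c))  # majority; tie -> worse class

    bags: list[list[RuleSet]] = []
    sample_ids: list[np.ndarray] = []
    for b in range(n_bags):
        if bootstrap:
            rng = np.random.default_rng(_derive_seed(seed, b))
            idx = rng.choice(n, size=n, replace=True, p=probs)
        else:
            idx = np.arange(n)
        sample = table.subset(idx)
        if len(sample.classes) < 2:
            msg = f"bag {b}: bootstrap degenerated to one class; skipped"
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)
            continue
        rulesets = [
            induce_rules(sample, own_union(c, classes), consistency, measure)
            for c in classes
        ]
        bags.append(rulesets)
        sample_ids.append(idx)
    return RuleEnsemble(bags=bags, sample_ids=sample_ids,
                        default_class=default, classes=classes)


# -- classification --------------------------------------------------------


def _vote_matrix(ensemble: RuleEnsemble, data) -> np.ndarray:
    """Summed rule strengths per (object, class)."""
    if isinstance(data, DecisionTable):
        n = data.n_objects
    else:
        n = len(data)
    votes = np.zeros((n, len(ensemble.classes)), dtype=float)
    col = {c: i for i, c in enumerate(ensemble.classes)}
    for rule in ensemble.iter_rules():
        fired = rule.matches(data)
        if not fired.any():
            continue
        for c in ensemble.classes:
            if rule.conclusion.contains_class(c):
                votes[fired, col[c]] += rule.strength
    return votes


def classify(ensemble: RuleEnsemble, data) -> np.ndarray:
    """Predict class labels by strength-weighted voting.

    ``data`` may be a DecisionTable or a DataFrame carrying every
    condition-attribute column the rules reference.  Objects matched by no
    rule get the training-majority class; vote ties go to the worse class
    (conservative: predicts a changed release profile).
    """
    if not isinstance(data, (DecisionTable, pd.DataFrame)):
        data = pd.DataFrame([data])
    votes = _vote_matrix(ensemble, data)
    classes = np.asarray(ensemble.classes)
    out = np.empty(votes.shape[0], dtype=int)
    for i, row in enumerate(votes):
        if row.sum() == 0:
            out[i] = ensemble.default_class
            continue
        tied = classes[np.isclose(row, row.max())]
        # tie -> numerically largest label, i.e. the worse class
        out[i] = int(tied.max())
    return out


# -- cross-validation ------------------------------------------------------


def cross_validate(
    table: DecisionTable,
    k: int = 5,
    repeats: int = 100,
    n_bags: int = 30,
    consistency: float = 1.0,
    seed: int = 0,
    measure: str = "s",
) -> CVReport:
    """Repeated stratified k-fold CV of the VC-bagged rule classifier."""
    plan = stratified_folds(table, k=k, repeats=repeats, seed=seed)
    labels = np.asarray(table.decision, dtype=int)
    classes = table.classes
    records = []
    all_pos = np.arange(table.n_objects)
    for r, folds in enumerate(plan):
        for f, test_pos in enumerate(folds):
            train_pos = np.setdiff1d(all_pos, test_pos)
            train = table.subset(train_pos)
            ensemble = vc_bagging_train(
                train,
                n_bags=n_bags,
                consistency=consistency,
                seed=_derive_seed(seed, 100_000 + r * k + f),
                measure=measure,
            )
            test_data = table.data.iloc[test_pos]
            pred = classify(ensemble, test_data)
            truth = labels[test_pos]
            rec = {
                "repeat": r,
                "fold": f,
                "n_test": len(test_pos),
                "n_correct": int(np.sum(pred == truth)),
                "n_incorrect": int(np.sum(pred != truth)),
            }
            for c in classes:
                rec[f"pred_tp_{c}"] = int(np.sum((pred == c) & (truth == c)))
                rec[f"pred_fp_{c}"] = int(np.sum((pred == c) & (truth != c)))
            records.append(rec)
    return CVReport(k=k, repeats=repeats, seed=seed, fold_records=pd.DataFrame(records))


# -- attribute relevance ---------------------------------------------------


def attribute_relevance(
    ensembles, table: DecisionTable, data: pd.DataFrame | None = None
) -> pd.Series:
    """Confirmation-style relevance of each condition attribute.

    Every (rule, object) pair with a satisfied premise is a suggestion
    event; the suggestion is correct when the object's true class lies in
    the rule's conclusion.  An attribute is credited when suggestions by
    rules that involve it are correct, and when suggestions by rules that
    omit it are incorrect; the score is

        P(correct | attribute in premise) - P(correct | attribute absent)

    so it increases with both bookkeeping channels and is 0 for an
    attribute whose presence carries no information.  Attributes occurring
    in no rule get NaN (not applicable).
    """
    if isinstance(ensembles, RuleEnsemble):
        ensembles = [ensembles]
    if data is None:
        data = table.data
    labels = np.asarray(table.decision, dtype=int)
    base_names = sorted({a.base for a in table.attributes})
    tally = {name: np.zeros(4, dtype=float) for name in base_names}  # a, b, c, d
    for ens in ensembles:
        for rule in ens.iter_rules():
            fired = rule.matches(data)
            if not fired.any():
                continue
            correct = np.zeros(len(labels), dtype=bool)
            for c in np.unique(labels):
                if rule.conclusion.contains_class(int(c)):
                    correct |= labels == c
            n_corr = float(np.sum(fired & correct))
            n_inc = float(np.sum(fired & ~correct))
            used = rule.attributes
            for name in base_names:
                t = tally[name]
                if name in used:
                    t[0] += n_corr
                    t[1] += n_inc
                else:
                    t[2] += n_corr
                    t[3] += n_inc
    scores = {}
    for name, (a, b, c, d) in tally.items():
        if a + b == 0:
            scores[name] = float("nan")
        elif c + d == 0:
            scores[name] = a / (a + b)
        else:
            scores[name] = a / (a + b) - c / (c + d)
    return pd.Series(scores, name="relevance").sort_values(ascending=False)
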