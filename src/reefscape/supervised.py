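"""Blocked supervised evaluation.

Reef recordings are temporally autocorrelated and carry instrument bias, so
train/validation/test splits hold out whole blocks — entire sites, or
site-and-date combinations — rather than random minutes. Between 66% and 75%
of minutes go to training and the held-out blocks are split evenly between
validation and test (the odd block goes to test). For each split, a bank of
seeded classifiers (fifty random forests by default) is trained; the instance
with the highest validation accuracy is used for inference on the test set.
Frame-level classifiers are scored per minute through a majority vote over
their 0.96-s frame predictions. Method comparisons across repeats use one-way
ANOVA followed by Tukey HSD when significant.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier

from .embeddings import EmbeddingMatrix

__all__ = [
    "SplitPlan",
    "EvalRecord",
    "make_blocked_splits",
    "majority_vote",
    "run_classification",
    "random_baseline",
    "compare_methods",
    "summarize_records",
]


@dataclass(frozen=True)
class SplitPlan:
    """A block-level train/validation/test partition with no leakage.

    ``blocks`` maps block id to its minute keys; ``assignment`` maps block id
    to one of train/validation/test. Every key belongs to exactly one block
    and every block to exactly one partition.
    """

    blocks: dict
    assignment: dict
    train_fraction: float

    def __post_init__(self) -> None:
        if set(self.blocks) != set(self.assignment):
            raise ValueError("blocks and assignment must cover the same block ids")
        bad = {b: p for b, p in self.assignment.items()
               if p not in ("train", "validation", "test")}
        if bad:
            raise ValueError(f"invalid partition labels: {bad}")
        all_keys = [k for keys in self.blocks.values() for k in keys]
        if len(set(all_keys)) != len(all_keys):
            raise ValueError("a minute key appears in more than one block")

    def keys(self, partition: str) -> list:
        return [k for b, p in sorted(self.assignment.items()) if p == partition
                for k in self.blocks[b]]

    @property
    def train_keys(self) -> list:
        return self.keys("train")

    @property
    def validation_keys(self) -> list:
        return self.keys("validation")

    @property
    def test_keys(self) -> list:
        return self.keys("test")

    def block_ids(self, partition: str) -> set:
        return {b for b, p in self.assignment.items() if p == partition}

    def assert_no_leakage(self) -> None:
        """Verify the three partitions share no blocks and no minute keys."""
        parts = ["train", "validation", "test"]
        for a, b in itertools.combinations(parts, 2):
            shared_blocks = self.block_ids(a) & self.block_ids(b)
            if shared_blocks:
                raise AssertionError(f"blocks {shared_blocks} in both {a} and {b}")
            shared_keys = set(self.keys(a)) & set(self.keys(b))
            if shared_keys:
                raise AssertionError(f"keys shared between {a} and {b}")


def _block_id(row: pd.Series, block_by: str):
    if block_by == "site":
        return row["site_id"]
    if block_by == "site_and_date":
        return (row["site_id"], row["date"])
    raise ValueError("block_by must be 'site' or 'site_and_date'")


def make_blocked_splits(
    manifest: pd.DataFrame,
    block_by: str = "site",
    train_frac: tuple = (0.66, 0.75),
    repeats: int = 100,
    seed: int = 0,
) -> list[SplitPlan]:
    """Enumerate (or sample) leakage-free blocked split plans.

    All block subsets whose realized train fraction of minutes falls inside
    ``train_frac`` are enumerated; each held-out set is split evenly between
    validation and test at the block level (extra block to test), in every
    arrangement. If more than ``repeats`` distinct plans exist, ``repeats``
    are sampled without replacement; if fewer, all are returned.
    """
    lo, hi = train_frac
    blocks: dict = {}
    for _, row in manifest.iterrows():
        blocks.setdefault(_block_id(row, block_by), []).append(row["file"])
    block_ids = sorted(blocks)
    n_blocks = len(block_ids)
    if n_blocks < 3:
        raise ValueError(f"need >= 3 blocks for train/validation/test, got {n_blocks}")
    total = sum(len(v) for v in blocks.values())

    plans: list[SplitPlan] = []
    if n_blocks <= 18:
        for h in range(2, n_blocks - 1 + 1):
            for held in itertools.combinations(block_ids, h):
                frac = (total - sum(len(blocks[b]) for b in held)) / total
                if not lo <= frac <= hi:
                    continue
                n_val = h // 2
                if n_val == 0:
                    continue
                for val in itertools.combinations(held, n_val):
                    assignment = {b: "train" for b in block_ids}
                    for b in held:
                        assignment[b] = "validation" if b in val else "test"
                    plans.append(SplitPlan(dict(blocks), assignment, frac))
    else:
        rng = np.random.default_rng(seed)
        seen = set()
        attempts = 0
        while len(plans) < repeats and attempts < repeats * 200:
            attempts += 1
            h = int(rng.integers(2, n_blocks))
            held_idx = sorted(rng.choice(n_blocks, size=h, replace=False))
            held = tuple(block_ids[i] for i in held_idx)
            frac = (total - sum(len(blocks[b]) for b in held)) / total
            if not lo <= frac <= hi:
                continue
            val_idx = sorted(rng.choice(h, size=h // 2, replace=False))
            val = tuple(held[i] for i in val_idx)
            if h // 2 == 0 or (held, val) in seen:
                continue
            seen.add((held, val))
            assignment = {b: "train" for b in block_ids}
            for b in held:
                assignment[b] = "validation" if b in val else "test"
            plans.append(SplitPlan(dict(blocks), assignment, frac))

    if not plans:
        raise ValueError(
            f"no valid block assignment with train fraction in [{lo}, {hi}] "
            f"over {n_blocks} blocks"
        )
    for plan in plans:
        plan.assert_no_leakage()
    if len(plans) > repeats:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(plans), size=repeats, replace=False)
        plans = [plans[i] for i in sorted(chosen)]
    return plans


def majority_vote(frame_labels) -> object:
    """Modal label of a minute's frame predictions; ties go to the smallest
    label under the natural sort order."""
    labels = list(frame_labels)
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(labels)
    best = max(counts.values())
    return sorted(l for l, c in counts.items() if c == best)[0]


@dataclass(frozen=True)
class EvalRecord:
    """One repeat of blocked evaluation for one method."""

    method_id: str
    split_index: int
    validation_accuracy: float
    test_accuracy: float
    confusion: pd.DataFrame
    best_model_index: int
    train_fraction: float
    flags: tuple = ()


def _accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def run_classification(
    embeddings: EmbeddingMatrix,
    labels: dict,
    plan: SplitPlan,
    classifier=None,
    n_models: int = 50,
    seed: int = 0,
    split_index: int = 0,
    vote_groups: dict | None = None,
) -> EvalRecord:
    """Train ``n_models`` seeded classifier instances on the plan's training
    minutes, pick the one with the highest validation accuracy (ties to the
    lowest instance seed), and report its test accuracy and confusion matrix.

    ``labels`` maps minute key to class. When ``vote_groups`` maps row key to
    a minute id (frame-level embeddings), per-minute predictions are obtained
    by majority vote over the frames of each minute.
    """
    if classifier is None:
        classifier = RandomForestClassifier()
    vec = embeddings.mapping()

    def matrix(keys):
        keys = [k for k in keys if k in vec]
        return keys, np.stack([vec[k] for k in keys])

    flags = []
    partitions = {}
    for part, keys in (("train", plan.train_keys),
                       ("validation", plan.validation_keys),
                       ("test", plan.test_keys)):
        keys, X = matrix(keys)
        y = np.asarray([labels[vote_groups[k] if vote_groups else k] for k in keys])
        if len(set(y)) < 2:
            flags.append(f"single-class {part} partition")
        partitions[part] = (keys, X, y)

    _, X_tr, y_tr = partitions["train"]
    best_idx, best_val, best_model = -1, -np.inf, None
    for i in range(n_models):
        model = clone(classifier)
        if "random_state" in model.get_params():
            model.set_params(random_state=seed + i)
        model.fit(X_tr, y_tr)
        val_acc = _accuracy(partitions["validation"][2],
                            model.predict(partitions["validation"][1]))
        if val_acc > best_val:  # strict: first (lowest seed) wins ties
            best_idx, best_val, best_model = i, val_acc, model

    test_keys, X_te, y_te = partitions["test"]
    y_pred = best_model.predict(X_te)
    if vote_groups is not None:
        by_minute: dict = {}
        for k, pred in zip(test_keys, y_pred):
            by_minute.setdefault(vote_groups[k], []).append(pred)
        minutes = sorted(by_minute)
        y_te = np.asarray([labels[m] for m in minutes])
        y_pred = np.asarray([majority_vote(by_minute[m]) for m in minutes])
    classes = sorted(set(labels.values()))
    conf = pd.crosstab(
        pd.Series(list(y_te), name="true"), pd.Series(list(y_pred), name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    return EvalRecord(
        method_id=embeddings.extractor_id,
        split_index=split_index,
        validation_accuracy=float(best_val),
        test_accuracy=_accuracy(y_te, y_pred),
        confusion=conf,
        best_model_index=best_idx,
        train_fraction=plan.train_fraction,
        flags=tuple(flags),
    )


def random_baseline(n_classes: int) -> float:
    """Expected accuracy of a uniformly random classifier: 1 / K."""
    if n_classes < 1:
        raise ValueError("class count must be >= 1")
    return 1.0 / n_classes


def summarize_records(records: list[EvalRecord]) -> pd.DataFrame:
    """Per-method mean and standard deviation of test accuracy across repeats."""
    df = pd.DataFrame(
        {
            "method": [r.method_id for r in records],
            "test_accuracy": [r.test_accuracy for r in records],
        }
    )
    return df.groupby("method")["test_accuracy"].agg(["mean", "std", "count"])


def _grouping_letters(methods: list[str], means: dict, distinct: set) -> dict:
    """Compact letter display: methods sorted by descending mean accuracy;
    methods not significantly different share a letter."""
    ordered = sorted(methods, key=lambda m: -means[m])
    letters: dict = {m: "" for m in methods}
    groups: list[set] = []
    for m in ordered:
        placed = False
        for g in groups:
            if all((m, o) not in distinct and (o, m) not in distinct for o in g):
                g.add(m)
                placed = True
        if not placed:
            groups.append({m})
    for gi, g in enumerate(groups):
        letter = chr(ord("A") + gi)
        for m in g:
            letters[m] += letter
    return letters


def compare_methods(accuracies: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA across methods' repeat accuracies; Tukey HSD post hoc
    when significant, with grouping letters (A = highest-accuracy group)."""
    methods = sorted(accuracies)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    lengths = {len(accuracies[m]) for m in methods}
    if len(lengths) != 1:
        raise ValueError("methods must have equal-length repeat lists")
    groups = [np.asarray(accuracies[m], dtype=float) for m in methods]
    if all(g.std() == 0 for g in groups):
        return {"degenerate": True, "anova_F": float("nan"), "anova_p": float("nan"),
                "tukey": None, "letters": None}
    F, p = stats.f_oneway(*groups)
    report: dict = {"degenerate": False, "anova_F": float(F), "anova_p": float(p),
                    "tukey": None, "letters": None}
    if p < alpha:
        res = stats.tukey_hsd(*groups)
        pairs = []
        distinct = set()
        for i, j in itertools.combinations(range(len(methods)), 2):
            ci = res.confidence_interval()
            sig = res.pvalue[i, j] < alpha
            if sig:
                distinct.add((methods[i], methods[j]))
            pairs.append(
                {
                    "method_a": methods[i],
                    "method_b": methods[j],
                    "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p": float(res.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "significant": bool(sig),
                }
            )
        means = {m: float(np.mean(g)) for m, g in zip(methods, groups)}
        report["tukey"] = pairs
        report["letters"] = _grouping_letters(methods, means, distinct)
    return report
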