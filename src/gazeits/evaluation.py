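"""Cross-validation protocols, paired Wilcoxon comparison, reports.

Three split strategies answer three generalization questions:

* person_dependent — five-fold CV within each participant's own trials;
  the comparison unit is the per-participant mean fold accuracy;
* person_independent — group five-fold over participants, so no test
  participant's data is ever seen in training; compared per fold;
* leave_one_task_out — each fold tests on all trials of one task type that
  was absent from training; compared per fold.

One split plan is built per dataset and reused by every classifier, which
makes the per-fold accuracies paired; classifiers are then compared with a
one-tailed Wilcoxon signed-rank test (alternative: row classifier better
than column classifier) at alpha = 0.05.  The signed-rank null distribution
is exact (dynamic program over rank sums, midranks, zeros dropped) up to
n = 25 pairs and a tie-corrected normal approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gaze_io import DataError

__all__ = [
    "SplitPlan",
    "make_splits",
    "ProtocolResult",
    "run_protocol",
    "wilcoxon_one_tailed",
    "build_report",
    "EvaluationReport",
]

PROTOCOLS = ("person_dependent", "person_independent", "leave_one_task_out")


class ProtocolError(ValueError):
    pass


@dataclass
class SplitPlan:
    """Fold assignments: frame with trial_id, participant_id, task_id,
    condition, fold (int), and for person_dependent also the participant
    the fold belongs to."""

    protocol: str
    assignments: pd.DataFrame
    k: int
    seed: int

    def __post_init__(self) -> None:
        a = self.assignments
        if self.protocol == "person_independent":
            for f in sorted(a["fold"].unique()):
                test_p = set(a.loc[a["fold"] == f, "participant_id"])
                train_p = set(a.loc[a["fold"] != f, "participant_id"])
                if test_p & train_p:
                    raise ProtocolError("participant appears in both train "
                                        f"and test of fold {f}")
        if self.protocol == "leave_one_task_out":
            for f in sorted(a["fold"].unique()):
                if a.loc[a["fold"] == f, "task_id"].nunique() != 1:
                    raise ProtocolError(f"fold {f} mixes tasks")

    def folds(self):
        """Yield (fold_key, train_index, test_index) over the assignment
        frame's positional indices."""
        a = self.assignments
        if self.protocol == "person_dependent":
            for pid in sorted(a["participant_id"].unique()):
                mask_p = (a["participant_id"] == pid).to_numpy()
                for f in sorted(a.loc[mask_p, "fold"].unique()):
                    test = mask_p & (a["fold"] == f).to_numpy()
                    train = mask_p & ~test
                    yield ((pid, int(f)), np.flatnonzero(train),
                           np.flatnonzero(test))
        else:
            for f in sorted(a["fold"].unique()):
                test = (a["fold"] == f).to_numpy()
                yield (int(f), np.flatnonzero(~test), np.flatnonzero(test))


def _meta_frame(trials_or_meta) -> pd.DataFrame:
    if isinstance(trials_or_meta, pd.DataFrame):
        return trials_or_meta[["trial_id", "participant_id", "task_id",
                               "condition"]].reset_index(drop=True)
    return pd.DataFrame([{
        "trial_id": t.trial_id, "participant_id": t.participant_id,
        "task_id": t.task_id, "condition": t.condition,
    } for t in trials_or_meta])


def make_splits(trials_or_meta, protocol: str, k: int = 5,
                seed: int = 0) -> SplitPlan:
    """Deterministic split plan, reusable across classifiers."""
    if protocol not in PROTOCOLS:
        raise ProtocolError(f"unknown protocol {protocol!r}")
    meta = _meta_frame(trials_or_meta).copy()
    rng = np.random.default_rng(seed)
    meta["fold"] = -1
    if protocol == "person_dependent":
        for pid in sorted(meta["participant_id"].unique()):
            idx = np.flatnonzero((meta["participant_id"] == pid).to_numpy())
            if len(idx) < k:
                raise ProtocolError(f"participant {pid} has fewer than {k} "
                                    "trials")
            # stratified by condition so folds stay balanced
            folds = np.empty(len(idx), dtype=int)
            for cond in np.unique(meta.loc[idx, "condition"]):
                sub = idx[(meta.loc[idx, "condition"] == cond).to_numpy()]
                sub = rng.permutation(sub)
                folds_c = np.arange(len(sub)) % k
                meta.loc[sub, "fold"] = folds_c
    elif protocol == "person_independent":
        participants = np.array(sorted(meta["participant_id"].unique()))
        if len(participants) < k:
            raise ProtocolError(f"{len(participants)} participants cannot "
                                f"fill {k} disjoint folds")
        participants = rng.permutation(participants)
        fold_of = {p: i % k for i, p in enumerate(participants)}
        meta["fold"] = meta["participant_id"].map(fold_of)
    else:  # leave_one_task_out
        tasks = sorted(meta["task_id"].unique())
        if len(tasks) < 2:
            raise ProtocolError("leave_one_task_out needs at least 2 tasks")
        fold_of = {t: i for i, t in enumerate(tasks)}
        meta["fold"] = meta["task_id"].map(fold_of)
    return SplitPlan(protocol=protocol, assignments=meta, k=k, seed=seed)


@dataclass
class ProtocolResult:
    """Per-fold accuracies plus the protocol's comparison units."""

    protocol: str
    fold_accuracies: pd.DataFrame  # columns: fold_key, n_test, accuracy
    skipped: list = field(default_factory=list)

    @property
    def comparison_units(self) -> np.ndarray:
        """Per-participant means for person_dependent, per-fold accuracies
        otherwise (the unit entering paired statistics)."""
        fa = self.fold_accuracies
        if self.protocol == "person_dependent":
            pids = [key[0] for key in fa["fold_key"]]
            return (fa.assign(pid=pids).groupby("pid")["accuracy"]
                    .mean().sort_index().to_numpy())
        return fa["accuracy"].to_numpy()

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.comparison_units))


def run_protocol(plan: SplitPlan,
                 fit_predict: Callable[[np.ndarray, np.ndarray], np.ndarray],
                 labels: np.ndarray | None = None) -> ProtocolResult:
    """Evaluate one classifier over a split plan.

    ``fit_predict(train_idx, test_idx)`` must fit on the training rows of
    the plan's assignment frame and return predicted labels for the test
    rows; everything fold-specific (normalization, selection, CNN training)
    belongs inside it.  Folds whose training labels collapse to one class
    are skipped and recorded.
    """
    y = np.asarray(labels if labels is not None
                   else plan.assignments["condition"].to_numpy())
    rows, skipped = [], []
    for key, tr, te in plan.folds():
        if len(np.unique(y[tr])) < 2:
            skipped.append(key)
            continue
        pred = np.asarray(fit_predict(tr, te))
        rows.append({"fold_key": key, "n_test": len(te),
                     "accuracy": float(np.mean(pred == y[te]))})
    return ProtocolResult(protocol=plan.protocol,
                          fold_accuracies=pd.DataFrame(rows),
                          skipped=skipped)


def wilcoxon_one_tailed(a, b) -> tuple[float, float]:
    """One-tailed Wilcoxon signed-rank test of ``a > b`` on paired values.

    Zero differences are dropped; all-zero differences give p = 1.  Exact
    null distribution (midranks, DP over rank sums) for n <= 25 pairs,
    tie-corrected normal approximation with continuity correction above.
    Returns ``(p_value, w_plus)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired sequences must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0, 0.0
    ranks = sps.rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # doubled ranks are integers even with .5 midranks
        r2 = np.round(2 * ranks).astype(int)
        total = r2.sum()
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:len(counts) - r]
            counts = counts + shifted
        w2 = int(np.round(2 * w_plus))
        p = counts[w2:].sum() / (2.0 ** n)
        return float(p), w_plus
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - (tie_counts ** 3 - tie_counts).sum() / 48.0)
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(sps.norm.sf(z)), w_plus


@dataclass
class EvaluationReport:
    protocol: str
    mean_accuracies: dict[str, float]
    p_values: pd.DataFrame          # raw, unrounded; row beats column
    comparison_units: dict[str, np.ndarray]
    skipped: dict[str, list] = field(default_factory=dict)
    alpha: float = 0.05

    def rendered_table(self) -> str:
        """Markdown table: mean accuracies + p-values rounded to 3 decimals
        (so 1 and 0 are possible); the best mean accuracy is starred."""
        names = list(self.mean_accuracies)
        best = max(self.mean_accuracies, key=self.mean_accuracies.get)
        lines = ["| classifier | mean acc | " + " | ".join(names) + " |",
                 "|" + "---|" * (len(names) + 2)]
        for r in names:
            acc = self.mean_accuracies[r]
            star = " *" if r == best else ""
            cells = [f"{self.p_values.loc[r, c]:.3f}" if r != c else "—"
                     for c in names]
            lines.append(f"| {r}{star} | {acc:.3f} | " + " | ".join(cells)
                         + " |")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "alpha": self.alpha,
            "mean_accuracies": {k: float(v)
                                for k, v in self.mean_accuracies.items()},
            "p_values": {r: {c: float(self.p_values.loc[r, c])
                             for c in self.p_values.columns}
                         for r in self.p_values.index},
            "comparison_units": {k: [float(x) for x in v]
                                 for k, v in self.comparison_units.items()},
            "skipped": {k: [str(s) for s in v]
                        for k, v in self.skipped.items()},
        }


def build_report(results: dict[str, ProtocolResult],
                 alpha: float = 0.05) -> EvaluationReport:
    """Pairwise one-tailed comparison of classifiers on paired units."""
    if len(results) < 2:
        raise DataError("need at least 2 classifiers to compare")
    names = list(results)
    protocol = results[names[0]].protocol
    units = {n: results[n].comparison_units for n in names}
    lengths = {len(u) for u in units.values()}
    if len(lengths) != 1:
        raise DataError("comparison units are not paired across classifiers")
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                     columns=names)
    for r in names:
        for c in names:
            if r != c:
                p.loc[r, c] = wilcoxon_one_tailed(units[r], units[c])[0]
    return EvaluationReport(
        protocol=protocol,
        mean_accuracies={n: results[n].mean_accuracy for n in names},
        p_values=p,
        comparison_units=units,
        skipped={n: results[n].skipped for n in names},
        alpha=alpha,
    )
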