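"""Scoring, subject-level summaries, and the end-to-end experiment.

Per-subject accuracies (%) of the four detectors — face expression, EEG,
sum-rule fusion, production-rule fusion — are tabulated with a mean ± SD
summary row (sample SD, n-1 denominator, reported half-up to 2 decimals)
and compared with paired two-tailed t-tests across subjects.

``run_experiment`` drives the whole pipeline on synthetic subjects: a
stratified half/half split of each subject's trials, per-subject classifier
fits (face PCA + network; EEG state and intensity SVMs on window-level band
powers), and per-trial decisions that pool the per-image/per-window scores
(normalized face scores averaged over a trial's images before the argmax;
raw EEG decision values averaged over a trial's windows, then normalized).

A reference per-subject accuracy table from the original twenty-subject
experiments ships with the package for the summary-statistics checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import eeg_classify, face_pipeline, fusion
from .eeg_features import windowed_features
from .face_pipeline import HyperParams
from .labels import EmotionState, STATE_ORDER
from .synthetic_data import SubjectDataset

__all__ = [
    "accuracy",
    "summarize",
    "round2",
    "PairedTestResult",
    "DegenerateDifferencesError",
    "paired_t_test",
    "reference_accuracy_table",
    "summarize_table",
    "t_test_table",
    "DETECTORS",
    "ExperimentConfig",
    "AccuracyTable",
    "run_experiment",
]

DETECTORS = ("face", "eeg", "sum_fusion", "production_fusion")

#: Detector pairs compared in the subject-level statistics.
T_TEST_PAIRS = (
    ("sum_fusion", "face"),
    ("sum_fusion", "eeg"),
    ("production_fusion", "face"),
    ("production_fusion", "eeg"),
    ("eeg", "face"),
    ("sum_fusion", "production_fusion"),
)


def accuracy(predictions: Sequence, truths: Sequence) -> float:
    """Percentage of correct predictions: 100 * matches / total."""
    if len(predictions) == 0:
        raise ValueError("empty prediction list")
    if len(predictions) != len(truths):
        raise ValueError(f"{len(predictions)} predictions vs {len(truths)} truths")
    hits = sum(int(p) == int(t) for p, t in zip(predictions, truths))
    return 100.0 * hits / len(predictions)


def round2(x: float) -> float:
    """Round half-up to 2 decimals (report-table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(per_subject: Iterable[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of per-subject accuracies."""
    x = np.asarray(list(per_subject), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(x.mean()), float(x.std(ddof=1))


class DegenerateDifferencesError(ValueError):
    """Raised when paired differences have zero variance (t undefined)."""


@dataclass(frozen=True)
class PairedTestResult:
    pair: tuple[str, str]
    t: float
    p: float  # two-tailed
    significant: bool  # at alpha = 0.05


def paired_t_test(
    a: Sequence[float], b: Sequence[float], pair: tuple[str, str] = ("a", "b")
) -> PairedTestResult:
    """Classical paired two-tailed t-test on per-subject differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired samples differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d, d[0]):
        raise DegenerateDifferencesError(
            "paired differences are constant; t statistic is undefined"
        )
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(pair=pair, t=float(t), p=float(p), significant=bool(p < 0.05))


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

def reference_accuracy_table() -> pd.DataFrame:
    """The packaged 20-subject reference accuracy table (percent)."""
    text = resources.files("emofuse.data").joinpath("reference_accuracies.csv").read_text()
    return pd.read_csv(StringIO(text), index_col="subject")


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD summary (2-decimal, half-up) for each detector column."""
    rows = {}
    for col in table.columns:
        m, s = summarize(table[col].to_numpy())
        rows[col] = {"mean": round2(m), "sd": round2(s)}
    return pd.DataFrame(rows).T[["mean", "sd"]]


def t_test_table(table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise subject-level t-tests of the standard detector pairs."""
    recs = []
    for x, y in T_TEST_PAIRS:
        if x in table.columns and y in table.columns:
            r = paired_t_test(table[x].to_numpy(), table[y].to_numpy(), pair=(x, y))
            recs.append({"a": x, "b": y, "t": r.t, "p": r.p, "significant": r.significant})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# End-to-end experiment on synthetic subjects
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Knobs of the per-subject train/evaluate protocol."""

    hyperparams: HyperParams = HyperParams()  # face branch (D, N, R)
    nn_epochs: int = 25
    svm_C: float = 1.0
    test_fraction: float = 0.5
    seed: int = 0


@dataclass
class AccuracyTable:
    """Per-subject rows plus the recomputable mean/SD summary."""

    rows: pd.DataFrame  # index: subject, columns: DETECTORS, percent
    summary: pd.DataFrame  # index: detector, columns: mean, sd

    @classmethod
    def from_rows(cls, rows: pd.DataFrame) -> "AccuracyTable":
        if len(rows) >= 2:
            summary = summarize_table(rows)
        else:  # single subject: SD is undefined
            summary = pd.DataFrame(
                {c: {"mean": round2(rows[c].iloc[0]), "sd": float("nan")} for c in rows.columns}
            ).T[["mean", "sd"]]
        return cls(rows=rows, summary=summary)


def _stratified_split(
    states: Sequence[EmotionState], test_fraction: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    train_idx: list[int] = []
    test_idx: list[int] = []
    for s in STATE_ORDER:
        idx = [i for i, st in enumerate(states) if st == s]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        n_test = int(round(len(idx) * test_fraction))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return sorted(train_idx), sorted(test_idx)


def _evaluate_subject(
    dataset: SubjectDataset, config: ExperimentConfig
) -> dict[str, float]:
    trials = dataset.trials
    if len(trials) < 2 * len(STATE_ORDER):
        raise ValueError(
            f"need at least {2 * len(STATE_ORDER)} trials to split; got {len(trials)}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, dataset.config.subject_id, 9))
    )
    train_idx, test_idx = _stratified_split(
        [t.state for t in trials], config.test_fraction, rng
    )
    if not train_idx or not test_idx:
        raise ValueError("degenerate split: empty train or test set")

    hp = config.hyperparams

    # --- face branch: PCA + network on all training images -----------------
    train_images = [im for i in train_idx for im in trials[i].faces]
    train_img_labels = [trials[i].state for i in train_idx for _ in trials[i].faces]
    pca = face_pipeline.fit_pca(train_images, hp.D)
    train_feats = [face_pipeline.project(pca, im) for im in train_images]
    nn = face_pipeline.train_nn(
        train_feats, train_img_labels, hp=hp, epochs=config.nn_epochs,
        seed=config.seed + dataset.config.subject_id,
    )

    # --- EEG branch: window-level band powers, two SVMs ---------------------
    train_X, train_y_state, train_y_int = [], [], []
    for i in train_idx:
        feats = windowed_features(trials[i].eeg)
        train_X.append(feats)
        train_y_state.extend([trials[i].state] * feats.shape[0])
        train_y_int.extend([trials[i].intensity] * feats.shape[0])
    train_X = np.vstack(train_X)
    state_model = eeg_classify.train_state_model(train_X, train_y_state, config.svm_C)
    intensity_model = eeg_classify.train_intensity_model(train_X, train_y_int, config.svm_C)

    # --- per-trial decisions on the held-out trials -------------------------
    preds: dict[str, list[EmotionState]] = {d: [] for d in DETECTORS}
    truths: list[EmotionState] = []
    for i in test_idx:
        trial = trials[i]
        truths.append(trial.state)

        img_scores = np.stack([
            fusion.normalize_scores(
                nn.forward(face_pipeline.project(pca, im))
            )
            for im in trial.faces
        ])
        sh1 = img_scores.mean(axis=0)
        r1 = fusion.decide(sh1)

        feats = windowed_features(trial.eeg)
        s2 = state_model.decision_values(feats).mean(axis=0)
        sh2 = fusion.normalize_scores(s2)
        r2 = fusion.decide(sh2)
        s2p = intensity_model.decision_values(feats).mean(axis=0)
        r2p = eeg_classify.INTENSITY_ORDER[int(np.argmax(s2p))]

        preds["face"].append(r1)
        preds["eeg"].append(r2)
        preds["sum_fusion"].append(fusion.sum_fusion(sh1, sh2).r_sum)
        preds["production_fusion"].append(fusion.production_fusion(r1, r2p))

    return {d: accuracy(preds[d], truths) for d in DETECTORS}


def run_experiment(
    datasets: Sequence[SubjectDataset], config: "ExperimentConfig | None" = None
) -> AccuracyTable:
    """Fit and evaluate all four detectors per subject.

    Each subject gets an independent face network and pair of SVMs, fitted
    on a stratified half of their trials and evaluated on the other half.
    Reproducible end to end given the dataset seeds and ``config.seed``.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one subject dataset")
    config = config or ExperimentConfig()
    rows = {}
    for ds in datasets:
        rows[ds.config.subject_id] = _evaluate_subject(ds, config)
    df = pd.DataFrame(rows).T[list(DETECTORS)]
    df.index.name = "subject"
    return AccuracyTable.from_rows(df)
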