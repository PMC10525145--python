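"""Sampling, splitting, iteration and aggregation protocols.

Two modes mirror the two levels of analysis:

* **trial_average** — per participant, one rare sample averaged from all
  24 rare trials and one frequent sample averaged from one of the
  floor(135/24) = 5 non-overlapping 24-trial subsets of frequent trials
  (subset membership fixed per cohort; *which* subset is used is redrawn
  every iteration).  With 200 participants this yields 400 samples per
  iteration, randomly re-split 300 train / 100 test each time.  The phase
  feature is the cross-trial phase-synchronization statistic.
* **single_trial** — per participant, all 24 rare trials plus 24 randomly
  selected frequent trials, each a sample of its own (4800 + 4800 at the
  200-participant scale).  The phase feature is the raw single-trial
  wavelet angle (phase synchronization is a cross-trial concept and does
  not exist per trial).

One *iteration* of the full procedure rebuilds the dataset, re-splits,
trains the three single-feature models, transfer-initializes and trains
the four composites, and records held-out accuracy after every training
epoch.  Iterations are aggregated into mean trajectories and mean +/- SEM
of a final-window accuracy (the last epoch in average mode; the mean of
the last 20 epochs in single-trial mode).

Sampling operations act on per-participant label sequences only, so
protocol counts can be exercised at full cohort scale without computing
any features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierModel, TrainingConfig, accuracy, labels_to_indices, train, transfer_init
from .data_model import BaselineSpec, EpochedRecording
from .features import (
    FeatureSample,
    WaveletSpec,
    compute_erp,
    crop_tensor,
    cwt,
    phase_synchronization,
    tf_phase,
    tf_power,
)

AVERAGE_KINDS = ("erp", "tf_power", "phase_sync")
SINGLE_TRIAL_KINDS = ("erp", "tf_power", "tf_phase")

DEFAULT_CROP = (-500.0, 1500.0)  # excludes wavelet edge-padding artefacts


def model_specs_for(kinds: tuple[str, ...]) -> list[tuple[str, ...]]:
    """The seven feature sets: three singles, three pairs, one triple."""
    e, t, p = kinds
    return [(e,), (t,), (p,), (e, t), (e, p), (t, p), (e, t, p)]


def spec_name(spec: tuple[str, ...]) -> str:
    return "+".join(spec)


def derive_seed(*parts: int) -> int:
    """Deterministically fold seed components into one 31-bit integer."""
    ss = np.random.SeedSequence(entropy=[int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class SamplingPlan:
    """How samples are drawn from a cohort across procedure iterations."""

    mode: str = "trial_average"
    n_per_average: int = 24
    test_fraction: float = 0.25
    n_iterations: int = 200
    seed: int = 0
    grouped_split: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("trial_average", "single_trial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_per_average < 1 or self.n_iterations < 1:
            raise ValueError("n_per_average and n_iterations must be >= 1")

    @property
    def final_window(self) -> int:
        """Epochs averaged into the summary score (last 20 for single-trial)."""
        return 20 if self.mode == "single_trial" else 1


@dataclass
class IterationResult:
    """Held-out accuracy after every training epoch, for one model in one
    realization of the full procedure."""

    model: str
    iteration: int
    accuracies: np.ndarray
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.accuracies.ndim != 1 or np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must be a 1-D vector in [0, 1]")


@dataclass
class SampleGroup:
    """One classifier sample: the same draw of trials seen by every feature."""

    participant_id: str
    label: str
    features: dict[str, FeatureSample]


# ---------------------------------------------------------------------------
# Trial sampling (feature-free: operates on label sequences)


def frequent_subsets(labels, n_per_average: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Non-overlapping ``n_per_average``-trial subsets of the frequent trials.

    Frequent trial indices are shuffled once and chunked into
    ``floor(n_frequent / n_per_average)`` consecutive blocks.
    """
    idx = np.flatnonzero(np.asarray(labels, dtype=object) == "frequent")
    if idx.size < n_per_average:
        raise ValueError(f"only {idx.size} frequent trials; need {n_per_average}")
    idx = rng.permutation(idx)
    n_subsets = idx.size // n_per_average
    return [np.sort(idx[k * n_per_average : (k + 1) * n_per_average]) for k in range(n_subsets)]


def draw_average_plan(
    cohort_labels: list[list[str]], plan: SamplingPlan, iteration_seed: int
) -> list[tuple[int, str, np.ndarray]]:
    """Trial draws for one trial-average iteration.

    Returns ``(participant_index, label, trial_ids)`` triples: per
    participant the full rare set plus one frequent subset chosen by the
    iteration seed (subset membership itself is fixed by ``plan.seed``).
    """
    rng_iter = np.random.default_rng(iteration_seed)
    out = []
    for p, labels in enumerate(cohort_labels):
        labels_arr = np.asarray(labels, dtype=object)
        rare = np.flatnonzero(labels_arr == "rare")
        if rare.size < plan.n_per_average:
            raise ValueError(
                f"participant {p}: only {rare.size} rare trials; need {plan.n_per_average}"
            )
        try:
            subsets = frequent_subsets(
                labels, plan.n_per_average, np.random.default_rng(derive_seed(plan.seed, 7, p))
            )
        except ValueError as exc:
            raise ValueError(f"participant {p}: {exc}") from exc
        chosen = subsets[rng_iter.integers(len(subsets))]
        out.append((p, "rare", rare))
        out.append((p, "frequent", chosen))
    return out


def draw_single_trial_plan(
    cohort_labels: list[list[str]], plan: SamplingPlan, iteration_seed: int
) -> list[tuple[int, str, int]]:
    """Trial draws for one single-trial iteration.

    Per participant: every rare trial, plus an equal number of frequent
    trials drawn without replacement by the iteration seed.
    """
    rng_iter = np.random.default_rng(iteration_seed)
    out = []
    for p, labels in enumerate(cohort_labels):
        labels_arr = np.asarray(labels, dtype=object)
        rare = np.flatnonzero(labels_arr == "rare")
        freq = np.flatnonzero(labels_arr == "frequent")
        if freq.size < rare.size:
            raise ValueError(f"participant {p}: fewer frequent than rare trials")
        chosen = np.sort(rng_iter.choice(freq, size=rare.size, replace=False))
        out.extend((p, "rare", int(i)) for i in rare)
        out.extend((p, "frequent", int(i)) for i in chosen)
    return out


def protocol_counts(
    n_participants: int = 200,
    n_rare: int = 24,
    n_frequent: int = 135,
    n_per_average: int = 24,
    seed: int = 0,
) -> dict[str, int]:
    """Run the sampling operations at full cohort scale, features unseen.

    Returns the per-iteration sample counts the sampling scheme produces:
    the trial-average dataset size, the number of non-overlapping frequent
    subsets per participant, and the single-trial counts per class.
    """
    labels = [["rare"] * n_rare + ["frequent"] * n_frequent for _ in range(n_participants)]
    plan = SamplingPlan(seed=seed, n_per_average=n_per_average)
    avg = draw_average_plan(labels, plan, derive_seed(seed, 1))
    subsets = frequent_subsets(labels[0], n_per_average, np.random.default_rng(seed))
    st = draw_single_trial_plan(labels, plan, derive_seed(seed, 2))
    st_labels = np.asarray([lab for _, lab, _ in st], dtype=object)
    return {
        "average_samples": len(avg),
        "frequent_subsets_per_participant": len(subsets),
        "single_trial_rare": int((st_labels == "rare").sum()),
        "single_trial_frequent": int((st_labels == "frequent").sum()),
    }


# ---------------------------------------------------------------------------
# Feature extraction for the two modes


def participant_average_features(
    rec: EpochedRecording,
    plan: SamplingPlan,
    participant_index: int,
    wavelet: WaveletSpec,
    baseline: BaselineSpec,
    crop: tuple[float, float] = DEFAULT_CROP,
) -> tuple[dict[str, FeatureSample], list[dict[str, FeatureSample]]]:
    """Rare sample and all frequent candidate samples for one participant.

    The rare sample averages every rare trial; each frequent candidate
    averages one non-overlapping subset.  All tensors are cropped to
    ``crop`` (ms) and stored as float32.
    """
    times = rec.times
    dec = cwt(rec, wavelet)

    def sample_for(trial_ids: np.ndarray, label: str) -> dict[str, FeatureSample]:
        erp = compute_erp(rec, trial_ids, baseline, label=label)
        power = tf_power(dec, trial_ids, baseline, average=True, label=label,
                         participant_id=rec.participant_id)
        sync = phase_synchronization(dec, trial_ids, baseline, label=label,
                                     participant_id=rec.participant_id)
        out = {}
        for fs in (erp, power, sync):
            fs.tensor = crop_tensor(fs.tensor, times, crop).astype(np.float32)
            out[fs.kind] = fs
        return out

    rare_ids = rec.trial_indices("rare")
    if rare_ids.size < plan.n_per_average:
        raise ValueError(
            f"participant {rec.participant_id}: only {rare_ids.size} rare trials; "
            f"need {plan.n_per_average}"
        )
    subset_rng = np.random.default_rng(derive_seed(plan.seed, 7, participant_index))
    subsets = frequent_subsets(rec.labels, plan.n_per_average, subset_rng)
    rare_sample = sample_for(rare_ids, "rare")
    candidates = [sample_for(s, "frequent") for s in subsets]
    return rare_sample, candidates


class AverageFeatureBank:
    """Per-cohort cache of trial-average features.

    Feature computation is the expensive step and depends only on the
    cohort and the fixed subset partition, so it is done once; iterations
    then only redraw which frequent candidate each participant contributes.
    """

    def __init__(
        self,
        cohort: list[EpochedRecording],
        plan: SamplingPlan,
        wavelet: WaveletSpec,
        baseline: BaselineSpec = BaselineSpec(),
        crop: tuple[float, float] = DEFAULT_CROP,
    ):
        self.plan = plan
        self.rare: list[dict[str, FeatureSample]] = []
        self.candidates: list[list[dict[str, FeatureSample]]] = []
        self.participant_ids = [rec.participant_id for rec in cohort]
        for p, rec in enumerate(cohort):
            rare_sample, cands = participant_average_features(
                rec, plan, p, wavelet, baseline, crop
            )
            self.rare.append(rare_sample)
            self.candidates.append(cands)

    def draw(self, iteration_seed: int) -> list[SampleGroup]:
        """One iteration's dataset: 2 samples per participant."""
        rng = np.random.default_rng(iteration_seed)
        groups = []
        for p, pid in enumerate(self.participant_ids):
            groups.append(SampleGroup(pid, "rare", self.rare[p]))
            chosen = self.candidates[p][rng.integers(len(self.candidates[p]))]
            groups.append(SampleGroup(pid, "frequent", chosen))
        return groups


def build_average_dataset(bank: AverageFeatureBank, iteration_seed: int) -> list[SampleGroup]:
    """Labeled sample groups for one trial-average iteration."""
    return bank.draw(iteration_seed)


def build_single_trial_dataset(
    cohort: list[EpochedRecording],
    plan: SamplingPlan,
    wavelet: WaveletSpec,
    baseline: BaselineSpec,
    iteration_seed: int,
    crop: tuple[float, float] = DEFAULT_CROP,
) -> list[SampleGroup]:
    """Labeled single-trial sample groups for one iteration.

    Per participant: every rare trial plus an equal number of seed-drawn
    frequent trials; features are the baselined epoch itself, the
    single-trial wavelet amplitude, and the raw single-trial phase.
    """
    cohort_labels = [rec.labels for rec in cohort]
    draws = draw_single_trial_plan(cohort_labels, plan, iteration_seed)
    by_participant: dict[int, list[tuple[str, int]]] = {}
    for p, label, trial in draws:
        by_participant.setdefault(p, []).append((label, trial))
    groups: list[SampleGroup] = []
    for p, rec in enumerate(cohort):
        wanted = by_participant[p]
        trial_ids = np.array([t for _, t in wanted])
        sub = EpochedRecording(
            data=rec.data[trial_ids],
            srate=rec.srate,
            window=rec.window,
            labels=[rec.labels[t] for t in trial_ids],
            channel_names=rec.channel_names,
            participant_id=rec.participant_id,
        )
        times = sub.times
        dec = cwt(sub, wavelet)
        powers = tf_power(dec, np.arange(sub.n_trials), baseline, average=False,
                          participant_id=rec.participant_id)
        for k, (label, trial) in enumerate(wanted):
            erp = compute_erp(sub, [k], baseline, label=label)
            erp.trial_ids = (trial,)
            power = powers[k]
            power.label = label
            power.trial_ids = (trial,)
            phase = tf_phase(dec, k, label=label, participant_id=rec.participant_id)
            phase.trial_ids = (trial,)
            feats = {}
            for fs in (erp, power, phase):
                fs.tensor = crop_tensor(fs.tensor, times, crop).astype(np.float32)
                feats[fs.kind] = fs
            groups.append(SampleGroup(rec.participant_id, label, feats))
    return groups


# ---------------------------------------------------------------------------
# Splitting, stacking, training


def split(
    groups: list[SampleGroup],
    test_fraction: float,
    seed: int,
    grouped: bool = False,
) -> tuple[list[SampleGroup], list[SampleGroup]]:
    """Uniform random train/test split without replacement.

    Sample-level by default (a participant may straddle the two sides);
    ``grouped=True`` splits whole participants instead for a leakage-safe
    variant.
    """
    n = len(groups)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if grouped:
        pids = sorted({g.participant_id for g in groups})
        n_test = max(1, int(round(test_fraction * len(pids))))
        test_pids = set(np.array(pids, dtype=object)[rng.permutation(len(pids))[:n_test]])
        test = [g for g in groups if g.participant_id in test_pids]
        train_g = [g for g in groups if g.participant_id not in test_pids]
    else:
        n_test = int(round(test_fraction * n))
        if n_test < 1 or n_test >= n:
            raise ValueError("degenerate split: need at least one sample per side")
        perm = rng.permutation(n)
        test = [groups[i] for i in perm[:n_test]]
        train_g = [groups[i] for i in perm[n_test:]]
    if not test or not train_g:
        raise ValueError("degenerate split: need at least one sample per side")
    return train_g, test


def stack_groups(groups: list[SampleGroup], kinds) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Flatten sample groups into per-feature design matrices plus labels."""
    X = {
        kind: np.stack([g.features[kind].flatten() for g in groups]).astype(np.float64)
        for kind in kinds
    }
    y = labels_to_indices([g.label for g in groups])
    return X, y


def run_procedure(
    cohort: list[EpochedRecording],
    plan: SamplingPlan,
    wavelet: WaveletSpec,
    training: TrainingConfig,
    baseline: BaselineSpec = BaselineSpec(),
    crop: tuple[float, float] = DEFAULT_CROP,
    model_specs: list[tuple[str, ...]] | None = None,
) -> list[IterationResult]:
    """The full multi-iteration procedure over the seven feature sets.

    Per iteration: rebuild the dataset, re-split, train the single-feature
    models, transfer-initialize and train every composite, recording
    held-out accuracy after each training epoch.  Fully deterministic given
    ``(plan.seed, training, cohort)``.
    """
    kinds = AVERAGE_KINDS if plan.mode == "trial_average" else SINGLE_TRIAL_KINDS
    specs = model_specs if model_specs is not None else model_specs_for(kinds)
    bank = None
    if plan.mode == "trial_average":
        bank = AverageFeatureBank(cohort, plan, wavelet, baseline, crop)
    results: list[IterationResult] = []
    for it in range(plan.n_iterations):
        iter_seed = derive_seed(plan.seed, 100, it)
        if plan.mode == "trial_average":
            groups = bank.draw(derive_seed(iter_seed, 0))
        else:
            groups = build_single_trial_dataset(
                cohort, plan, wavelet, baseline, derive_seed(iter_seed, 0), crop
            )
        train_g, test_g = split(groups, plan.test_fraction, derive_seed(iter_seed, 1),
                                grouped=plan.grouped_split)
        X_train, y_train = stack_groups(train_g, kinds)
        X_test, y_test = stack_groups(test_g, kinds)

        singles: dict[str, ClassifierModel] = {}
        for j, kind in enumerate(kinds):
            if (kind,) not in specs and not any(kind in s for s in specs if len(s) > 1):
                continue
            model = ClassifierModel({kind: X_train[kind].shape[1]},
                                    seed=derive_seed(iter_seed, 10, j))
            cfg = TrainingConfig(
                learning_rate=training.learning_rate,
                momentum=training.momentum,
                batch_size=training.batch_size,
                n_epochs=training.n_epochs,
                seed=derive_seed(iter_seed, 20, j),
            )
            model, _, accs = train(
                model, {kind: X_train[kind]}, y_train, cfg,
                eval_set=({kind: X_test[kind]}, y_test),
            )
            singles[kind] = model
            if (kind,) in specs:
                results.append(IterationResult(spec_name((kind,)), it, accs,
                                               seeds={"iteration": iter_seed}))
        for c, spec in enumerate(s for s in specs if len(s) > 1):
            composite = transfer_init([singles[k] for k in spec])
            cfg = TrainingConfig(
                learning_rate=training.learning_rate,
                momentum=training.momentum,
                batch_size=training.batch_size,
                n_epochs=training.n_epochs,
                seed=derive_seed(iter_seed, 30, c),
            )
            composite, _, accs = train(
                composite, {k: X_train[k] for k in spec}, y_train, cfg,
                eval_set=({k: X_test[k] for k in spec}, y_test),
            )
            results.append(IterationResult(spec_name(spec), it, accs,
                                           seeds={"iteration": iter_seed}))
    return results


def aggregate(results: list[IterationResult], final_window: int = 1) -> dict[str, dict]:
    """Mean trajectory and final-window mean +/- SEM per model.

    The per-iteration summary score is the mean held-out accuracy over the
    last ``final_window`` training epochs; SEM is sd / sqrt(n_iterations).
    Requires at least two iterations per model.
    """
    by_model: dict[str, list[IterationResult]] = {}
    for r in results:
        by_model.setdefault(r.model, []).append(r)
    out: dict[str, dict] = {}
    for model, rs in by_model.items():
        if len(rs) < 2:
            raise ValueError(f"model {model!r}: need >= 2 iterations to aggregate")
        rs = sorted(rs, key=lambda r: r.iteration)
        traj = np.stack([r.accuracies for r in rs])
        finals = traj[:, -final_window:].mean(axis=1)
        out[model] = {
            "mean_trajectory": traj.mean(axis=0),
            "final_per_iteration": finals,
            "mean": float(finals.mean()),
            "sem": float(finals.std(ddof=1) / np.sqrt(len(finals))),
            "n_iterations": len(finals),
        }
    return out


def results_to_frame(results: list[IterationResult]) -> pd.DataFrame:
    """Long-format (iteration, model, epoch, accuracy) table."""
    rows = [
        (r.iteration, r.model, epoch, acc)
        for r in results
        for epoch, acc in enumerate(r.accuracies)
    ]
    return pd.DataFrame(rows, columns=["iteration", "model", "epoch", "accuracy"])
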