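"""Experiment drivers: structural-statistics tables, scaling fits,
cross-distribution grids, bias probes, and pseudoknot censuses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..fold import FoldingOracle, get_oracle
from ..metrics import binary_report, evaluate_predictions
from ..pairedness.models import TrainingProtocol
from ..pairmatrix import (
    MatrixModelSpec,
    build_matrix_model,
    count_predicted_pairs,
    predict_matrix,
    train_matrix_model,
)
from ..structures import (
    RawPairAssignment,
    StructureStatsReport,
    aggregate_stats,
    crossing_and_multipair_census,
    matrix_to_structure,
    pairtable_to_matrix,
)
from ..synthdata import (
    PRESETS,
    DatasetBundle,
    dinucleotide_shuffle,
    fixed_length,
    fold_dataset,
    make_dataset,
    preset_distribution_sets,
)


# ---------------------------------------------------------------------------
# Table-3-style structural statistics


def table3_experiment(
    model=None,
    oracle: FoldingOracle | None = None,
    lengths=(70, 100),
    per_length: int = 2000,
    seed: int = 0,
) -> dict:
    """Structural statistics of oracle ground truth (and optionally a model).

    Returns {"oracle": {length: StructureStatsReport}, "model": {...}};
    model structures are obtained from raw matrices via postprocessing.
    """
    oracle = oracle or get_oracle()
    out: dict = {"oracle": {}, "model": {}}
    for L in lengths:
        bundle = make_dataset(
            per_length, fixed_length(L), seed=seed + L, oracle=oracle,
            split="test",
        )
        out["oracle"][L] = aggregate_stats(bundle.sequences, bundle.structures)
        if model is not None:
            pts = [
                matrix_to_structure(predict_matrix(model, s))
                for s in bundle.sequences
            ]
            out["model"][L] = aggregate_stats(bundle.sequences, pts)
    return out


# ---------------------------------------------------------------------------
# scaling analysis


@dataclass
class ScalingFit:
    """Linear vs quadratic least-squares fits of pair counts vs length."""

    lengths: list
    mean_counts: list
    linear: tuple  # (slope, intercept)
    quadratic: tuple  # (a, b, c)
    rss_linear: float
    rss_quadratic: float
    f_stat: float
    p_value: float

    @property
    def slope(self) -> float:
        return self.linear[0]

    @property
    def quad_coefficient(self) -> float:
        return self.quadratic[0]

    def quad_significant(self, alpha: float = 0.01) -> bool:
        return self.p_value < alpha


def fit_scaling(lengths, mean_counts) -> ScalingFit:
    """Nested-model F-test for a quadratic term in counts vs length."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 length bins for the nested F-test")
    lin = np.polyfit(x, y, 1)
    quad = np.polyfit(x, y, 2)
    rss1 = float(np.sum((y - np.polyval(lin, x)) ** 2))
    rss2 = float(np.sum((y - np.polyval(quad, x)) ** 2))
    df2 = len(x) - 3
    if rss2 <= 0:
        f = np.inf
        p = 0.0
    else:
        f = (rss1 - rss2) / (rss2 / df2)
        p = float(stats.f.sf(f, 1, df2))
    return ScalingFit(
        lengths=list(map(float, x)),
        mean_counts=list(map(float, y)),
        linear=tuple(lin),
        quadratic=tuple(quad),
        rss_linear=rss1,
        rss_quadratic=rss2,
        f_stat=float(f),
        p_value=p,
    )


def scaling_analysis(
    model, series: dict, threshold: float = 0.5
) -> tuple[ScalingFit | None, ScalingFit]:
    """(model fit, ground-truth fit) of mean pair counts vs sequence length.

    ``series`` maps length -> DatasetBundle.  Model counts are matrix
    entries above threshold before any postprocessing; ground-truth counts
    are true pair numbers.
    """
    if len(series) < 4:
        raise ValueError("need >= 4 length bins")
    lengths = sorted(series)
    truth_means, model_means = [], []
    for L in lengths:
        bundle = series[L]
        truth_means.append(
            float(np.mean([len(pt.pairs()) for pt in bundle.structures]))
        )
        if model is not None:
            model_means.append(
                float(
                    np.mean(
                        [
                            count_predicted_pairs(
                                predict_matrix(model, s), threshold
                            )
                            for s in bundle.sequences
                        ]
                    )
                )
            )
    truth_fit = fit_scaling(lengths, truth_means)
    model_fit = fit_scaling(lengths, model_means) if model is not None else None
    return model_fit, truth_fit


# ---------------------------------------------------------------------------
# cross-distribution grid


@dataclass
class GridResult:
    """MCC for every (training preset, validation preset) combination."""

    presets: list
    mcc: np.ndarray  # (4, 4)
    self_performance: np.ndarray  # MCC of each model on its own training set

    def diagonal_dominance(self) -> float:
        d = np.mean(np.diag(self.mcc))
        off = (self.mcc.sum() - np.trace(self.mcc)) / (
            self.mcc.size - len(self.presets)
        )
        return float(d - off)

    def as_dict(self) -> dict:
        return {
            "presets": self.presets,
            "mcc": self.mcc.tolist(),
            "self_performance": self.self_performance.tolist(),
            "diagonal_dominance": self.diagonal_dominance(),
        }


def cross_grid_experiment(
    model_spec: MatrixModelSpec,
    protocol: TrainingProtocol,
    train_size: int = 30000,
    val_size: int = 5000,
    seed: int = 0,
    presets=("D1", "D2", "D3", "D4"),
    oracle: FoldingOracle | None = None,
    self_eval_size: int | None = None,
) -> GridResult:
    """Train one model per length preset, evaluate on all validation sets."""
    presets = list(presets)
    oracle = oracle or get_oracle()
    bundles = {
        p: preset_distribution_sets(p, seed, train_size, val_size, oracle)
        for p in presets
    }
    k = len(presets)
    grid = np.zeros((k, k))
    self_perf = np.zeros(k)
    for a, pa in enumerate(presets):
        train, _ = bundles[pa]
        model = build_matrix_model(model_spec, seed=seed + a)
        model, _trace = train_matrix_model(
            model, train, bundles[pa][1], protocol
        )
        for b, pb in enumerate(presets):
            grid[a, b] = _matrix_mcc(model, bundles[pb][1])
        self_items = train if self_eval_size is None else train.subset(
            range(min(self_eval_size, len(train)))
        )
        self_perf[a] = _matrix_mcc(model, self_items)
    return GridResult(presets, grid, self_perf)


def _matrix_mcc(model, bundle) -> float:
    preds = [predict_matrix(model, s) for s in bundle.sequences]
    truths = [pairtable_to_matrix(pt) for pt in bundle.structures]
    return evaluate_predictions(preds, truths, "per-entry").mcc


# ---------------------------------------------------------------------------
# bias experiment


def bias_experiment(
    bias_train: DatasetBundle,
    bias_test: DatasetBundle,
    model_spec: MatrixModelSpec,
    protocol: TrainingProtocol,
    pretrain_epochs: int = 3,
    pretrain_size: int = 200,
    pretrain_lengths=(119, 120),
    seed: int = 0,
    oracle: FoldingOracle | None = None,
) -> dict:
    """Pre-train on random sequences, train on a structure-biased bundle,
    and compare MCC on the biased test set vs a dinucleotide-shuffled,
    refolded control at both checkpoints."""
    oracle = oracle or get_oracle()
    rng = np.random.default_rng(seed)
    # shuffled control: same composition, diverse structures
    shuffled_seqs, seen = [], set(bias_test.sequences)
    for s in bias_test.sequences:
        sh = dinucleotide_shuffle(s, rng)
        while sh in seen:
            sh = dinucleotide_shuffle(s, rng)
        seen.add(sh)
        shuffled_seqs.append(sh)
    shuffled = fold_dataset(shuffled_seqs, oracle, {"control": "dinuc-shuffle"},
                            "test")
    # pre-training on random long sequences
    per_len = max(1, pretrain_size // len(pretrain_lengths))
    pre_seqs: list[str] = []
    for L in pretrain_lengths:
        pre_seqs += make_dataset(
            per_len, fixed_length(L), seed=seed + L, oracle=oracle
        ).sequences
    pre_bundle = fold_dataset(pre_seqs, oracle, {}, "train")
    model = build_matrix_model(model_spec, seed=seed)
    pre_protocol = TrainingProtocol(
        max_epochs=pretrain_epochs,
        lr=protocol.lr,
        batch_size=protocol.batch_size,
        seed=protocol.seed,
        pos_weight=protocol.pos_weight,
    )
    model, _ = train_matrix_model(
        model, pre_bundle, bias_test.subset(range(min(50, len(bias_test)))),
        pre_protocol,
    )
    report = {
        "pretrained": {
            "mcc_inverse": _matrix_mcc(model, bias_test),
            "mcc_shuffled": _matrix_mcc(model, shuffled),
        }
    }
    model, trace = train_matrix_model(model, bias_train, bias_test, protocol)
    report["trained"] = {
        "mcc_inverse": _matrix_mcc(model, bias_test),
        "mcc_shuffled": _matrix_mcc(model, shuffled),
    }
    report["trace"] = trace
    return report


# ---------------------------------------------------------------------------
# pseudoknot / multi-pair census of raw network output


def pseudoknot_census_experiment(
    model,
    length: int = 100,
    count: int = 2000,
    seed: int = 0,
    threshold: float = 0.5,
    oracle: FoldingOracle | None = None,
) -> dict:
    """Binarize raw matrices (no postprocessing) and census crossings and
    multi-partnered positions; ground truth is censused as a control."""
    bundle = make_dataset(
        count, fixed_length(length), seed=seed, oracle=oracle, split="test"
    )
    raws = []
    for s in bundle.sequences:
        m = predict_matrix(model, s)
        iu = np.triu_indices(len(s), k=1)
        sel = m[iu] > threshold
        pairs = list(zip(iu[0][sel].tolist(), iu[1][sel].tolist()))
        raws.append(RawPairAssignment(len(s), pairs))
    truth_census = crossing_and_multipair_census(
        [RawPairAssignment(pt.n, pt.pairs()) for pt in bundle.structures]
    )
    model_census = crossing_and_multipair_census(raws)
    return {
        "model": model_census.as_tuple(),
        "ground_truth": truth_census.as_tuple(),
        "count": count,
        "length": length,
    }
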