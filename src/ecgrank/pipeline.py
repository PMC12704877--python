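"""End-to-end experiment orchestration.

A run executes: generate (or load) beats -> 70/30 stratified split -> fit
the input scaler on the training split -> train both extractors (AEF, CF)
-> fit the 8-classifier bank on each feature set (16 variants) -> metric
tables -> TOPSIS / mRMR rank tables per feature block and combined ->
McNemar + Holm pairwise comparison of the top-accuracy distinct models ->
report.  Everything is deterministic under the global seed (serial
execution); child seeds for the data, split, extractors and classifiers
are derived from it.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .classifiers import (PredictionSet, fit, predict, registry,
                          write_predictions_csv)
from .evaluation import (MetricTable, build_metric_table, printed_precision,
                         write_metric_csv)
from .features import (AutoencoderSpec, ConvExtractorSpec, apply_scaler,
                       build_autoencoder, build_conv_extractor, encode,
                       fit_scaler, save_extractor, train_autoencoder,
                       train_conv_extractor)
from .ranking import (pairwise_comparison_suite, pairwise_results_frame,
                      rank_metric_table)
from .synthetic import (DatasetSpec, SignalDataset, SplitSpec,
                        generate_dataset, read_beats_csv)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "desk_dataset_spec", "full_dataset_spec"]

# MIT-BIH class balance (4045 normal / 10505 abnormal) scaled to 2000 beats
DESK_COUNTS = {0: 556, 1: 1444}
FULL_COUNTS = {0: 4045, 1: 10505}


def desk_dataset_spec(seed: int = 0) -> DatasetSpec:
    return DatasetSpec(n_per_class=dict(DESK_COUNTS), seed=seed,
                       name="synthetic-desk")


def full_dataset_spec(seed: int = 0) -> DatasetSpec:
    return DatasetSpec(n_per_class=dict(FULL_COUNTS), seed=seed,
                       name="synthetic-full")


@dataclass
class ExperimentConfig:
    """Validated, serializable description of one experiment run."""

    seed: int = 0
    preset: str = "desk"                 # {"desk", "full"}
    input_csv: str | None = None         # load instead of generate
    dataset: DatasetSpec | None = None
    split: SplitSpec | None = None
    ae: AutoencoderSpec | None = None
    conv: ConvExtractorSpec | None = None
    weights: tuple[float, ...] | None = None
    alpha: float = 0.05
    top_k: int = 4                       # models entering the McNemar suite
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in ("desk", "full"):
            raise ValueError("preset must be 'desk' or 'full'")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        desk = self.preset == "desk"
        if self.dataset is None and self.input_csv is None:
            base = desk_dataset_spec if desk else full_dataset_spec
            self.dataset = base(seed=self.seed)
        if self.split is None:
            self.split = SplitSpec(seed=self.seed + 1)
        if self.ae is None:
            self.ae = AutoencoderSpec(epochs=50 if desk else 1000,
                                      seed=self.seed + 2)
        if self.conv is None:
            self.conv = ConvExtractorSpec(epochs=10 if desk else 50,
                                          seed=self.seed + 3)

    def to_dict(self) -> dict:
        def plain(obj):
            if obj is None:
                return None
            d = {}
            for k, v in vars(obj).items():
                if hasattr(v, "__dict__") and not isinstance(v, dict):
                    v = plain(v)
                elif isinstance(v, dict):
                    v = {str(kk): plain(vv) if hasattr(vv, "__dict__")
                         else vv for kk, vv in v.items()}
                elif isinstance(v, tuple):
                    v = list(v)
                d[k] = v
            return d
        out = {"seed": self.seed, "preset": self.preset,
               "input_csv": self.input_csv, "alpha": self.alpha,
               "top_k": self.top_k, "outdir": self.outdir,
               "weights": list(self.weights) if self.weights else None,
               "dataset": plain(self.dataset), "split": plain(self.split),
               "ae": plain(self.ae), "conv": plain(self.conv)}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        from .synthetic import BeatMorphology
        d = dict(d)
        ds = d.pop("dataset", None)
        if ds is not None:
            morphs = {int(k): BeatMorphology(
                wave_centers=tuple(m["wave_centers"]),
                wave_amplitudes=tuple(m["wave_amplitudes"]),
                wave_widths=tuple(m["wave_widths"]),
                beat_duration=m["beat_duration"])
                for k, m in ds.pop("morphology_per_class").items()}
            ds["n_per_class"] = {int(k): v
                                 for k, v in ds.pop("n_per_class").items()}
            d["dataset"] = DatasetSpec(morphology_per_class=morphs, **ds)
        sp = d.pop("split", None)
        if sp is not None:
            d["split"] = SplitSpec(**sp)
        ae = d.pop("ae", None)
        if ae is not None:
            ae["encoder_widths"] = tuple(ae["encoder_widths"])
            d["ae"] = AutoencoderSpec(**ae)
        cv = d.pop("conv", None)
        if cv is not None:
            d["conv"] = ConvExtractorSpec(**cv)
        w = d.pop("weights", None)
        if w is not None:
            d["weights"] = tuple(w)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Everything a run produced, with provenance."""

    config: ExperimentConfig
    metric_tables: dict[str, MetricTable]       # "AEF", "CF"
    combined_table: MetricTable
    rank_frames: dict[str, "pd.DataFrame"]      # per block + "combined"
    pairwise_results: list
    significance_matrix: "pd.DataFrame"
    collapsed_groups: list[list[str]]
    prediction_sets: dict[str, list[PredictionSet]]
    truth: np.ndarray
    loss_histories: dict[str, list[tuple[float, float]]]
    provenance: dict


def _log(stage: str, t0: float) -> None:
    print(f"[ecgrank] {stage} ({time.perf_counter() - t0:.1f}s)",
          file=sys.stderr)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full benchmark described by ``config``."""
    t0 = time.perf_counter()
    stage = "load data"
    try:
        if config.input_csv is not None:
            ds = read_beats_csv(config.input_csv)
        else:
            ds = generate_dataset(config.dataset)
        _log(stage, t0)

        stage = "split"
        train, test = split_dataset_cfg(ds, config)

        stage = "scale"
        scaler = fit_scaler(train.beats)
        scaled_train = apply_scaler(scaler, train.beats)

        stage = "train AEF extractor"
        aef = build_autoencoder(config.ae)
        train_autoencoder(aef, scaled_train, spec=config.ae)
        aef.scaler = scaler
        _log(stage, t0)

        stage = "train CF extractor"
        cf = build_conv_extractor(config.conv,
                                  input_dim=train.signal_length)
        train_conv_extractor(cf, scaled_train, train.labels)
        cf.scaler = scaler
        _log(stage, t0)

        metric_tables: dict[str, MetricTable] = {}
        predsets: dict[str, list[PredictionSet]] = {}
        for tag, extractor in (("AEF", aef), ("CF", cf)):
            stage = f"classifier bank on {tag} features"
            feats_train = encode(extractor, train.beats, train.name)
            feats_test = encode(extractor, test.beats, test.name)
            block = []
            for spec in registry(seed=config.seed + 4):
                model = fit(spec, feats_train, train.labels,
                            extractor_kind=tag)
                block.append(predict(model, feats_test))
            predsets[tag] = block
            metric_tables[tag] = build_metric_table(
                block, test.labels, dataset_tag=ds.name, feature_tag=tag)
            _log(stage, t0)

        stage = "ranking"
        combined = MetricTable(
            rows=metric_tables["AEF"].rows + metric_tables["CF"].rows,
            dataset_tag=ds.name, feature_tag="AEF+CF")
        rank_frames = {tag: rank_metric_table(printed_precision(tbl),
                                              config.weights)
                       for tag, tbl in metric_tables.items()}
        rank_frames["combined"] = rank_metric_table(
            printed_precision(combined), config.weights)

        stage = "pairwise McNemar suite"
        all_preds = predsets["AEF"] + predsets["CF"]
        acc = {r.model_id: r.accuracy for r in combined.rows}
        ordered = sorted(all_preds, key=lambda ps: -acc[ps.model_id])
        distinct: list[PredictionSet] = []
        for ps in ordered:  # keep top_k models with distinct predictions
            if not any(np.array_equal(ps.labels, q.labels)
                       for q in distinct):
                distinct.append(ps)
            if len(distinct) == config.top_k:
                break
        results, sig, groups = pairwise_comparison_suite(
            distinct, test.labels, alpha=config.alpha)
        _log(stage, t0)

        from . import __version__ as pkg_version
        provenance = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": pkg_version,
            "python": sys.version.split()[0],
            "n_train": train.n, "n_test": test.n,
        }
        report = ExperimentReport(
            config=config, metric_tables=metric_tables,
            combined_table=combined, rank_frames=rank_frames,
            pairwise_results=results, significance_matrix=sig,
            collapsed_groups=groups,
            prediction_sets=predsets, truth=test.labels,
            loss_histories={"AEF": list(aef.loss_history),
                            "CF": list(cf.loss_history)},
            provenance=provenance)
        if config.outdir is not None:
            stage = "write outputs"
            _write_outputs(report, aef, cf)
            _log(stage, t0)
        return report
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: "
                           f"{exc}") from exc


def split_dataset_cfg(ds: SignalDataset, config: ExperimentConfig):
    from .synthetic import split_dataset
    return split_dataset(ds, config.split)


def _write_outputs(report: ExperimentReport, aef, cf) -> None:
    out = Path(report.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = report.provenance["config_hash"]
    report.config.to_yaml(out / f"config_{h}.yaml")
    for tag, tbl in report.metric_tables.items():
        write_metric_csv(printed_precision(tbl),
                         out / f"metrics_{tag}_{h}.csv")
    write_metric_csv(printed_precision(report.combined_table),
                     out / f"metrics_combined_{h}.csv")
    for tag, frame in report.rank_frames.items():
        frame.to_csv(out / f"ranks_{tag}_{h}.csv", index=False)
    all_preds = (report.prediction_sets["AEF"]
                 + report.prediction_sets["CF"])
    write_predictions_csv(all_preds, report.truth,
                          out / f"predictions_{h}.csv")
    pairwise_results_frame(report.pairwise_results).to_csv(
        out / f"pairwise_{h}.csv", index=False)
    report.significance_matrix.to_csv(out / f"significance_{h}.csv")
    save_extractor(aef, out / f"extractor_AEF_{h}.npz",
                   out / f"extractor_AEF_{h}.json")
    save_extractor(cf, out / f"extractor_CF_{h}.npz",
                   out / f"extractor_CF_{h}.json")
    summary = {
        "provenance": report.provenance,
        "collapsed_groups": report.collapsed_groups,
        "loss_final": {k: v[-1] if v else None
                       for k, v in report.loss_histories.items()},
    }
    (out / f"report_{h}.json").write_text(json.dumps(summary, indent=2))
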