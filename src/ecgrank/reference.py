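"""Hand-entered reference metric tables distributed with the package.

These are the published benchmark results of the 16 pipeline variants on
the MIT-BIH and ECG5000 beat matrices (AUC / F1 / accuracy, percent scale,
printed precision).  They drive the worked examples and the reproduction
script: the ranking stage consumes them directly, exactly as it consumes
tables computed by a run.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import MetricTable, read_metric_csv

__all__ = ["available_tables", "load_reference_table"]

_FILES = {
    ("mitbih", "aef"): "metrics_mitbih_aef.csv",
    ("mitbih", "cf"): "metrics_mitbih_cf.csv",
    ("mitbih", "all"): "metrics_mitbih_all.csv",
    ("ecg5000", "aef"): "metrics_ecg5000_aef.csv",
    ("ecg5000", "cf"): "metrics_ecg5000_cf.csv",
    ("ecg5000", "all"): "metrics_ecg5000_all.csv",
}


def available_tables() -> list[tuple[str, str]]:
    return sorted(_FILES)


def load_reference_table(dataset: str, block: str) -> MetricTable:
    """Load one reference table.

    Parameters
    ----------
    dataset : {"mitbih", "ecg5000"}
    block : {"aef", "cf", "all"}
        Autoencoder-feature block (8 models), convolution-feature block
        (8 models), or the combined 16-model table.
    """
    key = (dataset.lower(), block.lower())
    if key not in _FILES:
        raise KeyError(f"no reference table {key}; "
                       f"choose from {available_tables()}")
    path = resources.files("ecgrank.data").joinpath(_FILES[key])
    with resources.as_file(path) as p:
        return read_metric_csv(p, dataset_tag=key[0], feature_tag=key[1])
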