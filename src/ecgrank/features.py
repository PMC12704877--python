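"""Dual feature extraction: autoencoder bottleneck (AEF) and 1-D
convolution/pooling (CF).

Both extractors share the same contracts: inputs are standard-scaled beats
(scaler fitted on the training split only), ``encode`` maps k beats to a
k x output_dim :class:`FeatureSet` deterministically, and training histories
are recorded per epoch.

The autoencoder is symmetric: Dense / BatchNorm / LeakyReLU encoder stages
narrowing to a 47-unit bottleneck (for 187-sample beats), mirrored decoder,
linear reconstruction output, Adam + MSE.  The conv extractor is two
kernel-3 same-padded convolution stages (32 then 64 filters, ReLU), each
followed by same-padded stride-2 max pooling, with dropout before a flatten;
it is trained once through a temporary softmax classification head that is
discarded afterwards, and its flattened features are re-standardized before
classifier use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ScalerParams", "AutoencoderSpec", "ConvExtractorSpec",
    "TrainedExtractor", "FeatureSet",
    "fit_scaler", "apply_scaler",
    "build_autoencoder", "train_autoencoder",
    "build_conv_extractor", "train_conv_extractor",
    "encode", "save_extractor", "load_extractor",
]


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature standardization parameters (population statistics).

    Standard deviations of constant features are replaced by 1, so those
    features scale to exactly zero.
    """

    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]


def fit_scaler(train_beats: np.ndarray) -> ScalerParams:
    """Fit standardization parameters on the training split only."""
    x = np.asarray(train_beats, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("train_beats must be a non-empty 2-D matrix")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return ScalerParams(mean=mean, sd=sd)


def apply_scaler(params: ScalerParams, beats: np.ndarray) -> np.ndarray:
    x = np.asarray(beats, dtype=float)
    if x.ndim != 2 or x.shape[1] != params.n_features:
        raise ValueError(
            f"expected {params.n_features} features, got shape {x.shape}")
    return (x - params.mean) / params.sd


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training settings for the bottleneck autoencoder.

    ``encoder_widths`` must be strictly decreasing and end in
    ``bottleneck_dim`` (default 47 for 187-sample beats; the hidden ladder
    128-96-64-47 is a smooth reduction and is configurable).  Training uses
    Adam at ``learning_rate`` with MSE reconstruction loss.
    """

    input_dim: int = 187
    encoder_widths: tuple[int, ...] = (128, 96, 64, 47)
    bottleneck_dim: int = 47
    leaky_slope: float = 0.01
    use_batch_norm: bool = True
    learning_rate: float = 1e-3
    epochs: int = 1000
    batch_size: int = 64
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.encoder_widths
        if not w or any(a <= b for a, b in zip(w, w[1:])):
            raise ValueError("encoder_widths must be strictly decreasing")
        if w[-1] != self.bottleneck_dim:
            raise ValueError("encoder_widths must end in bottleneck_dim")
        if not self.bottleneck_dim < self.input_dim:
            raise ValueError("bottleneck_dim must be < input_dim")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class ConvExtractorSpec:
    """Two-stage convolution/pooling extractor settings.

    With ``channel_pool`` off (default) the output is the full flattened
    vector (final temporal length x 64 channels, 3008 for 187-sample input);
    with it on, channels are averaged so the output has one value per
    temporal position (47 for 187-sample input).
    """

    filters1: int = 32
    filters2: int = 64
    kernel: int = 3
    pool: int = 3
    pool_stride: int = 2
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 64
    channel_pool: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_stride < 1:
            raise ValueError("pool_stride must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class FeatureSet:
    """n x d extracted-feature matrix tagged with its extractor identity."""

    matrix: np.ndarray
    extractor_kind: str
    source_dataset: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.size and not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass
class TrainedExtractor:
    """A fitted (or freshly initialized) feature extractor.

    ``scaler`` standardizes raw beats before the network; for CF,
    ``feature_scaler`` additionally standardizes the extracted features.
    ``loss_history`` holds one (train, validation) pair per epoch.
    """

    kind: str                      # {"AEF", "CF"}
    spec: object
    encoder: nn.Sequential
    output_dim: int
    scaler: ScalerParams | None = None
    feature_scaler: ScalerParams | None = None
    decoder: nn.Sequential | None = None
    head: nn.Sequential | None = None
    loss_history: list[tuple[float, float]] = field(default_factory=list)
    conv_temporal_length: int | None = None


def _dense_block(n_in, n_out, slope, use_bn, rng):
    layers = [nn.Dense(n_in, n_out, rng)]
    if use_bn:
        layers.append(nn.BatchNorm(n_out))
    layers.append(nn.LeakyReLU(slope))
    return layers


def build_autoencoder(spec: AutoencoderSpec) -> TrainedExtractor:
    """Untrained symmetric autoencoder; encoder output width is the
    bottleneck dimension, reconstruction output is linear."""
    rng = np.random.default_rng(spec.seed)
    enc_layers, n_in = [], spec.input_dim
    for width in spec.encoder_widths:
        enc_layers += _dense_block(n_in, width, spec.leaky_slope,
                                   spec.use_batch_norm, rng)
        n_in = width
    dec_layers = []
    mirror = list(spec.encoder_widths[-2::-1])  # decoder mirrors the encoder
    for width in mirror:
        dec_layers += _dense_block(n_in, width, spec.leaky_slope,
                                   spec.use_batch_norm, rng)
        n_in = width
    dec_layers.append(nn.Dense(n_in, spec.input_dim, rng))  # linear output
    return TrainedExtractor(
        kind="AEF", spec=spec,
        encoder=nn.Sequential(enc_layers),
        decoder=nn.Sequential(dec_layers),
        output_dim=spec.bottleneck_dim)


def train_autoencoder(extractor: TrainedExtractor,
                      scaled_train: np.ndarray,
                      scaled_validation: np.ndarray | None = None,
                      spec: AutoencoderSpec | None = None,
                      epochs: int | None = None) -> TrainedExtractor:
    """Train the reconstruction objective; record per-epoch (train, val)
    MSE; the returned extractor encodes via the bottleneck."""
    spec = spec or extractor.spec
    epochs = spec.epochs if epochs is None else epochs
    x = np.asarray(scaled_train, dtype=float)
    if scaled_validation is None and spec.validation_fraction > 0 and \
            x.shape[0] >= 10:
        n_val = max(1, int(round(x.shape[0] * spec.validation_fraction)))
        scaled_validation, x = x[:n_val], x[n_val:]
    xv = (np.asarray(scaled_validation, dtype=float)
          if scaled_validation is not None else None)
    model = nn.Sequential([extractor.encoder, extractor.decoder])
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    for _ in range(epochs):
        order = rng.permutation(x.shape[0])
        batch_losses = []
        for start in range(0, x.shape[0], spec.batch_size):
            xb = x[order[start:start + spec.batch_size]]
            recon = model.forward(xb, train=True)
            loss, grad = nn.mse_loss_grad(recon, xb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss!r}; reduce the "
                    f"learning rate or check the input scaling")
            model.backward(grad)
            opt.step()
            batch_losses.append(loss)
        train_loss = float(np.mean(batch_losses))
        if xv is not None and xv.shape[0]:
            val_loss, _ = nn.mse_loss_grad(model.forward(xv, train=False), xv)
        else:
            val_loss = train_loss
        extractor.loss_history.append((train_loss, float(val_loss)))
    return extractor


def build_conv_extractor(spec: ConvExtractorSpec, input_dim: int,
                         n_classes: int = 2) -> TrainedExtractor:
    """Untrained conv/pool extractor plus its temporary classification head.

    Each same-padded stride-2 pooling stage halves the temporal length
    (rounded up): 187 -> 94 -> 47.
    """
    if input_dim < spec.kernel:
        raise ValueError("input_dim must be >= kernel size")
    rng = np.random.default_rng(spec.seed)
    l1 = nn.pooled_output_length(input_dim, spec.pool_stride)
    l2 = nn.pooled_output_length(l1, spec.pool_stride)
    enc = nn.Sequential([
        nn.Conv1D(1, spec.filters1, spec.kernel, rng),
        nn.ReLU(),
        nn.MaxPool1D(spec.pool, spec.pool_stride),
        nn.Conv1D(spec.filters1, spec.filters2, spec.kernel, rng),
        nn.ReLU(),
        nn.MaxPool1D(spec.pool, spec.pool_stride),
        nn.Dropout(spec.dropout_rate, rng),
        nn.Flatten(),
    ])
    flat_dim = l2 * spec.filters2
    head = nn.Sequential([nn.Dense(flat_dim, n_classes, rng)])
    output_dim = l2 if spec.channel_pool else flat_dim
    return TrainedExtractor(kind="CF", spec=spec, encoder=enc, head=head,
                            output_dim=output_dim, conv_temporal_length=l2)


def train_conv_extractor(extractor: TrainedExtractor,
                         scaled_train: np.ndarray,
                         labels: np.ndarray,
                         epochs: int | None = None) -> TrainedExtractor:
    """Train conv layers through the temporary softmax head (cross-entropy
    on the binary labels), then fit the feature standardizer and discard
    the head for feature extraction."""
    spec = extractor.spec
    epochs = spec.epochs if epochs is None else epochs
    x = np.asarray(scaled_train, dtype=float)[:, :, None]
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("conv extractor training needs both classes")
    model = nn.Sequential([extractor.encoder, extractor.head])
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    for _ in range(epochs):
        order = rng.permutation(x.shape[0])
        batch_losses = []
        for start in range(0, x.shape[0], spec.batch_size):
            sel = order[start:start + spec.batch_size]
            logits = model.forward(x[sel], train=True)
            loss, grad = nn.softmax_xent_loss_grad(logits, y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss!r}")
            model.backward(grad)
            opt.step()
            batch_losses.append(loss)
        m = float(np.mean(batch_losses))
        extractor.loss_history.append((m, m))
    raw = _raw_features(extractor, x[:, :, 0])
    extractor.feature_scaler = fit_scaler(raw)
    return extractor


def _raw_features(extractor: TrainedExtractor, scaled_beats: np.ndarray):
    if extractor.kind == "AEF":
        return extractor.encoder.forward(scaled_beats, train=False)
    out = extractor.encoder.forward(scaled_beats[:, :, None], train=False)
    if getattr(extractor.spec, "channel_pool", False):
        l2 = extractor.conv_temporal_length
        out = out.reshape(out.shape[0], l2, -1).mean(axis=2)
    return out


def encode(extractor: TrainedExtractor, beats: np.ndarray,
           source_dataset: str = "") -> FeatureSet:
    """Map beats to features (deterministic: eval mode, no dropout).

    If the extractor carries an input scaler it is applied first, so
    ``beats`` may be raw; otherwise they must already be scaled.
    """
    x = np.asarray(beats, dtype=float)
    expected = (extractor.scaler.n_features if extractor.scaler is not None
                else None)
    if x.ndim != 2 or (expected is not None and x.shape[1] != expected):
        raise ValueError(f"encode expected (n, {expected}) beats, "
                         f"got shape {x.shape}")
    if extractor.scaler is not None:
        x = apply_scaler(extractor.scaler, x)
    if x.shape[0] == 0:
        return FeatureSet(np.empty((0, extractor.output_dim)),
                          extractor.kind, source_dataset)
    out = _raw_features(extractor, x)
    if extractor.feature_scaler is not None:
        out = apply_scaler(extractor.feature_scaler, out)
    return FeatureSet(out, extractor.kind, source_dataset)


def _state_arrays(seq: nn.Sequential) -> list[np.ndarray]:
    """All persistent arrays of a network: parameters plus batch-norm
    running statistics, in deterministic layer order."""
    arrays = [p for p, _ in seq.params()]
    stack = list(seq.layers)
    while stack:
        layer = stack.pop(0)
        if isinstance(layer, nn.Sequential):
            stack = list(layer.layers) + stack
        elif isinstance(layer, nn.BatchNorm):
            arrays += [layer.running_mean, layer.running_var]
    return arrays


def save_extractor(extractor: TrainedExtractor, weights_path,
                   meta_path) -> None:
    """Persist weights (npz) plus a JSON sidecar with spec and scalers."""
    weights = {}
    for i, p in enumerate(_state_arrays(extractor.encoder)):
        weights[f"enc_{i}"] = p
    for part in ("decoder", "head"):
        seq = getattr(extractor, part)
        if seq is not None:
            for i, p in enumerate(_state_arrays(seq)):
                weights[f"{part}_{i}"] = p
    np.savez(weights_path, **weights)
    meta = {
        "kind": extractor.kind,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(extractor.spec).items()},
        "output_dim": extractor.output_dim,
        "loss_history": extractor.loss_history,
        "input_dim": (extractor.scaler.n_features
                      if extractor.scaler else None),
        "scaler": _scaler_dict(extractor.scaler),
        "feature_scaler": _scaler_dict(extractor.feature_scaler),
        "conv_temporal_length": extractor.conv_temporal_length,
    }
    Path(meta_path).write_text(json.dumps(meta))


def _scaler_dict(s: ScalerParams | None):
    if s is None:
        return None
    return {"mean": s.mean.tolist(), "sd": s.sd.tolist()}


def _scaler_from(d) -> ScalerParams | None:
    if d is None:
        return None
    return ScalerParams(mean=np.array(d["mean"]), sd=np.array(d["sd"]))


def load_extractor(weights_path, meta_path) -> TrainedExtractor:
    meta = json.loads(Path(meta_path).read_text())
    spec_d = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in meta["spec"].items()}
    if meta["kind"] == "AEF":
        extractor = build_autoencoder(AutoencoderSpec(**spec_d))
    else:
        extractor = build_conv_extractor(ConvExtractorSpec(**spec_d),
                                         input_dim=meta["input_dim"])
    with np.load(weights_path) as archive:
        for i, p in enumerate(_state_arrays(extractor.encoder)):
            p[...] = archive[f"enc_{i}"]
        for part in ("decoder", "head"):
            seq = getattr(extractor, part)
            if seq is not None:
                for i, p in enumerate(_state_arrays(seq)):
                    key = f"{part}_{i}"
                    if key in archive:
                        p[...] = archive[key]
    extractor.loss_history = [tuple(t) for t in meta["loss_history"]]
    extractor.scaler = _scaler_from(meta["scaler"])
    extractor.feature_scaler = _scaler_from(meta["feature_scaler"])
    return extractor
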