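"""Epoch band-power features and the sleep/wake classification experiment.

A four-level decomposition of two EEG channels yields eight features per
30 s epoch: the per-sample mean-square power of the level-2/3/4 details and
the level-4 approximation (12.5-25, 6.25-12.5, 3.125-6.25 and 0-3.125 Hz at
a 100 Hz base rate).  Level-1 details are excluded: with no band limiting
ahead of the level-1 highpass, broadband noise passes straight through and
the analog estimate of that branch is poor.  Per-sample mean square (not
sum) keeps decimated coefficient streams and continuous oversampled
outputs on a common scale.

A feed-forward network (three hidden layers by default) is trained on the
features of all records but one and tested on the held-out record;
sensitivity = 100*TP/(TP+FN) and selectivity = 100*TP/(TP+FP) are averaged
over the folds, per class.  The transfer experiment trains on decimated-DWT
features and swaps the held-out record's features for analog-bank features
at test time only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .compare import MultiResResult, adwt_multires
from .signals import Signal
from .synthesis import ADWTDesignParams, build_filter_bank
from .wavelets import DWTDecomposition, dwt_multires

__all__ = [
    "ConfusionCounts",
    "ClassifierSpec",
    "DEFAULT_BRANCHES",
    "epoch_band_powers",
    "eeg_feature_table",
    "sensitivity",
    "selectivity",
    "confusion_from_labels",
    "loocv_experiment",
]

DEFAULT_BRANCHES = ("D2", "D3", "D4", "A4")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class confusion counts; totals must equal the test epoch count."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def sensitivity(c: ConfusionCounts) -> float:
    """100*TP/(TP+FN): fraction of true positives correctly classified."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive examples")
    return 100.0 * c.tp / (c.tp + c.fn)


def selectivity(c: ConfusionCounts) -> float:
    """100*TP/(TP+FP): fraction of positive calls that are correct."""
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("selectivity undefined: no positive calls")
    return 100.0 * c.tp / (c.tp + c.fp)


def confusion_from_labels(y_true, y_pred, positive) -> ConfusionCounts:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("label arrays differ in length")
    pos_t = yt == positive
    pos_p = yp == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _branch_series(result) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Map branch label (D1..Dn, A<n>) -> (times, values) for either transform."""
    if isinstance(result, DWTDecomposition):
        out = {f"D{i + 1}": (result.detail_times[i], result.details[i])
               for i in range(result.levels)}
        out[f"A{result.levels}"] = (result.approximation_times, result.approximation)
        return out
    if isinstance(result, MultiResResult):
        out = {f"D{i + 1}": (result.details[i].times, result.details[i].values)
               for i in range(result.levels)}
        out[f"A{result.levels}"] = (result.approx[-1].times, result.approx[-1].values)
        return out
    raise TypeError(f"unsupported decomposition type {type(result).__name__}")


def epoch_band_powers(
    result,
    epoch_s: float = 30.0,
    branches: tuple[str, ...] = DEFAULT_BRANCHES,
    log10: bool = False,
) -> pd.DataFrame:
    """Per-epoch, per-branch mean-square power of a decomposition.

    A sample at time t belongs to epoch floor(t/epoch_s); the final partial
    epoch is dropped, as is any epoch in which some branch has no samples.
    ``log10=True`` returns log10 powers (zero powers floored at 1e-300).

    Returns a DataFrame indexed by epoch with one column per branch.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    series = _branch_series(result)
    missing = [b for b in branches if b not in series]
    if missing:
        raise ValueError(f"decomposition lacks branches {missing}")
    t_end = min(t[-1] for b in branches for t in (series[b][0],))
    n_epochs = int(np.floor((t_end + 1e-12) / epoch_s))
    cols = {}
    for b in branches:
        t, v = series[b]
        idx = np.floor(t / epoch_s).astype(int)
        keep = idx < n_epochs
        counts = np.bincount(idx[keep], minlength=n_epochs)
        sums = np.bincount(idx[keep], weights=v[keep] ** 2, minlength=n_epochs)
        with np.errstate(invalid="ignore"):
            power = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        cols[b] = power
    df = pd.DataFrame(cols, index=pd.RangeIndex(n_epochs, name="epoch"))
    df = df.dropna()
    if log10:
        df = np.log10(df.clip(lower=1e-300))
    return df


def eeg_feature_table(
    signal: Signal,
    labels: np.ndarray,
    transform: str = "dwt",
    wavelet: str = "db1",
    levels: int = 4,
    epoch_s: float = 30.0,
    oversample: int = 1,
    record_id: str = "rec",
) -> pd.DataFrame:
    """Eight-feature epoch table for a multi-channel record.

    Decomposes each channel with the decimated DWT (``transform="dwt"``) or
    the analog bank (``"adwt"``, FIR-matched gains) and concatenates the
    four band powers per channel; attaches the per-epoch labels.
    """
    if transform not in ("dwt", "adwt"):
        raise ValueError("transform must be 'dwt' or 'adwt'")
    parts = []
    for c in range(signal.n_channels):
        ch = signal.channel(c)
        if transform == "dwt":
            dec = dwt_multires(ch, wavelet, levels)
        else:
            params = ADWTDesignParams.for_wavelet(wavelet, ch.fs)
            bank = build_filter_bank(params, levels, mode="designed",
                                     gain="fir_matched")
            dec = adwt_multires(ch, bank, oversample=oversample)
        bp = epoch_band_powers(dec, epoch_s=epoch_s)
        bp.columns = [f"ch{c + 1}_{b}" for b in bp.columns]
        parts.append(bp)
    df = pd.concat(parts, axis=1, join="inner")
    n = min(len(df), len(labels))
    df = df.iloc[:n].copy()
    df["label"] = np.asarray(labels)[:n]
    df.insert(0, "record", record_id)
    return df.reset_index()


@dataclass(frozen=True)
class ClassifierSpec:
    """Training configuration for the epoch classifier.

    ``hidden`` sizes the three hidden layers of the feed-forward network
    (input + 3 hidden + output = five layers); ``algorithm`` selects
    ``"mlp"`` (lbfgs-trained network) or ``"logistic"`` (deterministic
    linear fallback).  ``log10_features`` applies log10 to the powers,
    which span decades, before standardization.
    """

    hidden: tuple[int, ...] = (16, 8, 4)
    algorithm: str = "mlp"
    max_iter: int = 500
    seed: int = 0
    log10_features: bool = True


def _make_classifier(spec: ClassifierSpec):
    if spec.algorithm == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=spec.hidden,
            activation="logistic",
            solver="lbfgs",
            max_iter=spec.max_iter,
            random_state=spec.seed,
        )
    elif spec.algorithm == "logistic":
        clf = LogisticRegression(max_iter=spec.max_iter)
    else:
        raise ValueError(f"unknown algorithm {spec.algorithm!r}")
    return make_pipeline(StandardScaler(), clf)


def _feature_matrix(table: pd.DataFrame, log10: bool) -> np.ndarray:
    cols = [c for c in table.columns if c not in ("record", "epoch", "label")]
    x = table[cols].to_numpy(dtype=float)
    if log10:
        x = np.log10(np.clip(x, 1e-300, None))
    return x


def loocv_experiment(
    tables: list[pd.DataFrame],
    spec: ClassifierSpec | None = None,
    test_tables: list[pd.DataFrame] | None = None,
    classes: tuple[str, str] = ("wake", "sleep"),
) -> pd.DataFrame:
    """Leave-one-record-out cross-validated sensitivity/selectivity.

    One fold per record: the classifier (standardization fitted on the
    training folds only) is trained on all records but one and evaluated on
    the held-out record.  With ``test_tables`` given, the held-out record's
    features are taken from the paired alternative tables instead (the
    train-on-DWT / test-on-analog transfer experiment); training data and
    standardization statistics are unchanged.

    Returns a DataFrame with columns class, sensitivity, selectivity —
    fold averages per class.  Folds whose training data contain a single
    class are skipped; metrics undefined on a fold (no positives present or
    predicted) are excluded from that average.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 records for leave-one-out")
    if test_tables is not None and len(test_tables) != len(tables):
        raise ValueError("test_tables must pair one-to-one with tables")
    spec = spec or ClassifierSpec()

    per_class: dict[str, dict[str, list[float]]] = {
        c: {"sensitivity": [], "selectivity": []} for c in classes
    }
    for k in range(len(tables)):
        train = pd.concat([t for i, t in enumerate(tables) if i != k],
                          ignore_index=True)
        if train["label"].nunique() < 2:
            continue
        test = tables[k] if test_tables is None else test_tables[k]
        model = _make_classifier(spec)
        model.fit(_feature_matrix(train, spec.log10_features),
                  train["label"].to_numpy())
        pred = model.predict(_feature_matrix(test, spec.log10_features))
        truth = test["label"].to_numpy()
        for cls in classes:
            c = confusion_from_labels(truth, pred, positive=cls)
            if c.tp + c.fn > 0:
                per_class[cls]["sensitivity"].append(sensitivity(c))
            if c.tp + c.fp > 0:
                per_class[cls]["selectivity"].append(selectivity(c))
    rows = []
    for cls in classes:
        rows.append(dict(
            **{"class": cls},
            sensitivity=float(np.mean(per_class[cls]["sensitivity"]))
            if per_class[cls]["sensitivity"] else np.nan,
            selectivity=float(np.mean(per_class[cls]["selectivity"]))
            if per_class[cls]["selectivity"] else np.nan,
        ))
    return pd.DataFrame(rows)
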